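"""Genome model: chromosomal region catalogs and synthetic transcript annotation.

The genome is partitioned into chromosomal regions — p/q arms of
submetacentric chromosomes plus whole acrocentric chromosomes — which are
the unit of arm-level copy-number calling and of every per-region density
statistic downstream.  The default human layout subdivides the genome into
42 regions: both arms of the 17 non-acrocentric autosomes, the five
acrocentric autosomes (13, 14, 15, 21, 22) as single regions, Xp, Xq, and Y.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

ARM = "arm"
WHOLE = "whole-acrocentric"

PROTEIN_CODING = "protein_coding"
LINCRNA = "lincRNA"
OTHER_NONCODING = "other_noncoding"
TEC = "TEC"

#: biotype labels excluded from the per-biotype partition tables
EXCLUDED_BIOTYPES = frozenset({TEC, "NA", "not_assessed"})

# Approximate chromosome lengths and centromere positions (Mb).  Acrocentric
# autosomes and Y carry a single region and have no centromere entry.
_CHROMOSOMES: list[tuple[str, float, float | None]] = [
    ("1", 249.0, 123.4),
    ("2", 242.2, 93.9),
    ("3", 198.3, 90.9),
    ("4", 190.2, 50.0),
    ("5", 181.5, 48.8),
    ("6", 170.8, 59.8),
    ("7", 159.3, 60.1),
    ("8", 145.1, 45.2),
    ("9", 138.4, 43.0),
    ("10", 133.8, 39.8),
    ("11", 135.1, 53.4),
    ("12", 133.3, 35.5),
    ("13", 114.4, None),
    ("14", 107.0, None),
    ("15", 102.0, None),
    ("16", 90.3, 36.8),
    ("17", 83.3, 25.1),
    ("18", 80.4, 18.5),
    ("19", 58.6, 26.2),
    ("20", 64.4, 28.1),
    ("21", 46.7, None),
    ("22", 50.8, None),
    ("X", 156.0, 60.6),
    ("Y", 57.2, None),
]

_MB = 1_000_000


@dataclass(frozen=True)
class Region:
    """One chromosomal region: an arm or a whole acrocentric chromosome."""

    region_id: str
    chromosome: str
    start: int
    end: int
    kind: str  # ARM or WHOLE

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionCatalog:
    """The partition of the genome into chromosomal regions.

    Regions within a chromosome must be disjoint and region ids unique.
    The catalog is the coordinate authority for arm-level calls, group
    selection and NCDI computation.
    """

    def __init__(self, regions: list[Region]):
        ids = [r.region_id for r in regions]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate region ids in catalog")
        for r in regions:
            if r.end <= r.start:
                raise ConfigurationError(f"region {r.region_id} has non-positive length")
        by_chrom: dict[str, list[Region]] = {}
        for r in regions:
            by_chrom.setdefault(r.chromosome, []).append(r)
        for chrom, rs in by_chrom.items():
            rs_sorted = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs_sorted, rs_sorted[1:]):
                if b.start < a.end:
                    raise ConfigurationError(
                        f"regions {a.region_id} and {b.region_id} overlap on chromosome {chrom}"
                    )
        self._regions = list(regions)
        self._by_id = {r.region_id: r for r in regions}
        self._by_chrom = {c: sorted(rs, key=lambda r: r.start) for c, rs in by_chrom.items()}

    # -- access -----------------------------------------------------------

    @property
    def regions(self) -> list[Region]:
        return list(self._regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self._regions]

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for r in self._regions:
            if r.chromosome not in seen:
                seen.append(r.chromosome)
        return seen

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def region(self, region_id: str) -> Region:
        return self._by_id[region_id]

    def regions_of(self, chromosome: str) -> list[Region]:
        if chromosome not in self._by_chrom:
            raise KeyError(f"chromosome {chromosome!r} not in catalog")
        return list(self._by_chrom[chromosome])

    def is_acrocentric(self, chromosome: str) -> bool:
        return all(r.kind == WHOLE for r in self.regions_of(chromosome))

    def arms_of(self, chromosome: str) -> tuple[Region, Region]:
        """Return (p, q) arms; raises for single-region chromosomes."""
        rs = self.regions_of(chromosome)
        if len(rs) != 2:
            raise ConfigurationError(
                f"chromosome {chromosome} has {len(rs)} region(s); p/q arms undefined"
            )
        return rs[0], rs[1]

    def transcript_totals(self, annotation: pd.DataFrame) -> pd.Series:
        """X_n: total transcripts per region, indexed like the catalog."""
        counts = annotation["region"].value_counts()
        return counts.reindex(self.region_ids, fill_value=0).astype(int)

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.region_id for r in self._regions],
                "chromosome": [r.chromosome for r in self._regions],
                "start": [r.start for r in self._regions],
                "end": [r.end for r in self._regions],
                "kind": [r.kind for r in self._regions],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionCatalog":
        return cls(
            [
                Region(str(row.region), str(row.chromosome), int(row.start), int(row.end), str(row.kind))
                for row in df.itertuples()
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chromosome": str, "region": str}))

    @classmethod
    def from_layout(cls, layout: str) -> "RegionCatalog":
        """Build a catalog from a named layout.

        ``human-42``
            The default 42-region human layout described in the module
            docstring.
        ``toy-N``
            N regions on synthetic chromosomes ``c1, c2, ...``: pairs of
            1 Mb p/q arms; if N is odd the last chromosome is a single
            2 Mb acrocentric-style region.
        """
        if layout == "human-42":
            regions: list[Region] = []
            for chrom, length_mb, cen_mb in _CHROMOSOMES:
                length = int(length_mb * _MB)
                if cen_mb is None:
                    regions.append(Region(chrom, chrom, 0, length, WHOLE))
                else:
                    cen = int(cen_mb * _MB)
                    regions.append(Region(f"{chrom}p", chrom, 0, cen, ARM))
                    regions.append(Region(f"{chrom}q", chrom, cen, length, ARM))
            return cls(regions)
        m = re.fullmatch(r"toy-(\d+)", layout)
        if m:
            n = int(m.group(1))
            if n < 1:
                raise ConfigurationError("toy layout needs at least one region")
            regions = []
            for i in range(n // 2):
                chrom = f"c{i + 1}"
                regions.append(Region(f"{chrom}p", chrom, 0, _MB, ARM))
                regions.append(Region(f"{chrom}q", chrom, _MB, 2 * _MB, ARM))
            if n % 2:
                chrom = f"c{n // 2 + 1}"
                regions.append(Region(chrom, chrom, 0, 2 * _MB, WHOLE))
            return cls(regions)
        raise ConfigurationError(f"unknown region layout {layout!r}")


_BIOTYPES = np.array([PROTEIN_CODING, LINCRNA, OTHER_NONCODING, TEC])
_BIOTYPE_PROBS = np.array([0.65, 0.15, 0.17, 0.03])


def build_genome_model(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RegionCatalog, pd.DataFrame]:
    """Build the region catalog and a synthetic transcript annotation.

    Transcripts are placed uniformly inside their region with log-normal
    lengths (median ~2 kb) and a biotype drawn from the protein-coding /
    lincRNA / other-non-coding repertoire (plus a small TEC fraction that
    exercises the downstream biotype exclusion rule).

    Returns ``(catalog, annotation)`` where the annotation has one row per
    transcript with columns: transcript, gene, chromosome, start, end,
    length, biotype, region.
    """
    config.validate()
    catalog = RegionCatalog.from_layout(config.region_layout)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    idx = 0
    for region in catalog.regions:
        n = config.n_transcripts_per_region
        lengths = np.exp(rng.normal(np.log(2000.0), 0.8, size=n))
        lengths = np.clip(lengths, 200, max(200, region.length // 2)).astype(int)
        starts = region.start + (rng.random(n) * (region.length - lengths)).astype(int)
        biotypes = rng.choice(_BIOTYPES, size=n, p=_BIOTYPE_PROBS)
        order = np.argsort(starts)
        for j in order:
            rows.append(
                {
                    "transcript": f"T{idx:05d}",
                    "gene": f"G{idx:05d}",
                    "chromosome": region.chromosome,
                    "start": int(starts[j]),
                    "end": int(starts[j] + lengths[j]),
                    "length": int(lengths[j]),
                    "biotype": str(biotypes[j]),
                    "region": region.region_id,
                }
            )
            idx += 1
    annotation = pd.DataFrame(rows).set_index("transcript")
    return catalog, annotation
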