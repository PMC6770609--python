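"""Arm-level copy-number calling from segmented profiles.

A region (chromosome arm or whole acrocentric chromosome) is called gained
when segments with copy number above the cohort ploidy cover strictly more
than 50% of its length, and lost when sub-ploidy segments do; exactly 50%
is neutral.  Unsegmented gaps count as neutral bases, which dilutes the
aberrant fraction (conservative).  Because the gained and lost fractions of
one region sum to at most 1, a region can never be simultaneously gained
and lost.

Derived per-sample quantities: the broad-CNA count (number of non-neutral
calls), the karyotype class (normal: 0 broad CNAs; near-normal: 1-2;
aberrant: >2) and isochromosome flags — i(Nq) meaning p-arm loss with
simultaneous q-arm gain on chromosome N, and i(Np) the mirror pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ARM, RegionCatalog

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

KARYOTYPE_NORMAL = "normal"
KARYOTYPE_NEAR_NORMAL = "near-normal"
KARYOTYPE_ABERRANT = "aberrant"


class SegmentError(ValueError):
    """Raised for segments outside the catalog or malformed profiles."""


def _check_segments(segments: pd.DataFrame, catalog: RegionCatalog) -> None:
    chroms = set(catalog.chromosomes)
    for row in segments.itertuples():
        if row.end <= row.start:
            raise SegmentError(
                f"segment {row.chromosome}:{row.start}-{row.end} has non-positive length"
            )
        if str(row.chromosome) not in chroms:
            raise SegmentError(
                f"segment {row.chromosome}:{row.start}-{row.end} lies outside the catalog"
            )
    for chrom, sub in segments.groupby("chromosome"):
        s = sub.sort_values("start")
        prev_end = None
        for row in s.itertuples():
            if prev_end is not None and row.start < prev_end:
                raise SegmentError(f"overlapping segments on chromosome {chrom}")
            prev_end = row.end


def aberrant_fractions(
    segments: pd.DataFrame, catalog: RegionCatalog, ploidy: int = 2
) -> pd.DataFrame:
    """Per-region fractions of bases above/below ploidy for one profile.

    ``segments`` holds one sample's rows with columns chromosome, start,
    end, copy_number.  Returns a frame indexed by region id with columns
    ``gain_fraction`` and ``loss_fraction``.
    """
    _check_segments(segments, catalog)
    out = pd.DataFrame(
        0.0, index=pd.Index(catalog.region_ids, name="region"),
        columns=["gain_fraction", "loss_fraction"],
    )
    for region in catalog.regions:
        sub = segments[segments["chromosome"].astype(str) == region.chromosome]
        if sub.empty:
            continue
        starts = np.maximum(sub["start"].to_numpy(), region.start)
        ends = np.minimum(sub["end"].to_numpy(), region.end)
        overlap = np.maximum(ends - starts, 0)
        cn = sub["copy_number"].to_numpy()
        gained = overlap[cn > ploidy].sum()
        lost = overlap[cn < ploidy].sum()
        out.loc[region.region_id, "gain_fraction"] = gained / region.length
        out.loc[region.region_id, "loss_fraction"] = lost / region.length
    return out


def call_arm_cna(
    segments: pd.DataFrame, catalog: RegionCatalog, ploidy: int = 2
) -> pd.Series:
    """Gain/loss/neutral call per region for one sample's profile."""
    frac = aberrant_fractions(segments, catalog, ploidy)
    calls = pd.Series(NEUTRAL, index=frac.index, name="call")
    calls[frac["gain_fraction"] > 0.5] = GAIN
    calls[frac["loss_fraction"] > 0.5] = LOSS
    return calls


@dataclass
class ArmCallMatrix:
    """Per-sample, per-region calls with derived karyotype summaries."""

    calls: pd.DataFrame  # samples x regions, values gain/loss/neutral
    catalog: RegionCatalog

    def __post_init__(self) -> None:
        missing = set(self.catalog.region_ids) - set(self.calls.columns)
        if missing:
            raise SegmentError(f"call matrix lacks regions: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    def broad_cna_count(self) -> pd.Series:
        return (self.calls != NEUTRAL).sum(axis=1).rename("broad_cna_count")

    def karyotype(self) -> pd.Series:
        return self.broad_cna_count().map(karyotype_class_from_count).rename("karyotype")

    def iso_flags(self) -> pd.DataFrame:
        """Boolean matrix of i(Np)/i(Nq) flags per sample."""
        cols: dict[str, pd.Series] = {}
        for chrom in self.catalog.chromosomes:
            regions = self.catalog.regions_of(chrom)
            if len(regions) != 2 or any(r.kind != ARM for r in regions):
                continue  # whole acrocentrics never carry an isochromosome flag
            p, q = regions
            cols[f"i({chrom}q)"] = (
                (self.calls[p.region_id] == LOSS) & (self.calls[q.region_id] == GAIN)
            )
            cols[f"i({chrom}p)"] = (
                (self.calls[p.region_id] == GAIN) & (self.calls[q.region_id] == LOSS)
            )
        return pd.DataFrame(cols, index=self.calls.index)


def build_arm_call_matrix(
    segments: pd.DataFrame, catalog: RegionCatalog, ploidy: int = 2
) -> ArmCallMatrix:
    """Call every sample in a SEG-like table (long format)."""
    rows = {}
    for sample, sub in segments.groupby("sample", sort=False):
        rows[sample] = call_arm_cna(sub, catalog, ploidy)
    calls = pd.DataFrame.from_dict(rows, orient="index")
    calls = calls.reindex(columns=catalog.region_ids, fill_value=NEUTRAL)
    calls.index.name = "sample"
    return ArmCallMatrix(calls=calls, catalog=catalog)


def detect_isochromosome(calls_row: pd.Series, catalog: RegionCatalog) -> dict[str, bool]:
    """Isochromosome flags for one sample's call row."""
    flags: dict[str, bool] = {}
    for chrom in catalog.chromosomes:
        regions = catalog.regions_of(chrom)
        if len(regions) != 2 or any(r.kind != ARM for r in regions):
            continue
        p, q = regions
        flags[f"i({chrom}q)"] = calls_row[p.region_id] == LOSS and calls_row[q.region_id] == GAIN
        flags[f"i({chrom}p)"] = calls_row[p.region_id] == GAIN and calls_row[q.region_id] == LOSS
    return flags


def karyotype_class_from_count(n_broad: int) -> str:
    if n_broad == 0:
        return KARYOTYPE_NORMAL
    if n_broad <= 2:
        return KARYOTYPE_NEAR_NORMAL
    return KARYOTYPE_ABERRANT


def karyotype_class(calls_row: pd.Series) -> str:
    """Karyotype class of one sample from its call row."""
    return karyotype_class_from_count(int((calls_row != NEUTRAL).sum()))


def cna_frequencies(
    calls: ArmCallMatrix | pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Percentage of samples with a gain / loss call per region.

    ``samples`` restricts the tabulation to a subset (e.g. CIN tumours);
    an empty subset is an error.
    """
    df = calls.calls if isinstance(calls, ArmCallMatrix) else calls
    if samples is not None:
        missing = set(samples) - set(df.index)
        if missing:
            raise KeyError(f"samples not in call matrix: {sorted(missing)[:5]}")
        df = df.loc[list(samples)]
    if len(df) == 0:
        raise ValueError("cannot tabulate frequencies over an empty sample subset")
    n = len(df)
    return pd.DataFrame(
        {
            "gain_pct": 100.0 * (df == GAIN).sum(axis=0) / n,
            "loss_pct": 100.0 * (df == LOSS).sum(axis=0) / n,
        }
    ).rename_axis("region")
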