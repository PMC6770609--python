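"""Chromosomal densities and the Normalized Chromosomal Distribution Index.

For a transcript class with ``x_n`` members among the ``X_n`` transcripts
of region ``n``, the density is ``d_n = x_n / X_n`` and

    NCDI_n = d_n / sum_i d_i * 100,

so NCDI values sum to 100 over the T regions of the genome partition.
Regions without any annotated transcript are dropped (with a warning) and
T reduced, which preserves the sum-to-100 invariant on toy genomes.
NCDI is density-weighted, not count-weighted, so it is deliberately not
invariant under merging regions.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genome import RegionCatalog


def ncdi(
    class_members: Iterable[str],
    annotation: pd.DataFrame,
    catalog: RegionCatalog,
) -> pd.DataFrame:
    """NCDI profile of one transcript class.

    Returns a frame indexed by region with columns ``x_n``, ``X_n``,
    ``density`` and ``ncdi``.  Raises if a class member is missing from
    the annotation or the class is empty.
    """
    members = pd.Index(list(class_members)).unique()
    missing = members.difference(annotation.index)
    if len(missing):
        raise KeyError(f"class members absent from annotation, e.g. {missing[0]}")
    totals = catalog.transcript_totals(annotation)
    empty = totals.index[totals == 0]
    if len(empty):
        warnings.warn(f"dropping {len(empty)} region(s) without transcripts: {list(empty)}")
        totals = totals[totals > 0]
    x = (
        annotation.loc[members, "region"].value_counts()
        .reindex(totals.index, fill_value=0)
        .astype(int)
    )
    density = x / totals
    total_density = density.sum()
    if total_density == 0:
        raise ValueError("empty transcript class: NCDI undefined")
    out = pd.DataFrame(
        {"x_n": x, "X_n": totals, "density": density, "ncdi": density / total_density * 100.0}
    )
    out.index.name = "region"
    return out


def ncdi_by_tpm_bin(
    class_members: Iterable[str],
    tpm_summary: pd.Series,
    bin_edges: Iterable[float],
    region: str,
    annotation: pd.DataFrame,
    catalog: RegionCatalog,
) -> pd.DataFrame:
    """NCDI of one region recomputed inside each TPM bin.

    ``tpm_summary`` maps every transcript of the universe to a single TPM
    value (typically the mean over the selected group's samples).  Bins
    are half-open ``[lo, hi)`` with the last bin closed.  Bins without any
    transcript in the universe yield NaN (flagged, not an error); a
    populated bin without class members yields 0.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 edges")
    members = pd.Index(list(class_members)).unique()
    universe = tpm_summary.index
    missing = members.difference(universe)
    if len(missing):
        raise KeyError(f"class members without TPM summary, e.g. {missing[0]}")
    if region not in catalog.region_ids:
        raise KeyError(f"unknown region {region!r}")
    values = tpm_summary.to_numpy(dtype=float)
    bin_idx = np.digitize(values, edges[1:-1], right=False)  # 0..len(edges)-2
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    rows = []
    for i, label in enumerate(labels):
        in_bin = universe[bin_idx == i]
        n_universe = len(in_bin)
        bin_members = members.intersection(in_bin)
        if n_universe == 0 or len(bin_members) == 0:
            # empty bin -> undefined (NaN); populated bin with no class
            # members -> zero density in every region of the bin
            value = 0.0 if n_universe > 0 else float("nan")
            rows.append({"bin": label, "n_transcripts": n_universe,
                         "n_class": len(bin_members), "ncdi": value})
            continue
        profile = ncdi(bin_members, annotation.loc[annotation.index.intersection(in_bin)], catalog)
        value = float(profile.loc[region, "ncdi"]) if region in profile.index else 0.0
        rows.append({"bin": label, "n_transcripts": n_universe,
                     "n_class": len(bin_members), "ncdi": value})
    return pd.DataFrame(rows).set_index("bin")


def correlate_ncdi_cna(profile: pd.DataFrame | pd.Series, freqs: pd.Series) -> float:
    """Pearson r between a class's NCDI values and per-region CNA frequencies."""
    values = profile["ncdi"] if isinstance(profile, pd.DataFrame) else profile
    common = values.index.intersection(freqs.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched regions for a correlation")
    va = values.loc[common].to_numpy(dtype=float)
    vb = freqs.loc[common].to_numpy(dtype=float)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(va, vb).statistic)
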