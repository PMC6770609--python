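"""Signed hypergeometric enrichment and depletion of transcript classes.

Given a universe of N transcripts (restricted to one chromosomal region),
an annotated set of K (e.g. the region's up-regulated transcripts or a
fitness gene set) and a query set of n (e.g. the region's overexpressed
transcripts) with overlap k, the expected overlap is nK/N and the fold is
k divided by it.  Folds below 1 are reported under the negative-reciprocal
convention (0.5 becomes -2).  The test is one-sided with the direction
chosen by the observed overlap: P(X >= k) for enrichment, P(X <= k) for
depletion, X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome import RegionCatalog

ENRICHMENT = "enrichment"
DEPLETION = "depletion"


@dataclass
class EnrichmentResult:
    """One signed hypergeometric test."""

    universe_size: int      # N
    annotated_size: int     # K
    query_size: int         # n
    overlap: int            # k
    expected: float         # nK/N
    fold: float             # k / expected
    signed_fold: float      # fold if >= 1, else -1/fold
    pvalue: float
    direction: str          # enrichment or depletion
    region: str | None = None

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "N": self.universe_size,
            "K": self.annotated_size,
            "n": self.query_size,
            "k": self.overlap,
            "expected": self.expected,
            "fold": self.fold,
            "signed_fold": self.signed_fold,
            "pvalue": self.pvalue,
            "direction": self.direction,
        }


def signed_fold(raw_fold: float) -> float:
    """Negative-reciprocal reporting of folds below 1 (0 maps to -inf)."""
    if raw_fold >= 1.0:
        return float(raw_fold)
    if raw_fold == 0.0:
        return float("-inf")
    return float(-1.0 / raw_fold)


def hypergeom_enrichment(
    universe: Iterable[str],
    annotated_set: Iterable[str],
    query_set: Iterable[str],
    region: str | None = None,
) -> EnrichmentResult:
    """Signed hypergeometric test of a query against an annotated set.

    Both sets are intersected with the universe first (the caller is
    expected to have restricted the universe to one region already).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    annotated = set(annotated_set) & uni
    query = set(query_set) & uni
    if not query:
        raise ValueError("empty query set within the universe")
    n_uni, n_ann, n_query = len(uni), len(annotated), len(query)
    k = len(annotated & query)
    expected = n_query * n_ann / n_uni
    if expected == 0:
        raise ValueError("expected overlap is zero (empty annotated set)")
    fold = k / expected
    if k >= expected:
        direction = ENRICHMENT
        p = float(hypergeom.sf(k - 1, n_uni, n_ann, n_query))
    else:
        direction = DEPLETION
        p = float(hypergeom.cdf(k, n_uni, n_ann, n_query))
    return EnrichmentResult(
        universe_size=n_uni,
        annotated_size=n_ann,
        query_size=n_query,
        overlap=k,
        expected=expected,
        fold=fold,
        signed_fold=signed_fold(fold),
        pvalue=min(p, 1.0),
        direction=direction,
        region=region,
    )


def run_enrichment_grid(
    universe: Iterable[str],
    query_set: Iterable[str],
    annotated_sets: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
    catalog: RegionCatalog,
    regions: Iterable[str],
) -> pd.DataFrame:
    """Region x annotated-class grid of signed hypergeometric tests.

    For each requested region the universe is restricted to its
    transcripts before testing the query (typically the overexpressed
    transcripts) against every annotated class (up/down-regulated
    transcripts and external gene sets).  Cells whose annotated set or
    query is empty within the region are marked not-computable (NC).
    """
    uni = pd.Index(list(universe)).unique()
    missing = uni.difference(annotation.index)
    if len(missing):
        raise KeyError(f"universe members absent from annotation, e.g. {missing[0]}")
    region_of = annotation.loc[uni, "region"]
    query = set(query_set)
    rows = []
    for region in regions:
        if region not in catalog.region_ids:
            raise KeyError(f"unknown region {region!r}")
        region_universe = set(uni[region_of == region])
        for name, members in annotated_sets.items():
            cell = {"region": region, "annotated_class": name}
            try:
                res = hypergeom_enrichment(region_universe, members, query, region)
            except ValueError:
                cell.update({"signed_fold": np.nan, "pvalue": np.nan, "nc": True,
                             "N": len(region_universe), "K": len(set(members) & region_universe),
                             "n": len(query & region_universe), "k": 0,
                             "direction": "NC"})
            else:
                cell.update({"signed_fold": res.signed_fold, "pvalue": res.pvalue,
                             "nc": False, "N": res.universe_size, "K": res.annotated_size,
                             "n": res.query_size, "k": res.overlap,
                             "direction": res.direction})
            rows.append(cell)
    return pd.DataFrame(rows)


def run_table1(
    assignment: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
    catalog: RegionCatalog,
    regions: Iterable[str],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Enrichment grid of overexpressed transcripts per selected region.

    The query is the ``over_t`` class; annotated classes are the
    group-level up/down-regulated transcripts plus the supplied external
    gene sets (fitness, gained-VEL, focal-amplification).  The universe
    defaults to every transcript that entered differential testing (the
    assignment's index).
    """
    uni = pd.Index(list(universe)) if universe is not None else assignment.index
    query = assignment.index[assignment["over_t"].astype(bool)]
    annotated: dict[str, Iterable[str]] = {
        "positive_t": assignment.index[assignment["positive_t_group"].astype(bool)],
        "negative_t": assignment.index[assignment["negative_t_group"].astype(bool)],
    }
    for name, members in gene_sets.items():
        annotated[name] = list(members)
    return run_enrichment_grid(uni, query, annotated, annotation, catalog, regions)
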