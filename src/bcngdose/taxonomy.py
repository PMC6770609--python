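"""Transcript-class taxonomy derived from the four contrasts.

Classes (all thresholds configurable through ``AnalysisConfig``):

* ``vt_FCk`` — variable transcripts: BH-FDR below the threshold in
  contrast FCk.
* ``positive_t`` / ``negative_t`` — cohort-level up/down-regulation:
  variable in FC1 (all tumours vs normals) with linear FC above / below 1.
* ``positive_t_fc3`` / ``positive_t_fc4`` (and the negative mirrors) —
  up/down-regulation of the control / selected group vs normals, each
  requiring FDR significance in its own contrast.
* ``positive_t_group`` / ``negative_t_group`` — up (down) in both FC3 and
  FC4: the group-level definition used by the enrichment grid.
* ``over_t`` — overexpressed transcripts: variable in FC2 with linear FC2
  above the overexpression threshold (default 1.3).
* ``over_positive_t`` / ``over_negative_t`` — over_t whose FC3 and FC4 are
  both above 1 (both below 1), i.e. overexpressed transcripts that are
  also up- (down-)regulated vs normal tissue.

Internally "FC < 1" is evaluated as a negative signed linear fold-change.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import AnalysisConfig
from .diffexpr import DEResult
from .genome import EXCLUDED_BIOTYPES, LINCRNA, OTHER_NONCODING, PROTEIN_CODING

CLASS_COLUMNS = [
    "vt_fc1", "vt_fc2", "vt_fc3", "vt_fc4",
    "positive_t", "negative_t",
    "positive_t_fc3", "positive_t_fc4",
    "negative_t_fc3", "negative_t_fc4",
    "positive_t_group", "negative_t_group",
    "over_t", "over_positive_t", "over_negative_t",
]


def _check_universes(results: dict[str, DEResult]) -> pd.Index:
    items = list(results.items())
    base_name, base = items[0]
    for name, res in items[1:]:
        if not base.transcripts.equals(res.transcripts):
            diff = base.transcripts.symmetric_difference(res.transcripts)
            raise ValueError(
                f"contrasts {base_name} and {name} cover different transcript universes; "
                f"symmetric difference has {len(diff)} entries, e.g. {list(diff[:5])}"
            )
    return base.transcripts


def classify(
    de_fc1: DEResult,
    de_fc2: DEResult,
    de_fc3: DEResult,
    de_fc4: DEResult,
    config: AnalysisConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign every transcript its taxonomy flags from the four contrasts.

    Returns a boolean flag table indexed by the shared transcript
    universe; signed fold-changes of each contrast are carried along as
    ``fc1..fc4``.  If ``annotation`` is given, its ``biotype`` column is
    attached.
    """
    config = config or AnalysisConfig()
    config.validate()
    results = {"FC1": de_fc1, "FC2": de_fc2, "FC3": de_fc3, "FC4": de_fc4}
    universe = _check_universes(results)
    alpha = config.fdr_threshold

    flags = pd.DataFrame(index=universe)
    for name, res in results.items():
        key = name.lower()
        flags[f"vt_{key}"] = res.table["fdr"] < alpha
        flags[key] = res.table["signed_fc"]

    up1 = flags["fc1"] > 0
    flags["positive_t"] = flags["vt_fc1"] & up1
    flags["negative_t"] = flags["vt_fc1"] & ~up1

    flags["positive_t_fc3"] = flags["vt_fc3"] & (flags["fc3"] > 0)
    flags["positive_t_fc4"] = flags["vt_fc4"] & (flags["fc4"] > 0)
    flags["negative_t_fc3"] = flags["vt_fc3"] & (flags["fc3"] < 0)
    flags["negative_t_fc4"] = flags["vt_fc4"] & (flags["fc4"] < 0)
    flags["positive_t_group"] = flags["positive_t_fc3"] & flags["positive_t_fc4"]
    flags["negative_t_group"] = flags["negative_t_fc3"] & flags["negative_t_fc4"]

    flags["over_t"] = flags["vt_fc2"] & (flags["fc2"] > config.overt_fc2_threshold)
    flags["over_positive_t"] = flags["over_t"] & (flags["fc3"] > 0) & (flags["fc4"] > 0)
    flags["over_negative_t"] = flags["over_t"] & (flags["fc3"] < 0) & (flags["fc4"] < 0)

    if annotation is not None:
        flags["biotype"] = annotation["biotype"].reindex(universe)
    return flags


def class_members(assignment: pd.DataFrame, column: str) -> pd.Index:
    """Transcripts carrying one taxonomy flag."""
    return assignment.index[assignment[column].astype(bool)]


_BIOTYPE_TABLES = {
    PROTEIN_CODING: (PROTEIN_CODING,),
    LINCRNA: (LINCRNA,),
    "non_coding": (OTHER_NONCODING,),
}


def biotype_partition(
    assignment: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Split the assignment into protein-coding / lincRNA / non-coding tables.

    TEC and not-assessed entries are excluded from every table; unknown
    biotype labels are routed to the non-coding table with a warning.
    """
    biotype = annotation["biotype"].reindex(assignment.index)
    if biotype.isna().any():
        raise KeyError(
            f"transcripts without biotype, e.g. {assignment.index[biotype.isna()][0]}"
        )
    known = set(EXCLUDED_BIOTYPES) | {b for bs in _BIOTYPE_TABLES.values() for b in bs}
    unknown = set(biotype.unique()) - known
    if unknown:
        warnings.warn(f"unknown biotype labels routed to non-coding: {sorted(unknown)}")
    tables = {}
    for name, accepted in _BIOTYPE_TABLES.items():
        mask = biotype.isin(accepted)
        if name == "non_coding" and unknown:
            mask = mask | biotype.isin(unknown)
        tables[name] = assignment.loc[mask]
    return tables


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Counts of the seven intersection regions of three sets."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(a & b & c),
    }
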