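"""Selected and control tumour groups, and profile similarity between them.

A *selected* group collects tumours bearing a specific broad copy-number
gain pattern on a target chromosome — whole-chromosome gain (every region
of the chromosome called gain) or an isochromosome pattern (p-loss +
q-gain for i(Nq), the mirror for i(Np)).  The matched *control* group
collects tumours with no arm-level CNA on any region of that chromosome;
aberrations elsewhere in the genome are unconstrained.  Groups can be
restricted to an instability class (CIN / MSI) from the sample metadata
before selection.

Profile similarity between two groups is the Pearson correlation of their
per-region gain and loss frequency vectors, after dropping the target
chromosome's entries (whose frequencies are structurally forced to 0% in
the control group and 100% in the selected group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .armcalls import GAIN, LOSS, NEUTRAL, ArmCallMatrix
from .config import ConfigurationError

WHOLE_GAIN = "whole-gain"
ISO_Q = "iso-q"
ISO_P = "iso-p"
CONTROL = "control"

_MODES = (WHOLE_GAIN, ISO_Q, ISO_P, CONTROL)


@dataclass
class GroupDefinition:
    group_id: str
    mode: str
    chromosome: str
    instability: str  # "all", "CIN" or "MSI"
    members: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _filter_samples(
    calls: ArmCallMatrix, metadata: pd.DataFrame | None, instability: str
) -> pd.Index:
    idx = calls.calls.index
    if metadata is not None:
        tumours = metadata.index[metadata.get("condition", "tumour") == "tumour"]
        idx = idx.intersection(tumours)
        if instability != "all":
            keep = metadata.index[metadata["instability"] == instability]
            idx = idx.intersection(keep)
    elif instability != "all":
        raise ConfigurationError("instability filtering requires sample metadata")
    return idx


def select_gain_group(
    calls: ArmCallMatrix,
    chromosome: str,
    mode: str,
    metadata: pd.DataFrame | None = None,
    instability: str = "all",
) -> GroupDefinition:
    """Members of the selected group for one chromosome and gain pattern."""
    if mode not in (WHOLE_GAIN, ISO_Q, ISO_P):
        raise ConfigurationError(f"invalid selection mode {mode!r}")
    regions = calls.catalog.regions_of(chromosome)
    region_ids = [r.region_id for r in regions]
    if mode in (ISO_Q, ISO_P):
        if calls.catalog.is_acrocentric(chromosome) or len(regions) != 2:
            raise ConfigurationError(
                f"isochromosome mode is undefined for single-region chromosome {chromosome}"
            )
    idx = _filter_samples(calls, metadata, instability)
    sub = calls.calls.loc[idx, region_ids]
    if mode == WHOLE_GAIN:
        mask = (sub == GAIN).all(axis=1)
        label = f"wChr{chromosome}-gain"
    else:
        p_id, q_id = region_ids
        if mode == ISO_Q:
            mask = (sub[p_id] == LOSS) & (sub[q_id] == GAIN)
            label = f"i({chromosome}q)"
        else:
            mask = (sub[p_id] == GAIN) & (sub[q_id] == LOSS)
            label = f"i({chromosome}p)"
    if instability != "all":
        label = f"{label}-{instability}"
    return GroupDefinition(
        group_id=label, mode=mode, chromosome=chromosome,
        instability=instability, members=list(sub.index[mask]),
    )


def select_control_group(
    calls: ArmCallMatrix,
    chromosome: str,
    metadata: pd.DataFrame | None = None,
    instability: str = "all",
) -> GroupDefinition:
    """Tumours with no arm-level CNA on any region of the chromosome."""
    region_ids = [r.region_id for r in calls.catalog.regions_of(chromosome)]
    idx = _filter_samples(calls, metadata, instability)
    sub = calls.calls.loc[idx, region_ids]
    mask = (sub == NEUTRAL).all(axis=1)
    label = f"Chr{chromosome}-control"
    if instability != "all":
        label = f"{label}-{instability}"
    group = GroupDefinition(
        group_id=label, mode=CONTROL, chromosome=chromosome,
        instability=instability, members=list(sub.index[mask]),
    )
    if len(group) == 0:
        warnings.warn(f"control group for chromosome {chromosome} is empty")
    return group


def profile_similarity(
    freq_a: pd.DataFrame,
    freq_b: pd.DataFrame,
    excluded_regions: list[str] | None = None,
) -> float:
    """Pearson r between two groups' aberration-frequency profiles.

    Both frames must carry ``gain_pct`` and ``loss_pct`` over the same
    region index.  Gain and loss entries of ``excluded_regions`` (normally
    the target chromosome's regions) are dropped before correlating the
    concatenated gain+loss vectors.
    """
    if not freq_a.index.equals(freq_b.index):
        raise ValueError("frequency tables cover different regions")
    excluded = set(excluded_regions or [])
    keep = [r for r in freq_a.index if r not in excluded]
    if len(keep) < 3:
        raise ValueError("need at least 3 retained regions for a correlation")
    va = np.concatenate([freq_a.loc[keep, "gain_pct"], freq_a.loc[keep, "loss_pct"]])
    vb = np.concatenate([freq_b.loc[keep, "gain_pct"], freq_b.loc[keep, "loss_pct"]])
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("correlation undefined for a constant frequency vector")
    return float(stats.pearsonr(va, vb).statistic)
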