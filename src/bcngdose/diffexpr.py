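"""Two-group differential expression for count data.

The engine normalizes libraries with the trimmed mean of M-values (TMM),
tests each transcript with an exact conditional negative-binomial test
using a per-transcript dispersion shrunk toward a common cohort estimate,
and adjusts p-values with the Benjamini-Hochberg step-up procedure.
Linear fold-changes below one are reported under the negative-reciprocal
convention (a ratio of 1/2 is reported as -2), so signed fold-changes
never fall strictly between -1 and 1.

TMM follows the published method: M- and A-values against a reference
sample (the one whose upper-quartile of library-size-normalized counts is
closest to the cohort mean), double trimming (30% on M, 5% on A by
default) and inverse-variance precision weights, with the resulting
factors rescaled to a unit geometric mean.

The exact test conditions on the total count of each transcript across
both groups after scaling all samples to a common effective library size;
the p-value sums the conditional probabilities of all outcomes no more
likely than the observed split.  Dispersions are estimated per transcript
by the method of moments on normalized counts and shrunk toward the
cohort median with a prior weight expressed in degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, rankdata


class DegenerateDataError(ValueError):
    """Raised for all-zero samples, undersized groups and similar defects."""


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float, weighted: bool
) -> float:
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if len(log_r) == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = len(log_r)
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM normalization factors with unit geometric mean."""
    if counts.shape[1] < 2:
        raise DegenerateDataError("TMM needs at least two samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0][0]
        raise DegenerateDataError(f"sample {bad} has zero library size")
    mat = counts.to_numpy(dtype=float)
    # reference: sample whose upper quartile (library-size scaled) is
    # closest to the mean upper quartile
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            factors[j] = _tmm_pair_factor(ref, ref, trim_m, trim_a, weighted)
        else:
            factors[j] = _tmm_pair_factor(mat[:, j], ref, trim_m, trim_a, weighted)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# fold-change conventions and multiplicity
# ---------------------------------------------------------------------------

def signed_linear_fc(log2fc):
    """Map log2 fold-changes to the signed linear reporting convention.

    ``2**log2fc`` if the linear ratio is at least 1, else the negative of
    its reciprocal, so a linear ratio of 1/2 is reported as -2 and no
    value falls strictly inside (-1, 1).
    """
    arr = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("signed_linear_fc requires finite input")
    linear = 2.0 ** arr
    out = np.where(linear >= 1.0, linear, -1.0 / linear)
    if np.isscalar(log2fc) or arr.ndim == 0:
        return float(out)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d array")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise KeyError(f"no length for transcript {missing}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for transcript {bad}")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    norm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: float = 20.0,
) -> pd.Series:
    """Moment-based per-transcript NB dispersions shrunk toward the median.

    ``norm`` holds counts scaled to a common library size.  The raw
    estimate solves ``var = mu + phi * mu**2`` with the pooled
    within-group variance; shrinkage combines it with the cohort median
    using ``prior_df`` pseudo-degrees of freedom.
    """
    ya = norm[group_a].to_numpy(dtype=float)
    yb = norm[group_b].to_numpy(dtype=float)
    na, nb_ = ya.shape[1], yb.shape[1]
    df = na + nb_ - 2
    if df <= 0:
        raise DegenerateDataError("dispersion estimation needs > 2 samples in total")
    ma = ya.mean(axis=1)
    mb = yb.mean(axis=1)
    ss = ((ya - ma[:, None]) ** 2).sum(axis=1) + ((yb - mb[:, None]) ** 2).sum(axis=1)
    var = ss / df
    mu = (ma * na + mb * nb_) / (na + nb_)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu) / mu**2
    raw = np.clip(np.nan_to_num(raw, nan=0.0), 1e-6, 10.0)
    informative = mu >= 1.0
    common = float(np.median(raw[informative])) if informative.any() else float(np.median(raw))
    shrunk = (prior_df * common + df * raw) / (prior_df + df)
    return pd.Series(np.clip(shrunk, 1e-6, 10.0), index=norm.index, name="dispersion")


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

def _exact_nb_pvalue(ya: int, yb: int, na: int, nb_: int, phi: float) -> float:
    """Conditional two-sided exact test of equal means given the total.

    Group totals are NB with sizes ``n/phi``; conditioning on the total
    removes the nuisance mean.  The p-value sums the conditional
    probabilities of every split no more likely than the observed one.
    """
    s = ya + yb
    if s == 0:
        return 1.0
    ra, rb = na / phi, nb_ / phi
    mu = s / (na + nb_)
    p = 1.0 / (1.0 + phi * mu)
    mean_a = s * na / (na + nb_)
    var_half = na * mu * (1.0 + phi * mu) / 2.0
    half_width = 20.0 * math.sqrt(var_half) + 10.0
    lo = max(0, int(mean_a - half_width))
    hi = min(s, int(mean_a + half_width) + 1)
    lo = min(lo, ya)
    hi = max(hi, ya)
    y = np.arange(lo, hi + 1)
    logp = nbinom.logpmf(y, ra, p) + nbinom.logpmf(s - y, rb, p)
    logp -= logsumexp(logp)
    pr = np.exp(logp)
    p_obs = pr[ya - lo]
    return float(min(1.0, pr[pr <= p_obs * (1.0 + 1e-10)].sum()))


# ---------------------------------------------------------------------------
# public test driver
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-transcript differential-expression table for one contrast."""

    contrast: str
    table: pd.DataFrame  # index transcript: mean_cpm, log2_fc, signed_fc, pvalue, fdr

    def __post_init__(self) -> None:
        required = {"mean_cpm", "log2_fc", "signed_fc", "pvalue", "fdr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")

    @property
    def transcripts(self) -> pd.Index:
        return self.table.index


@dataclass
class Contrast:
    name: str
    numerator: list[str]
    denominator: list[str]

    def validate(self) -> None:
        overlap = set(self.numerator) & set(self.denominator)
        if overlap:
            raise DegenerateDataError(
                f"contrast {self.name}: groups share samples {sorted(overlap)[:5]}"
            )
        if len(self.numerator) < 2 or len(self.denominator) < 2:
            raise DegenerateDataError(
                f"contrast {self.name}: both groups need at least 2 samples"
            )


@dataclass
class ContrastSet:
    """The four dosage-analysis contrasts.

    FC1: all tumours (selected + control) vs normals; FC2: selected vs
    control; FC3: control vs normals; FC4: selected vs normals.  The
    numerator of each contrast is the first-named group, so positive
    fold-changes mean higher expression there.
    """

    selected: list[str]
    control: list[str]
    normals: list[str]

    def __post_init__(self) -> None:
        if set(self.selected) & set(self.control):
            raise DegenerateDataError("selected and control groups overlap")
        tumours = set(self.selected) | set(self.control)
        if tumours & set(self.normals):
            raise DegenerateDataError("normal samples appear in a tumour group")

    def contrasts(self) -> dict[str, Contrast]:
        tumours = list(self.selected) + list(self.control)
        return {
            "FC1": Contrast("FC1", tumours, list(self.normals)),
            "FC2": Contrast("FC2", list(self.selected), list(self.control)),
            "FC3": Contrast("FC3", list(self.control), list(self.normals)),
            "FC4": Contrast("FC4", list(self.selected), list(self.normals)),
        }


def expression_filter(
    counts: pd.DataFrame, groups: list[list[str]], min_cpm: float = 1.0
) -> pd.Index:
    """Transcripts with CPM above ``min_cpm`` in at least min-group-size samples.

    Computed over the union of all group members so that every contrast
    built from these groups shares one transcript universe.
    """
    samples: list[str] = []
    for g in groups:
        samples.extend(s for s in g if s not in samples)
    sub = counts[samples]
    lib = sub.sum(axis=0)
    cpm = sub.div(lib, axis=1) * 1e6
    min_n = min(len(g) for g in groups)
    keep = (cpm > min_cpm).sum(axis=1) >= min_n
    return counts.index[keep]


def de_test(
    counts: pd.DataFrame,
    numerator: list[str],
    denominator: list[str],
    contrast: str = "FC",
    factors: pd.Series | None = None,
    dispersion: float | pd.Series | None = None,
    transcripts: pd.Index | None = None,
    min_cpm: float = 1.0,
    prior_df: float = 20.0,
    prior_count: float = 0.5,
) -> DEResult:
    """Exact-NB two-group test for every transcript passing the filter.

    ``transcripts`` pins the tested universe (e.g. a filter shared across
    contrasts); otherwise the CPM filter is applied to these two groups.
    ``dispersion`` may be a known scalar, a per-transcript series, or None
    to estimate from the data.  All-zero transcripts are excluded.
    """
    Contrast(contrast, list(numerator), list(denominator)).validate()
    samples = list(numerator) + list(denominator)
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise KeyError(f"samples absent from count matrix: {missing[:5]}")
    sub = counts[samples]
    if transcripts is not None:
        sub = sub.loc[transcripts]
    else:
        sub = sub.loc[expression_filter(sub, [list(numerator), list(denominator)], min_cpm)]
    nonzero = sub.sum(axis=1) > 0
    if (~nonzero).any():
        warnings.warn(f"excluding {(~nonzero).sum()} all-zero transcripts")
        sub = sub.loc[nonzero]
    if len(sub) == 0:
        raise DegenerateDataError("no transcripts left after filtering")

    if factors is None:
        factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors.reindex(sub.columns)
    common_scale = float(np.exp(np.mean(np.log(eff_lib))))
    norm = sub * (common_scale / eff_lib)

    if dispersion is None:
        phi = estimate_dispersions(norm, list(numerator), list(denominator), prior_df)
    elif np.isscalar(dispersion):
        phi = pd.Series(float(dispersion), index=norm.index)
    else:
        phi = dispersion.reindex(norm.index)

    na, nb_ = len(numerator), len(denominator)
    sum_a = norm[list(numerator)].sum(axis=1).round().astype(int)
    sum_b = norm[list(denominator)].sum(axis=1).round().astype(int)
    pvals = np.array([
        _exact_nb_pvalue(int(a), int(b), na, nb_, float(d))
        for a, b, d in zip(sum_a, sum_b, phi)
    ])

    mean_a = norm[list(numerator)].mean(axis=1)
    mean_b = norm[list(denominator)].mean(axis=1)
    log2_fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    table = pd.DataFrame(
        {
            "mean_cpm": norm.mean(axis=1) / common_scale * 1e6,
            "log2_fc": log2_fc,
            "signed_fc": signed_linear_fc(log2_fc.to_numpy()),
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
            "dispersion": phi,
        },
        index=sub.index,
    )
    return DEResult(contrast=contrast, table=table)


def run_contrasts(
    counts: pd.DataFrame,
    contrast_set: ContrastSet,
    min_cpm: float = 1.0,
    dispersion: float | None = None,
    prior_df: float = 20.0,
) -> dict[str, DEResult]:
    """Run FC1-FC4 on one shared transcript universe.

    The expression filter uses all four group sizes over the union of
    samples, so every contrast reports the same transcripts — a
    precondition of the transcript-class assignment.
    """
    cs = contrast_set.contrasts()
    groups = [contrast_set.selected, contrast_set.control, contrast_set.normals]
    universe = expression_filter(counts, groups, min_cpm)
    # keep the universe identical across contrasts: every group must carry signal
    for g in groups:
        universe = universe[counts.loc[universe, list(g)].sum(axis=1) > 0]
    results = {}
    for name, c in cs.items():
        c.validate()
        results[name] = de_test(
            counts, c.numerator, c.denominator, contrast=name,
            transcripts=universe, dispersion=dispersion, prior_df=prior_df,
        )
    return results
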