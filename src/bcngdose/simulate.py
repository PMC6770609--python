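"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a mixed CIN/MSI colorectal cohort profiled
by SNP arrays and RNA-seq: segmented copy-number profiles with recurrent
arm-level gains/losses and isochromosome patterns, negative-binomial counts
with tumour up/down-regulation, and a multiplicative copy-number dosage
effect ``(CN / 2) ** s`` whose sensitivity ``s`` differs between
up-regulated, down-regulated and unregulated transcripts.  Ground truth
(per-transcript regulation class and per-sample events) is emitted
alongside the data and is never consumed by the analysis pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .genome import RegionCatalog, build_genome_model

GAIN_CN = 3
LOSS_CN = 1
NEUTRAL_CN = 2

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "copy_number"]


@dataclass
class GroundTruth:
    """Generator-side truth: regulation classes, arm events, set membership."""

    transcripts: pd.DataFrame  # index transcript: regulation, dosage_exponent, baseline_mean
    events: pd.DataFrame       # sample, region, event in {gain, loss}
    gene_sets: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    catalog: RegionCatalog
    annotation: pd.DataFrame
    segments: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth

    @property
    def tumour_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["condition"] == "tumour"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["condition"] == "normal"])


def _sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_tumour):
        if i < config.n_cin:
            label = "CIN"
        elif i < config.n_cin + config.n_msi:
            label = "MSI"
        else:
            label = "other"
        rows.append({"sample": f"TUM{i:03d}", "condition": "tumour", "instability": label})
    for i in range(config.n_normal):
        rows.append({"sample": f"NRM{i:03d}", "condition": "normal", "instability": "none"})
    return pd.DataFrame(rows).set_index("sample")


def simulate_cna_profiles(
    config: SimulationConfig,
    catalog: RegionCatalog,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-sample arm events and render them as segmented profiles.

    Per chromosome, events are drawn in precedence order: a
    whole-chromosome gain, else an isochromosome (p-loss + q-gain), else
    each region independently gains or loses with its configured
    frequency.
    MSI tumours draw events at ``msi_event_scale`` times the configured
    frequencies, emulating their near-normal karyotypes.  Each event is
    rendered as one aberrant segment covering >50% of the region (uniform
    60-100% coverage); untouched stretches are emitted at CN=2, so normal
    samples carry flat disomic profiles.

    Returns ``(segments, events, metadata)``.
    """
    config.validate()
    metadata = _sample_metadata(config)
    seg_rows: list[tuple] = []
    event_rows: list[tuple] = []

    def render_event(sample: str, region, cn: int) -> None:
        frac = rng.uniform(0.6, 1.0)
        length = int(round(frac * region.length))
        length = max(length, region.length // 2 + 1)  # guarantee >50%
        offset = int(rng.random() * (region.length - length))
        s, e = region.start + offset, region.start + offset + length
        if s > region.start:
            seg_rows.append((sample, region.chromosome, region.start, s, NEUTRAL_CN))
        seg_rows.append((sample, region.chromosome, s, e, cn))
        if e < region.end:
            seg_rows.append((sample, region.chromosome, e, region.end, NEUTRAL_CN))

    for sample, row in metadata.iterrows():
        if row["condition"] == "normal":
            for chrom in catalog.chromosomes:
                rs = catalog.regions_of(chrom)
                seg_rows.append((sample, chrom, rs[0].start, rs[-1].end, NEUTRAL_CN))
            continue
        scale = config.msi_event_scale if row["instability"] == "MSI" else 1.0
        for chrom in catalog.chromosomes:
            regions = catalog.regions_of(chrom)
            whole_p = config.per_chromosome_whole_gain_freq.get(chrom, 0.0) * scale
            if rng.random() < whole_p:
                for region in regions:
                    render_event(sample, region, GAIN_CN)
                    event_rows.append((sample, region.region_id, "gain"))
                continue
            iso_p = config.iso_freq.get(chrom, 0.0) * scale
            if len(regions) == 2 and rng.random() < iso_p:
                p_arm, q_arm = regions
                render_event(sample, p_arm, LOSS_CN)
                render_event(sample, q_arm, GAIN_CN)
                event_rows.append((sample, p_arm.region_id, "loss"))
                event_rows.append((sample, q_arm.region_id, "gain"))
                continue
            for region in regions:
                u = rng.random()
                g = config.gain_freq(region.region_id) * scale
                l = config.loss_freq(region.region_id) * scale
                if u < g:
                    render_event(sample, region, GAIN_CN)
                    event_rows.append((sample, region.region_id, "gain"))
                elif u < g + l:
                    render_event(sample, region, LOSS_CN)
                    event_rows.append((sample, region.region_id, "loss"))
                else:
                    seg_rows.append((sample, region.chromosome, region.start, region.end, NEUTRAL_CN))
    segments = pd.DataFrame(seg_rows, columns=SEG_COLUMNS)
    events = pd.DataFrame(event_rows, columns=["sample", "region", "event"])
    return segments, events, metadata


def assign_regulation(
    config: SimulationConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-transcript regulation class, dosage exponent and baseline mean."""
    n = len(annotation)
    classes = rng.choice(
        np.array(["up", "down", "null"]),
        size=n,
        p=[config.frac_upregulated, config.frac_downregulated,
           1.0 - config.frac_upregulated - config.frac_downregulated],
    )
    exponent = np.where(
        classes == "up", config.dosage_exponent_up,
        np.where(classes == "down", config.dosage_exponent_down, config.dosage_exponent_null),
    )
    baseline = np.exp(rng.normal(config.mean_log_expression, config.sd_log_expression, size=n))
    return pd.DataFrame(
        {"regulation": classes, "dosage_exponent": exponent, "baseline_mean": baseline},
        index=annotation.index,
    )


def copy_number_matrix(
    events: pd.DataFrame, metadata: pd.DataFrame, catalog: RegionCatalog
) -> pd.DataFrame:
    """Samples x regions integer CN implied by the ground-truth events."""
    cn = pd.DataFrame(NEUTRAL_CN, index=metadata.index, columns=catalog.region_ids, dtype=int)
    for row in events.itertuples():
        cn.loc[row.sample, row.region] = GAIN_CN if row.event == "gain" else LOSS_CN
    return cn


def simulate_counts(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    events: pd.DataFrame,
    metadata: pd.DataFrame,
    truth_transcripts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the raw count matrix (transcripts x samples).

    Expected counts follow ``mu = baseline * tumour_effect * (CN/2)**s *
    library_factor`` and are drawn from a negative binomial with variance
    ``mu + nb_dispersion * mu**2``.
    """
    missing = annotation.index.difference(truth_transcripts.index)
    if len(missing):
        raise ConfigurationError(f"truth missing {len(missing)} transcripts (e.g. {missing[0]})")
    cn = copy_number_matrix(events, metadata, config_catalog(config, annotation))
    samples = list(metadata.index)
    is_tumour = (metadata["condition"] == "tumour").to_numpy()
    lib = rng.lognormal(0.0, config.library_size_sd, size=len(samples))

    baseline = truth_transcripts.loc[annotation.index, "baseline_mean"].to_numpy()
    exponent = truth_transcripts.loc[annotation.index, "dosage_exponent"].to_numpy()
    regulation = truth_transcripts.loc[annotation.index, "regulation"].to_numpy()
    tumour_factor = np.where(
        regulation == "up", config.tumour_effect_fc,
        np.where(regulation == "down", 1.0 / config.tumour_effect_fc, 1.0),
    )
    region_of = annotation["region"].to_numpy()
    cn_sub = cn.loc[samples, :]
    # CN per transcript x sample
    cn_mat = cn_sub.T.reindex(region_of).to_numpy()  # transcripts x samples
    dosage = (cn_mat / 2.0) ** exponent[:, None]
    effect = np.where(is_tumour[None, :], tumour_factor[:, None] * dosage, 1.0)
    mu = baseline[:, None] * effect * lib[None, :]
    phi = config.nb_dispersion
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    return pd.DataFrame(counts, index=annotation.index, columns=samples)


def config_catalog(config: SimulationConfig, annotation: pd.DataFrame) -> RegionCatalog:
    """Catalog consistent with the config layout (helper for CN expansion)."""
    return RegionCatalog.from_layout(config.region_layout)


GENE_SET_NAMES = ("fitness_t", "gained_vel_t", "amp_t")


def make_gene_sets(
    config: SimulationConfig,
    truth_transcripts: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Draw synthetic fitness / gained-VEL / focal-amplification gene sets.

    Each set samples ``geneset_size`` transcripts without replacement with
    dosage-sensitive up-regulated transcripts over-weighted by
    ``geneset_enrichment_factor``; a factor of 1 makes membership
    independent of the truth.
    """
    if config.geneset_enrichment_factor < 1.0:
        raise ConfigurationError("geneset_enrichment_factor must be >= 1")
    pool = truth_transcripts.index.to_numpy()
    if len(pool) == 0:
        warnings.warn("empty candidate pool: emitting empty gene sets")
        return {name: [] for name in GENE_SET_NAMES}
    weights = np.where(
        truth_transcripts["regulation"].to_numpy() == "up",
        config.geneset_enrichment_factor,
        1.0,
    )
    probs = weights / weights.sum()
    size = min(config.geneset_size, len(pool))
    sets = {}
    for name in GENE_SET_NAMES:
        members = rng.choice(pool, size=size, replace=False, p=probs)
        sets[name] = sorted(str(t) for t in members)
    return sets


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run the full generator from one seed: genome, CN, counts, gene sets."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog, annotation = build_genome_model(config, rng)
    segments, events, metadata = simulate_cna_profiles(config, catalog, rng)
    truth_transcripts = assign_regulation(config, annotation, rng)
    counts = simulate_counts(config, annotation, events, metadata, truth_transcripts, rng)
    gene_sets = make_gene_sets(config, truth_transcripts, rng)
    truth = GroundTruth(transcripts=truth_transcripts, events=events, gene_sets=gene_sets)
    return SyntheticCohort(
        config=config,
        catalog=catalog,
        annotation=annotation,
        segments=segments,
        counts=counts,
        metadata=metadata,
        truth=truth,
    )
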