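# Methods

This note documents the models, estimators and design choices behind
`bcngdose`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Genome partition

All per-region statistics run over a `RegionCatalog` partitioning the
genome into chromosomal regions. The default `human-42` layout has 42
regions: p and q arms of the 17 non-acrocentric autosomes (34), the five
acrocentric autosomes 13, 14, 15, 21 and 22 as single regions, Xp, Xq and
Y. Coordinates are 0-based half-open with approximate megabase-scale arm
lengths; only relative lengths matter to the >50% calling rule. The exact
composition of a 42-region human partition is not uniquely determined
(sex-chromosome handling in particular), so the layout is configurable:
`toy-N` layouts build N synthetic regions for testing, and any catalog can
be supplied as a TSV.

## Arm-level calling

For each region the caller computes the fraction of bases covered by
segments with copy number above (below) the cohort ploidy, default 2. A
region is gained (lost) when that fraction **strictly exceeds** 0.5;
exactly 50% is neutral. Unsegmented gaps count as neutral bases, which is
conservative: gaps dilute the aberrant fraction. Gained and lost fractions
of one region sum to at most 1, so the two calls are mutually exclusive by
construction. No tumour-ploidy re-centering is attempted; the comparison is
against a fixed integer ploidy. Mixed arms (e.g. 40% gained plus 40% lost)
yield neutral because neither fraction passes 0.5.

Isochromosome flags are purely operational: i(Nq) means the p arm is
called lost and the q arm gained on chromosome N (i(Np) is the mirror);
single-region chromosomes never carry the flag. Karyotype classes count
non-neutral calls: 0 = normal, 1–2 = near-normal, >2 = aberrant.

## Group construction

A selected group collects tumours whose calls match a gain pattern on the
target chromosome (`whole-gain`: every region gained; `iso-q`/`iso-p`: the
isochromosome patterns). The control group requires *every* region of the
target chromosome to be neutral — an isochromosome on the target therefore
excludes a sample from the control, as does any single-arm event.
Instability filtering (CIN/MSI) is applied from the metadata before
selection; instability labels are consumed as given, never recomputed.

Profile similarity between two groups is the Pearson correlation of their
concatenated per-region gain% and loss% vectors. Both the gain and the
loss entries of the target chromosome's regions are dropped first: the
gain side is structurally forced (0% in controls, 100% in the selected
group), and keeping the loss side would leave a mirrored artifact for
isochromosome groups.

## Expression model and differential testing

Counts are TMM-normalized: M- and A-values against a reference sample
(the column whose upper quartile of library-normalized counts is closest
to the cohort mean), 30% two-sided trimming on M and 5% on A, optional
inverse-variance precision weights, factors rescaled to unit geometric
mean. These are the published defaults of the trimmed-mean-of-M-values
method; the unit test freezes factors independently computed by the
R/Bioconductor reference implementation on a fixture matrix. Note that
with precision weights TMM is only approximately invariant to pure
library-size scaling (the weights depend on depth); the unweighted
variant is exactly invariant.

The two-group test is an exact conditional negative-binomial test. After
scaling all samples to a common effective library size, the two group
totals are treated as NB with shape `n_g / phi`; conditioning on their sum
removes the nuisance mean, and the p-value sums the conditional
probabilities of every split no more likely than the observed one. The
enumeration window is the conditional mean ±20 conditional standard
deviations (always extended to include the observed total), which keeps
the truncated mass far below double precision.

Dispersions are estimated per transcript by the method of moments on
normalized counts (`var = mu + phi mu^2`, pooled within-group variance,
clipped to `[1e-6, 10]`) and shrunk toward the cohort median with a prior
weight of 20 pseudo-degrees of freedom. With 15 vs 15 samples and 2000
null transcripts, the empirical rejection rate at alpha in {0.01, 0.05}
sits within 3 Monte-Carlo standard errors of alpha, and the p-value
distribution passes a Kolmogorov–Smirnov uniformity check at alpha = 0.01
(both asserted in the suite).

Transcripts enter testing when their counts-per-million exceed 1 in at
least min-group-size samples; when the four contrasts are run together the
filter is computed once over the union of samples (and every group must
carry non-zero totals), so all four share one transcript universe — a
precondition of the taxonomy. All-zero transcripts are excluded with a
warning. Fold-changes are `log2((mean_a + 0.5) / (mean_b + 0.5))` on
normalized counts; linear folds below 1 are reported as the negative
reciprocal, so no signed fold lies strictly inside (−1, 1).

Benjamini–Hochberg adjustment is the standard step-up rule (monotone,
capped at 1, stable under ties); a property test checks it against an
independent implementation on random p-vectors. TPM is
`count/length / Σ(count/length) × 1e6` per sample.

## Transcript taxonomy

Variable transcripts (VT) have FDR < 0.05 in a given contrast (threshold
configurable). Overexpression (OverT) requires **both** VT status in the
FC2 contrast and linear FC2 > 1.3: the significance requirement refers to
the same comparison the fold-change comes from. Over-PositiveT and
Over-NegativeT add only sign conditions on FC3 and FC4 (no extra
significance), matching the three-circle Venn construction
({FC2 > 1.3} ∩ {FC3 > 1} ∩ {FC4 > 1}). Group-level PositiveT/NegativeT —
used as annotated classes in the enrichment grid — do require VT status in
both FC3 and FC4, since each of those classes is defined through its own
significant contrast. Cohort-level PositiveT/NegativeT come from FC1.
"FC < 1" is evaluated internally as "signed FC < 0". The biotype partition
(protein-coding / lincRNA / non-coding) excludes TEC and not-assessed
entries; unknown labels route to non-coding with a warning.

## NCDI

For class density `d_n = x_n / X_n`, `NCDI_n = d_n / Σ d_i × 100`. Regions
with `X_n = 0` (possible on toy genomes or heavily filtered universes) are
dropped with a warning and T reduced, preserving the sum-to-100 invariant.
NCDI is density-weighted, not count-weighted, so it is deliberately *not*
consistent under region merging; this is documented rather than asserted.
When computed over a tested universe (the usual case downstream of DE),
`X_n` counts tested transcripts, not all annotated ones.

TPM-binned NCDI summarizes each transcript by its mean (configurable to
median) TPM over the selected group's samples, splits the universe into
half-open bins `[lo, hi)` (defaults `0, 1, 4, 16, 64, 256, inf` — the
exact edges are user-configurable since no canonical set exists), and
recomputes the NCDI of the requested region within each bin. Empty bins
yield NaN; populated bins without class members yield 0. At desk-scale
cohort sizes the Over-NegativeT class is typically near-empty, so only the
qualitative OverT-above-Over-NegativeT ordering is meaningful, and only on
larger simulations.

## Enrichment

Each cell of the enrichment grid restricts the universe to one region's
transcripts and tests the query (OverT) against an annotated class with a
one-sided hypergeometric tail chosen by the observed overlap versus its
expectation `nK/N`: `P(X >= k)` for enrichment, `P(X <= k)` for depletion.
Folds below 1 are signed-negative (0.5 → −2; a zero overlap gives −inf).
Cells with an empty annotated set or query in the region are marked NC
(not computable) rather than erroring. The universe defaults to
tested-only transcripts, since untested transcripts can be neither VT nor
OverT; an all-annotated universe can be supplied explicitly. Note the
direction-adaptive report does not control the null rejection rate at
alpha (it can reach 2*alpha); the fixed single tail does, as the suite
verifies. No multiplicity correction is applied across grid cells — the
grid reports raw hypergeometric p-values.

## Synthetic cohort generator

The generator emulates the structure of a mixed CIN/MSI colorectal cohort
profiled by SNP arrays and RNA-seq. Per tumour and chromosome, copy-number
events are drawn in precedence order: whole-chromosome gain, else
isochromosome (p-loss + q-gain), else independent per-region gains/losses.
MSI tumours draw at `msi_event_scale` (default 0.15) times the configured
frequencies, reproducing their near-normal karyotypes. Each event renders
one segment covering 60–100% of the region (always >50%, so the caller
must recover it) at CN 3 (gain) or 1 (loss); untouched stretches are
emitted at CN 2. Default frequencies follow the recurrent colorectal
pattern: whole-gains of chromosomes 20, 7 and 8, arm gains of 20q, 13 and
8q, isochromosomes of 8, 20, 17, 1 and 5, and broad losses of 18, 8p, 17p,
14, 15, 4, 21, 22 and 1p, over a 5% background.

Expression: baseline means are log-normal (`exp(N(4, 1.2^2))`, i.e. a
median of ~55 counts); a fraction of transcripts (15% each by default) is
up- or down-regulated in tumours by a symmetric factor (default 2); the
dosage effect multiplies the expected mean by `(CN/2)^s`. The sensitivity
exponent is class-specific: `s_up = 0.9`, `s_down = 0.25`, `s_null = 0.55`
by default. The null value satisfies `(3/2)^0.55 ≈ 1.25`, the middle of
the 1.2–1.3 fold range commonly reported for trisomic transcription, and
the up/down split encodes the differential dosage susceptibility the
pipeline is designed to detect. Counts are negative binomial with
dispersion 0.1 and log-normal library-size factors (sd 0.15 on the log
scale). Default cohort composition scales the real study down roughly
four-fold: 120 tumours (62 CIN, 17 MSI, the rest unlabelled) and 41
normals, 40 transcripts per region (1680 genome-wide).

Synthetic gene sets (fitness, gained-VEL targets, focal amplification)
sample transcripts without replacement with up-regulated transcripts
over-weighted by `geneset_enrichment_factor` (default 3). The measured
fold-enrichment of a set among up-regulated transcripts approaches the
factor only when the up-regulated fraction is small (the weighted odds
saturate otherwise); the recovery test therefore uses a 2% fraction.

Determinism: one `numpy` generator stream seeded from the single config
seed drives genome construction, CN events, regulation assignment, counts
and gene-set draws in a fixed order, so identical configs reproduce
byte-identical outputs. Ground truth is emitted alongside the data (under
`truth/` in pipeline runs) and never consumed by any analysis stage.

### What the generator does not emulate

Focal/subclonal/allele-specific copy number, correlated co-occurrence of
events beyond the whole-gain and isochromosome patterns, GC or length
biases in counts, batch effects, tumour purity, and any spatial clustering
of regulated genes within regions. Passing tests therefore demonstrate
statistical correctness and recovery of the modelled effects, not
robustness to artefacts absent from the model.

## Test problem sizes

The suite sizes its simulations for a single CPU: calibration uses 2000
transcripts at 15 vs 15 samples; dosage recovery uses the 42-region layout
with 25 transcripts per region and 60 tumours; the caricature property
uses a 5-region toy layout with 1000 transcripts, 70 tumours and 5 seeds;
the hypergeometric oracle enumerates every universe up to N = 12 with
exact fraction arithmetic. The full run takes under two minutes.
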