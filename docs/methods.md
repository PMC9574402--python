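# Methods

This note documents the quantitative model behind `apmsquant`, the
parameters that matter, the synthetic-data generator used for validation,
and the numerical and design choices made where the underlying methodology
leaves room.

## Quantification: spectral index normalized to global intensity

The pipeline's unit of evidence is the PSM (peptide-spectrum match). The
per-protein *raw spectral index* in a run is the sum of the intensities of
the PSMs assigned to that protein; dividing by the run total over all
detected proteins gives SI_GI, a composition in [0, 1] whose values sum to
1 per run. Two consequences shape everything downstream:

* **Scale invariance.** Multiplying every intensity in a run by any c > 0
  leaves SI_GI unchanged, so total ion current and injection amount cancel.
* **Compositional closure.** A protein can only gain share at the expense
  of others. A strong specific pull-down therefore *depletes* the
  background in bait runs relative to IgG controls, and a two-tailed test
  will flag those depletions as significant. The enrichment table exposes
  both the plain `significant` flag (p < α, either direction) and an
  `enriched` flag (significant with t > 0) for analyses that mean
  "elevated in the bait purification".

The `intensity` column is taken as supplied. When built from real search
results it should be the summed fragment-ion intensity of the matched MS2
spectrum, the primitive the spectral-index family of label-free measures is
defined over; the contract, and the simulator, operate on the supplied
column either way. A PSM maps to exactly one protein — the pipeline never
splits or duplicates intensity across shared peptides, which keeps the
sum-to-one invariant exact. Proteins whose PSMs all have zero intensity
count as *detected* with SI_GI 0: detection (presence in the run) and
abundance are distinct concepts, and the detected-in-all-replicates filter
uses the former.

## Enrichment testing

Per protein seen in ≥ 1 bait replicate: Welch's unequal-variance t-test of
the n bait SI_GI values against the m control values,

t = (x̄ − ȳ) / √(s²x/n + s²y/m),

with Welch–Satterthwaite degrees of freedom and a two-tailed p from
Student's t. Undetected entries are zero-filled by default so both group
vectors have full length — in a composition, absence is informative, and
zero-filling reproduces the way replicate means are reported when a protein
appears in only some replicates (e.g. a mean like 0.00003 ± 0.00003 over
n = 5). Pairwise deletion is available (`zero_fill=False`); groups left
with fewer than two detected values are then flagged degenerate, never
significant. When one sample variance is zero the Welch formula applies
unchanged (df collapses to n − 1); when both are zero the test is
degenerate: p is NaN, not 0, and the protein cannot be significant.

Defaults: α = 0.05, two-tailed, raw per-protein p-values with no
multiple-testing correction — the convention of the AP-MS studies this
pipeline targets, where the IgG contrast plus the detected-in-all filter
carry the specificity burden. Benjamini–Hochberg adjustment of the
significance calls is available via `EnrichConfig(multiple_testing="fdr_bh")`.

At the defaults, the measured type-I error of the full
simulate → quantify → test path under a null design (identical bait and
control distributions, 5 vs 5 replicates) is ≈ 0.043–0.045 against the
nominal 0.05 — Welch is mildly conservative at n = 5 on skewed intensity
sums.

## Stoichiometry and composition summaries

Class fractions (e.g. each α-isoform's share of total α-subunit signal) are
ratios of summed mean SI_GI over the selected records. The denominator is
restricted to *significant* records by default, which is what makes the
printed per-isoform percentages total 100: shares are claims about the
isoforms credibly present, not about every trace detection. Pie summaries
sort fractions descending and merge slices below `other_threshold`
(default 0.02) into a trailing "Other" bucket; with threshold 0 the pie
reproduces the plain composition.

Between-purification comparisons (bait recovery, occupancy differences) use
the pooled-variance unpaired Student's t-test, not Welch — matching the
statistics convention such studies apply outside the proteome-wide screen —
and accept printed summaries (mean, SEM, n) directly, recovering the sample
variance as s² = n·SEM². The summary-statistic path and the
replicate-vector path agree to machine precision. Means and SEMs are kept
at full precision internally; rounding is a display concern, and the note
below on printed-value checks quantifies what rounding does.

## Phosphosite occupancy

Localized phospho modifications (`phospho@offset`, 1-based within the
peptide) are projected to reference coordinates: residue = peptide start +
offset − 1. Peptides that occur more than once in their protein are
excluded with a warning rather than guessed. Occupancy of a site in a run
is n_phos / n_total, where n_total counts every PSM of the protein whose
peptide covers the residue and n_phos those carrying a phospho at exactly
that residue; a PSM phosphorylated elsewhere counts as dephosphorylated
here. Sites with no covering PSMs are reported *not covered*, not 0 — a
site can be genuinely absent from one receptor subtype's data.

Counting is PSM-level by default (each spectrum counts once);
distinct-peptide counting (`count_mode="peptide"`) is exposed because the
underlying "ratio of phosphorylated to dephosphorylated peptides" idea can
be read either way. The estimator is the per-run binomial proportion; with
C covering PSMs its standard error is √(θ(1−θ)/C), and the acceptance
checks verify the mean absolute error stays below twice that bound at
C = 200. Phospho-localization scoring is out of scope: inputs are assumed
site-localized.

## Network and PCA

Network nodes are the records passing the triple filter — significant,
detected in all bait replicates, and mean SI_GI strictly greater than
`node_threshold` (default 5·10⁻⁴; a record at exactly the threshold is
excluded). Edges come from a local interaction snapshot (TSV: protein_a,
protein_b, score) restricted to node pairs, undirected, self-edges dropped,
duplicates collapsed keeping the best score; nodes carry their mean SI_GI
(node size is a presentation concern) and the top GO term from a local
annotation snapshot. Live database queries are deliberately absent:
snapshots make runs reproducible and offline-testable, at the cost of
making snapshot versioning the caller's responsibility.

The replicate PCA standardizes each feature column (protein) to zero mean
and unit sample variance (ddof = 1) over the selected runs — undetected
entries enter as 0 before the z-transform, consistent with zero-filling in
the tests — then decomposes the standardized matrix by SVD, i.e. the
eigen-structure of the feature correlation matrix. Zero-variance features
are dropped with a warning (a protein absent or constant everywhere is
uninformative), and each component's sign is fixed by making its
largest-magnitude loading positive, so scores are deterministic across
linear-algebra backends. Feature sets default to the union of each
purification's significant, all-replicate proteins, with zero-fill for runs
where a feature was never seen.

## Synthetic experiments

The generator emulates the targeted study design: `n_bait_runs = 5` bait-IP
and `n_control_runs = 5` IgG-control replicates per purification; a bait
receptor complex with graded member weights (defaults follow a native
GABA_A-receptor α1 purification profile — one dominant subunit, partners at
2–90× lower weight, against a background baseline of 1); 30 specific
interactors with fold-enrichments log-spaced 2–50× over background (absent
from controls by default); 100 nonspecific background proteins with
per-protein log-normal weights (σ = 1) shared by both conditions.

Per run, each non-dropped protein receives Poisson(`psms_per_protein`,
default 10) PSMs; each PSM's intensity is weight × LogNormal(0, σ) with
σ = 0.3, the heavy-tailed noise standard for MS intensities. Dropout is an
independent per-protein per-run Bernoulli event (default 0.05); an
abundance-dependent variant (failure probability scaled by
baseline/abundance) is exposed as an option but off by default — the
independent mechanism is the simplest one that makes the
detected-in-all-replicates filter meaningful, and its consequences are
exact: a protein survives all five bait runs with probability 0.95⁵ ≈ 0.774,
which caps the sensitivity of any "significant AND detected in all
replicates" call at ≈ 0.77 under these conditions even when the test itself
has essentially full power (significance-only sensitivity for 5×
interactors measures ≈ 0.97). Peptides are fixed-length (12-mer) windows
over per-protein random sequences (length 120), unique to their protein
with overwhelming probability; planted phosphosites force their residue
letter and phosphorylate covering PSMs with per-PSM probability equal to
the configured occupancy. `count_model="fixed"` replaces Poisson counts
with exactly round(rate) PSMs for noise-free fixtures.

Randomness is reproducible by construction: one stream per run derived from
(seed, blake2s(run_id)), plus one structural stream for sequences and
background weights, so identical configs are byte-identical on disk and
adding runs never perturbs existing ones.

What the simulator does **not** model — and hence what passing tests do not
certify about real data: search-engine misidentifications and decoy
statistics, shared/degenerate peptides, correlated (batch) intensity drift,
abundance-dependent MS1 sampling, chromatographic effects, phospho
mis-localization, and contaminant structure beyond exchangeable log-normal
background. Results on real PSM tables inherit whatever upstream search
quality provides.

## Checks against printed values

Two closed-form checks run against published summary numbers of the kind of
study the pipeline targets, using the printed (rounded) values as inputs:
the pooled t-test on two purifications' printed mean ± SEM
(0.0087 ± 0.0009 vs 0.0046 ± 0.0011, n = 5) gives p ≈ 0.0204 against the
reported 0.0211 — the gap is exactly what 2-significant-figure rounding of
the inputs produces; and α-isoform shares recomputed from printed
per-subunit means (0.0087 / 0.0003 / 0.0007) give 89.7 / 3.1 / 7.2%
against reported 88.28 / 3.82 / 7.90% computed from unrounded replicate
data, a ~1–2 point rounding discrepancy. These tolerances are statements
about input rounding, not about the arithmetic, which is exact.

## Problem sizes

Validation workloads are sized to run comfortably on one CPU: the null
calibration uses 500 simulated experiments of 200 background proteins;
recovery uses 100 seeds of 20 interactors over 50 background proteins;
occupancy recovery uses 100 seeds × 4 occupancies at 200 covering PSMs per
run; the oracle-agreement check uses 1,000 random group pairs. The full
suite runs in about a minute; `scripts/acceptance.py` likewise.

## Known limitations

* Intensity semantics are delegated to the input; no recalibration,
  retention-time alignment, or match-between-runs.
* Single-protein PSM assignment is an input responsibility; tables with
  shared peptides should be resolved upstream.
* The two-tailed `significant` flag includes compositional depletions; use
  `enriched` when "elevated in bait" is meant.
* Occupancy comparisons assume per-run proportions are approximately
  normal; at very low coverage (a handful of covering PSMs) the t-test on
  proportions is coarse.
* No SAINT-style probabilistic interactome scoring or CRAPome-style
  contaminant priors; specificity rests on the IgG contrast and the
  detection filter.
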