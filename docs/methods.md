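# Methods

## Model and orientation

Both experiments measure one biological contrast — the two alleles of the
introgressed chromosome 4 interval — from opposite strain backgrounds:
experiment A compares the iP background strain with the P.NP congenic
(8 animals per group), experiment B the NP.P congenic with the iNP background
(6 per group). All differences and ratios in this package are oriented
**iP-allele-carrier minus/over iNP-allele-carrier**, so a positive value
always means higher expression with the iP interval regardless of which
strain was congenic. Published-style ratios computed in the opposite
orientation are re-oriented by signed-ratio inversion (s → −s; ±1 is a fixed
point, since a ratio of exactly 1 has no direction).

Signed fold changes follow the symmetric convention s = 2^Δ for Δ ≥ 0 and
s = −2^|Δ| for Δ < 0, so |s| ≥ 1 always and s and its inverse-orientation
counterpart differ only in sign. `to_log2` inverts it exactly; values in
(−1, 1) are rejected as convention violations rather than silently rescaled.

## Locus classification

Coordinates are 1-based and inclusive on both ends; the default interval is
chromosome 4, 29,413,686–128,186,835 bp (the markers flanking the
introgressed segment). A probe set is represented by a single anchor
position; probe sets without placement (e.g. ESTs aligning to multiple loci)
are *unplaced* and excluded from both testing universes, because they cannot
be assigned to either multiple-testing family. Chromosome labels are
compared case-insensitively with an optional `chr` prefix stripped.

## Detection filtering

Detection calls are consumed, never computed (the upstream present/absent
algorithm is a platform step outside this package's scope). The retention
rule is at least one third of arrays called present in at least one group —
within the region under analysis for regional tests, or in at least one
(region × group) cell for the combined analysis. The fraction comparison
carries a 1e-12 epsilon so exact boundary counts (2 of 6 arrays) are
retained. A matrix without detection calls runs with filtering disabled and
a logged warning; the command-line `analyze` front-end instead refuses,
requiring an explicit `--no-detection-filter`, so a silently missing file
cannot change the analyzed universe.

## Differential testing

The combined context averages each animal's log2 values across the five
regions (arithmetic mean on the log2 scale, i.e. geometric mean of linear
values), gaining power for effects shared in direction across regions.

Three tests are offered. `student` and `welch` delegate to the standard
pooled- and unequal-variance two-sample t-tests. The default `moderated`
test shrinks each probe set's pooled variance toward a common prior using a
scaled-inverse-χ²(d₀, s₀²) model estimated by moment matching on the log
sample variances: with z = log s², E[z] and Var[z] have digamma/trigamma
closed forms, so d₀ solves ψ′(d₀/2) = Var(z) − ψ′(d/2) (Newton inversion of
the trigamma) and s₀² follows from the mean equation. The statistic is
Δ̄ / (s̃·√(1/n₁+1/n₂)) with s̃² = (d₀s₀² + d·s²)/(d₀+d) on d₀ + d degrees of
freedom. When the observed spread of log variances is no larger than pure
sampling noise the moment equations have no finite d₀ and the implementation
falls back to the ordinary student test on the same data — which also
realizes the exact-equal-variances limit. (The reference empirical-Bayes
implementation instead reports d₀ = ∞ with the common variance; the
difference arises only in that degenerate regime. Away from it the two agree
to numerical precision, which one test verifies against the Bioconductor
implementation through Rscript on a small simulated matrix.)

Degenerate inputs follow fixed conventions: both groups constant and equal
→ t = 0, p = 1; constant but unequal → p = 0 under the pooled test and a
validation error under Welch (its df is undefined); groups of fewer than two
samples are rejected.

Benjamini–Hochberg adjustment is applied separately per (locus class ×
context) family, after detection filtering — the in-interval universe is two
orders of magnitude smaller than the rest-of-genome universe, and pooling
them would let the genome-wide family dominate the interval's adjusted
values. Single-experiment significance is q ≤ 0.25.

## Concordance selection

A context (one region, or combined) qualifies for a probe set iff **both**
experiments are significant there at raw p ≤ α (default 0.05) **and** the
two oriented ratios share a defined sign in that same context; a probe set
is selected iff at least one context qualifies. Raw p-values are
deliberately used here — the cross-experiment replication requirement,
not the per-test threshold, controls false positives (per-context null
qualification probability ≤ α², halved again by the sign condition).
Direction consistency is evaluated within the qualifying context, not
across all contexts. Pairs with a missing ratio, or a ratio of exactly ±1
(zero log2 difference, direction undefined), are excluded pairwise from
agreement counts and correlations. R² is the squared Pearson correlation of
the two log2-ratio vectors, computed over all complete combined-context
pairs, including direction-discordant ones.

The packaged candidate fixture (74 probe sets × 6 contexts) stores the
published per-context significance marks as boolean flags; `select_concordant`
accepts either raw p-values or such flags.

## Probe-level SNP screen

Probe intensities are averaged within animal across regions exactly as probe
sets are. Per probe, d_p = mean(iP-carriers) − mean(iNP-carriers); the probe
set's overall differential expression is ascertained as the **median** of its
probes' d_p (median centering — the reference cannot be dragged by the very
outlier being sought; mean centering is available behind a switch), the
residual is e_p = d_p − center, and the robust z is e_p over
1.4826 × median|e|. A probe is flagged iff |z| > 3 **and** |e_p| ≥ 0.5 log2;
the absolute floor prevents flagging trivial deviations in probe sets with
near-zero scatter, where the MAD denominator alone would be hair-trigger.
Probe sets with fewer than 4 probes cannot support a meaningful robust scale
and are emitted with the flag left missing, under a logged warning. A zero
robust scale with all-zero residuals produces no flags.

At the study's design (8v8 animals, 11 probes per set, residual σ = 0.2
log2, injected offset 2.0), the simulated operating point is sensitivity
≈ 100% with a false-flag rate ≈ 0 (bounds ≥ 95% and ≤ 1% are asserted over
600 simulated probe sets).

## Synthetic data: what it emulates, and what it does not

The generator draws value(g, i, r) = baseline_g + region_offset_r +
animal_i + allele_effect + noise on the log2 scale, with the allele effect
δ_g **identical** in both experiments — the biological premise of the
reciprocal design (both congenics segregate the same two alleles). Defaults
are the study conditions where stated (8v8 and 6v6 animals, five regions)
and fixed realistic choices where not: baseline N(8, 1.5²) log2 (typical
RMA scale), residual σ = 0.2, animal effect σ = 0.1, allele effects
N(0, 0.4²) resampled to |δ| ≥ 0.1, ~3% of probe sets inside the interval
(mirroring ~960 of ~31k on the platform), 15% of those regulated
(≈ 157/960), 2% unplaced, 11 probes per set with N(0, 0.5²) affinity
offsets, and a 2.0 log2 single-probe mismatch loss in iNP-allele carriers
for SNP-designated probe sets. Detection is Bernoulli with present
probability logistic in the realized value (midpoint 6, slope 1.5), giving
10–20% absent calls. Default desk-scale problem size is 2,000 probe sets;
calibration routines use 20,000 (null) and 600 (screen).

Not emulated: array-level technical artifacts and normalization residue,
mean–variance trends (noise is homoscedastic normal, so the moderated test's
advantage over student is muted), correlated co-regulation between probe
sets, region-specific effect sizes (δ is shared across regions), and any
genetic structure beyond the single introgressed interval. Passing tests
therefore certify the machinery's correctness and calibration under an
idealized model, not performance on real arrays.

One calibration-specific choice: the null-calibration checks simulate with
animal-effect σ = 0. The shared per-animal effect is exchangeable within a
probe set (the t-test stays valid marginally) but is the *same* draw for
every probe set, so it correlates the panel and overdisperses genome-wide
false-positive counts relative to the binomial reference the check uses.

## Numerical and I/O conventions

TSV output uses 6 significant digits; JSON reports full double precision.
Determinism: every stochastic routine is driven by one integer seed through
a single `numpy.random.Generator`; the probe-level simulator uses a seed
substream so probe-set- and probe-level data are independent draws from the
same model. The simulation manifest records the seed and a SHA-256 hash of
the configuration. CLI exit codes: 0 success, 2 validation/configuration
error, 3 I/O error.

## Known limitations

- The analyzed-universe counts of the original study (e.g. per-region
  detection-filtered probe-set totals) depend on its raw deposited arrays
  and are not reproduced here; the packaged fixtures carry the published
  summary tables instead.
- The moderated test assumes a common variance prior across the family;
  with strong mean–variance trends a trend-aware prior would fit better.
- The screen's ≥ 4-probe minimum leaves very small probe sets unscreened.
- `select_concordant` treats contexts symmetrically; it does not weight the
  combined context's higher power.
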