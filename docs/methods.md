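# Methods

## Scope and data model

The package analyses gene-level blood expression for two myocardial-infarction
presentations (STEMI, NSTEMI) plus 7-day and 30-day follow-up groups, together
with three kinds of external evidence: literature report counts for candidate
marker genes, disease-gene scores in [0, 1] (DisGeNET-style), and an
undirected weighted interaction edge list (STRING-style exports parse
directly). Gene identifiers are uppercase symbols everywhere; matching across
sources is case-insensitive exact string match. Expression values are treated
as additive and log-like, so group contrasts are additive differences; no
probe-level, count-based or intensity-based modelling is attempted, and
probe-to-gene collapse (mean by default, max-variance optionally) is the only
platform-aware step.

## Batch integration

Datasets are merged on the intersection of their gene universes, with the
source index as batch label. Correction is control-anchored location-scale
harmonization: per gene and batch, values are affinely mapped so the batch's
control mean equals the pooled control mean and its control SD equals the
pooled *within-batch* control SD. Two numerical choices matter:

* The scale target is the pooled within-batch SD, not the grand SD: with that
  choice the transform is exactly idempotent (a second application is the
  identity to machine precision), which the test suite asserts at 1e-9.
* Anchoring uses control samples only, because the source datasets differ
  systematically in group composition; anchoring on all samples would absorb
  genuine group effects into the batch term. Genes with numerically zero
  within-batch control variance (tolerance 1e-12) get shift-only correction.

This is a deliberately simple stand-in for surrogate-variable-style
correction: the contract downstream code relies on is only that group
contrasts are comparable across sources. The `method` argument exists so a
richer estimator could be plugged in. Surrogate-variable estimation itself is
out of scope.

## Fold and score algebra

The fold is implemented literally as the centred-sum formula
`Σ(x_case − μ_ctrl)/n_case − Σ(x_ctrl − μ_ctrl)/n_ctrl`; because the second
term is identically zero it equals the difference of group means, and the two
evaluations are compared to 1e-12 in the tests. No variance moderation or
shrinkage is applied — the statistic is a plain mean difference by design.

Evidence integration: the text-mining score rescales report counts onto the
DisGeNET score range via `count / max(count) · max(score)`; the exact
normalization used by the original analysis is not recoverable, so this
default is explicit and configurable-by-replacement. Genes absent from a
source contribute 0 from it and are flagged, never dropped, so rankings cover
the union universe. The enrichment-fold average divides by the number of
tables actually containing the gene; with full three-table coverage this is
the divide-by-three rule.

## Selection conventions

* Percentile selection (> 99.5 / < 0.25) computes cutoffs by linear
  interpolation between closest ranks (the common "type 7" estimator) and
  applies strict inequalities; realized cutoffs are recorded in the result so
  selections are auditable. Membership is verified against a brute-force
  full-sort oracle.
* The centile filter used for network membership (> 25 / < 25) is rank-based:
  a gene's percentile rank is `100 · r / n` with `r` = 1 + the number of
  scores strictly below it (ties share the lowest rank), compared strictly.
  This convention — rather than the interpolated-cutoff one — is forced by
  the boundary behaviours required of it: centile 0 must pass every gene, and
  an all-tied vector must pass none.
* Profiles use strict `>` on final score, sub-profiles strict `>` on fold,
  ties in orderings break lexicographically on the symbol so outputs are
  deterministic.

## Networks and enrichment

Networks are assembled from the supplied edge list restricted to the query
genes; isolated nodes are retained. Node weight is the final score; edge
weight is the mean of the two endpoints' experiment scores multiplied by the
supplied interaction weight — the combination is a documented package choice,
since only "edge strength reflects the experiment score" is specified by the
design. Interaction retrieval and graph layout are out of scope.

Enrichment is a local upper-tail hypergeometric test per gene set within a
caller-supplied universe, Benjamini–Hochberg adjusted across the tested sets;
sets with no universe overlap are skipped. The implementation uses the scipy
hypergeometric survival function and is tested against exact combinatorial
enumeration (math.comb) to 1e-10, plus a null-calibration check. E-values
reported by web enrichment services are version-dependent and are not
reproduced.

## Sigma-metric time cut-off

QC arithmetic: `TEa = Bias + (ΔSE + Z)·CV` with Z = 1.96 (Pfr = 5%) and
`Sigma = (TE − Bias)/CV`; their algebraic identity
`Sigma(TEa(d)) = d + Z` is asserted to 1e-12. The detection probability uses a
standard normal error model, `Ped(ΔSE) = Φ(ΔSE − L)` with detection limit
L = 3 SD by default: the three reference operating points (ΔSE = 2, 3, 4 →
Ped = 16%, 50%, 84%) are exactly Φ(ΔSE − 3) rounded, which fixes L = 3 even
though the false-reject quantile is 1.96; both quantiles are separate config
fields.

The cut-off search shifts the acute fold profile by k·CV per round and
two-sample t-tests it against the 7-day reference (pooled-variance Student by
default, Welch by flag; identical vectors return p = 1 by convention). k\* is
the first round with p ≥ α. Additional choices:

* **Shift direction.** The additive shift only converges when the acute
  profile sits below the reference; with decaying markers the acute profile
  is typically above it. `direction="auto"` (default) shifts toward the
  reference (sign of the mean difference), `"up"`/`"down"` force it; the
  constructed-recovery behaviour (reference = acute + 3·CV ⇒ k\* = 3) is
  unchanged by the default.
* **CV.** Accepted as a scalar or per-gene vector; the pipeline default is the
  standard error of the case-group mean (SD/√n), i.e. the sampling
  uncertainty of the fold. Which CV the original procedure added is not
  stated, so the choice is explicit.
* **Day mapping.** ΔSE → days is not a derivable function (the reference
  table {2 → 1, 3 → 3, 4 → 2} is not monotone), so the mapping is a lookup
  table supplied by the caller; the reference table ships as the preset
  named `"reported"` and rounds outside the table yield a note rather than a
  number.
* A companion stability test (7-day vs 30-day) guards the premise that the
  reference profile is stationary over follow-up, and `profile_trend` fits
  per-gene OLS fold-vs-time slopes with a two-tailed slope test (constant
  series: slope 0, p = 1 by convention).

## Synthetic data generator

Each matrix entry is `scale_b · (baseline + shift_b + effect + noise)` with
per-batch shift ~ N(0, batch_shift_sd), scale ~ U(batch_scale_range), noise
i.i.d. Gaussian, and planted additive group effects recorded as ground truth.
One integer seed drives a splittable RNG (numpy `SeedSequence`); every
sub-generator derives a child seed.

Default study conditions (used by the test suite and the acceptance script):
2000 genes; 10 samples per group for control/STEMI/NSTEMI/day7/day30/MI;
baseline 8 (log2-like units); noise SD 0.3; between-dataset batch shifts
N(0, 2) with unit scale; planted effects ±1.0 (≥ 3× noise SD) for 8 high- and
4 low-fold genes per acute condition, attenuated to 0.5 / 0.45 at day 7 /
day 30. Evidence tables cover a 5% background of unplanted genes
(Poisson(2) counts, U(0, 0.3) scores) and 80% of planted genes with counts
and scores increasing in effect magnitude; the edge list chains 80% of
planted genes plus random background pairs; one gene set collects the planted
genes alongside four random sets. These sizes run the full pipeline in
seconds while leaving planted effects comfortably estimable at n = 10.

What the generator does **not** emulate: probe-level structure, heavy-tailed
or gene-correlated noise, mean–variance coupling, non-affine batch
distortions, and realistic literature-count distributions. Passing tests
therefore demonstrate that the algebra, selection rules and QC procedure are
implemented correctly and recover planted truth under the stated model — not
that the biological conclusions of any particular study transfer to new data.

## Known limitations

* Batch correction is affine and control-anchored; confounding structures
  beyond location/scale per batch are not removed.
* The published headline heatmap counts from the original cohorts require the
  original raw downloads and unstated correction settings and are not
  desk-reproducible; the packaged panels carry synthetic scores consistent
  with the published thresholds (see `migex.panels`) for exercising the
  bookkeeping only.
* The demo profile threshold (2.5 on the synthetic score scale) is chosen to
  separate within-condition from cross-condition planted genes in the demo
  bundle; real analyses must choose thresholds from their own score
  distributions.
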