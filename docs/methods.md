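# Methods

This note records the model assumptions, the numerical choices, the
synthetic study conditions the package is validated on, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Enrichment statistic

Activity inference reduces each (regulon, signature column) pair to a
normalized enrichment score. The signature column is converted to normal
scores `q = Φ⁻¹(rank/(N+1))` (ties get their mean rank, for determinism)
and folded scores `q1 = Φ⁻¹(½ + |rank/(N+1) − ½|)`. The statistic has a
two-tail part for the sign-informative weight of each target (`w·|m|`)
and a one-tail part for the mode-uncertain weight (`w·(1−|m|)`),
standardized by the half-normal moments `μ₁ = √(2/π)`, `σ₁² = 1 − 2/π`,
and combined with weights `α = Σw|m|`, `β = Σw(1−|m|)`:

```
NES = (α·NES2 + β·sign(NES2)·NES1) / sqrt(α² + β²)
```

Design notes:

* **Rank-based by construction.** NES is invariant to any strictly
  monotone transform of the signature, so normalization choices upstream
  (CPM vs. raw, log vs. linear) do not affect inference within a sample.
* **Sign coupling.** Tying the one-tail part to `sign(NES2)` perturbs
  null normality slightly when `β > 0`; for fully signed regulons
  (`|m| = 1` everywhere, as in the synthetic generators) `β = 0` and the
  statistic is exactly the standardized weighted sum of normal scores.
  Calibration is verified empirically rather than assumed: over 10⁴ null
  signatures (3000 genes, 50-target ±1-mode regulon) the suite requires
  |mean| < 0.02, sd ∈ [0.97, 1.03] and type-I error at α = 0.05 within
  [0.04, 0.06]. The sd sits slightly below 1 because normal scores on a
  finite grid have variance just under 1.
* **Fully mode-uncertain regulons** (`α = 0`) have no defined direction;
  the one-tail magnitude is reported positive and flagged.
* **The permutation oracle is the binding contract.** `permutation_nes`
  recomputes the full combined statistic under gene-label permutations
  (uniform target placement without replacement) and z-scores the
  observed value against that null. The combined statistic — rather than
  an unstandardized "combined ES" — is permuted because the two parts are
  standardized differently and only their combination is well defined.
  The suite requires |analytic − permutation z| ≤ 0.15 over 20 randomized
  mixed-mode, mixed-likelihood cases at 10⁴ permutations.
* `min_targets` defaults to 25: enrichment over very small target sets is
  unstable. The mutation-association benchmark overrides it to 3, where
  the "regulon" is a set of mutated samples.

## Multi-network integration

Per-network NES values are combined per (regulator, sample) over the
networks where the regulon passed `min_targets`; no imputation is done
and the per-cell evidence count is reported. `NESScore` is implemented as
the |z|-weighted Stouffer combination `Σ|z|z / √(Σz²)` (the alternative
normalization `Σ|z|z / Σ|z|` is available as `NESmean`). Two caveats are
deliberate and documented rather than hidden:

* With data-dependent weights the Stouffer null is **not** exactly unit
  normal: for k independent null inputs the variance grows from 1 (k = 1)
  toward 3 as k grows, and shared-signature/shared-target correlation
  between networks inflates it further. Nominal p-values from integrated
  scores are therefore anticonservative for ranking-free uses; ranking
  and the recovery benchmarks are unaffected, and single-network NES
  p-values are calibrated.
* `maxScore` ties are broken by input order and logged — reproducibility
  over elegance.

`randomMatch` draws one network per sample (not per protein), as a
baseline control. A cell whose drawn network lacks the regulon is left
missing with evidence count 0 — the one place the activity matrix can
contain non-finite entries.

Single-evidence cells short-circuit to the plain per-network value so
that a one-network integration is bitwise identical to plain
single-network analysis (the suite asserts this exactly, as well as the
√k duplicate-network identity of `NESScore`).

## Signatures

`zscore` (default for bulk) and `mad` (default for single cells; robust
to dropout-inflated tails) score test samples against a reference;
`rank` maps within-sample ranks to normal quantiles. Per-cell signatures
use a leave-self-out reference to avoid self-contamination (an all-cells
reference is available by flag). Genes with zero reference dispersion
score 0 and are flagged. Since enrichment is rank-based, the choice
mostly affects interpretability of the signature itself, not the
downstream activity ranking.

## Repertoire adequacy

A sample's ECDF of |NES| over all scored proteins (≥ 100 required) is
compared against a pooled reference panel by the two-sample KS distance.
The threshold is the conformal `alpha`-quantile — the
`ceil(alpha·(n+1))`-th order statistic — of the leave-one-out distances
among the n reference profiles. Under exchangeability this bounds the
false-alarm rate at `1 − alpha` without any tuned constant; a plain
empirical quantile would give ≈ `alpha·n/(n+1)` coverage and
systematically over-flag. Pooling the reference (concatenating |NES|
values) approximates averaging the cohort-specific densities.

## Synthetic study conditions

The generators define the conditions under which every claim is tested;
all are seed-deterministic and parameter-logged into `SyntheticTruth`.

* **Master interactome** — default 100 regulators × 50 targets over 3000
  genes; modes ±1 with 30% repressions (regulons are typically
  activator-dominated); likelihoods ~ Uniform(0.5, 1].
* **Context networks** — per regulon, exactly `ceil(fidelity·size)`
  original targets kept; the rest replaced by genes outside the original
  target set with random modes, sizes preserved. Fidelity is the
  "partial regulon conservation" knob.
* **Signatures** — per sample, 5 active regulators at θ = ±0.5 plus
  N(0, 1) gene noise, 200 samples; signature-space generation is used for
  bulk tests because enrichment only sees ranks. At these settings a
  planted regulator's single-network NES is ≈ θ·√(Σw²) ≈ 2.7 on average,
  so single-sample detection is strong but not saturated — integration
  across a repertoire is what pushes recovery into the top decile.
* **Default recovery scenario** — the package's subject is multi-network
  integration, so recovery is measured on a 6-context repertoire
  (fidelity 0.5 unless the test varies it) integrated with `NESScore`.
  "Planted regulators rank in the top decile" is operationalized as the
  *median* planted (regulator, sample) percentile lying in the top decile
  of each simulation, consistent with the median-based comparisons used
  throughout.
* **Single-cell counts** — per cell, gamma-perturbed means (negative
  binomial, dispersion 0.3) multinomially thinned to the cell depth;
  dropout arises purely from depth, with no zero-inflation parameter.
  The dropout benchmark uses two populations of 120 cells at 20 000
  reads/cell over 8000 genes, driven by two disjoint sets of 40
  regulators at per-target log-effect 0.5 — the regime where individual
  gene reads are unreliable (most genes have zero counts in a cell) but
  50-target aggregates are not.
* **Mutations** — every regulator gene gets a recurrence drawn uniformly
  from the configured range; coupled genes shift the planted activity of
  their mutated samples by `effect_shift` before signatures are
  regenerated. The association benchmark scores each protein's
  mutated-sample set against its activity vector with the enrichment
  engine (min_targets 3, pooled across all samples) and reports the
  fraction significant at p < 0.01 per recurrence threshold.

What passing these tests shows — and does not. The generators emulate
planted low-rank structure plus i.i.d. noise, depth-driven dropout and
uniform mutation recurrence. They do not emulate gene-length/GC bias,
doublets, batch structure beyond a scale factor, correlated regulon
overlap of real networks, or the mutation spectra of real tumors;
passing here demonstrates correctness and calibration of the machinery
under its stated model, not performance on any particular real dataset.

## Problem sizes used by the suite and acceptance script

Chosen as the smallest sizes at which the measured quantities are stable:
null calibration 10⁴ draws × 3000 genes; oracle 20 cases × 10⁴
permutations; recovery 20 simulations (tests) / 8 (script) of the default
scenario; fidelity sweep 50 simulations × 6 fidelities at 20 samples;
40%-fidelity detection pooled over ≥ 1000 planted calls; holdout 100
samples; adequacy 30 reference + 40 + 40 trial profiles of 200 proteins;
mutation association 600 proteins × 200 samples; dropout 2 × 120 cells.

## Known limitations

* No pleiotropy/shadow-regulon correction: regulators with overlapping
  regulons share evidence and their activities are correlated.
* ARACNe-style import estimates modes by Spearman correlation between
  regulator and target expression — a documented convention, not a
  reconstruction of how any given network encoded its modes; likelihoods
  are MI rescaled to a per-regulon maximum of 1.
* Integrated (multi-network) p-values are anticonservative (see above);
  treat them as ranking scores unless k = 1.
* The adequacy rule assumes exchangeable reference profiles; references
  mixing very different cohort sizes or score scales should be pooled
  with care.
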