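# Methods

## Island-level methylation and the 0.2 threshold

A gene's methylation level in a sample is the arithmetic mean β over the
probes of its promoter CpG island (for *SDC2*, the canonical 12-probe set
cg13096260 … cg07146119). The 450k β distribution is bimodal with the
unmethylated peak below 0.2, so 0.2 is used as the decision boundary
throughout: a sample is methylation **positive** when the island level is
*strictly above* 0.2 and **hypomethylated** at or below 0.2. The two
conditions partition samples exactly; the boundary is unit-tested at
β = 0.2 and the next representable float. Missing probe values are excluded
from the island mean; a sample with all probes missing gets a missing level
and is dropped from downstream denominators with a warning.

## Complement screen

Within the anchor-hypomethylated case samples, every island is scored by
`complement_rate = 100 × (#samples with level > 0.2) / (#samples with a
non-missing level)` and islands are ranked by rate, descending, with ties
broken alphabetically by gene name (the tie-break is a free choice; only the
top of the ranking is scientifically meaningful). The screen operates at
island level; a per-probe mode exists behind a flag for exploration but is
not part of the standard procedure. Subsite tables report positive /
negative / total / rate per tumor location plus a Total row; rates are
rounded half-up, with the number of decimals a parameter (the published
tables round to one decimal and pad a trailing zero).

## MSP calling

* Validity: ACTB must amplify with Ct ≤ 36; invalid samples are excluded
  from every downstream denominator (sensitivity, specificity, ROC).
* Per-gene call: target Ct ≤ 38 is positive; NO_AMP (no amplification
  within the 45-cycle run) is negative. NO_AMP is a distinct state at the
  data layer and is never silently coerced to a cycle number.
* Combined call: OR over the target genes.
* ML = 2^−ΔΔCt against the fully methylated positive-control plasmid mix
  (the calibrator); a NO_AMP target has ML = 0 — no detectable methylated
  template. ML is shift-invariant in (Ct_target, Ct_ACTB) and equals 1 for
  the calibrator itself; both identities hold to machine precision.
* ROC scores: the combined Ct score is the **minimum** target Ct with
  NO_AMP coerced to 45 (the run length) — the only place that coercion
  happens — so that a sample is score-positive at 38 exactly when the OR
  call fires; the combined ML score is the **maximum** target ML. How two
  Ct values reduce to one ROC score is a genuinely open design point; the
  min-Ct reduction is the one consistent with the OR calling rule.

## ROC, CIs, cutoffs, tests

AUC is the midrank (Mann–Whitney) estimator with ½ credit for ties; the
oracle tests verify it against exhaustive concordant-pair counting. The 95%
CI uses DeLong's structural-components variance (validated against R pROC
to 10 decimals on a frozen instance); a percentile bootstrap (2000 seeded
resamples) is available behind a flag. The optimal cutoff maximizes
Youden's J over all observed score values; ties in J break toward higher
sensitivity, then toward the more permissive cutoff. Orientation is
explicit (low Ct = case-like, high ML = case-like) and negating scores
while flipping orientation leaves all results unchanged.

Fisher's exact test (two-sided conditional hypergeometric, scipy) handles
subsite contrasts; a zero margin returns p = 1 with a warning. Mann–Whitney
U and Wilcoxon signed-rank (scipy) use exact enumeration for small samples
(n ≤ 25; MWU requires tie-free data for the exact path) and the
tie-corrected normal approximation otherwise. Dual-vs-single sensitivity is
tested per location with Fisher's exact test on the independent 2×2 of
detected/missed × marker set; because the two calls are paired on the same
samples, McNemar's exact test is reported alongside it — the Fisher p is
kept for comparability, the McNemar p is the statistically proper one.

## Synthetic cohorts

**β cohorts.** Each sample draws a location, then a latent methylation
state per gene (Bernoulli, group- and location-specific), then i.i.d. probe
β values from a truncated normal on [0, 1] for that state. Truncated
normals (rather than Beta distributions) are used because the source
summary statistics are means and SDs, which truncated normals match
directly. Default emissions: anchor unmethylated 0.067 ± 0.018, methylated
0.492 ± 0.178; complement unmethylated 0.161 ± 0.078, methylated
0.558 ± 0.149. Genes are independent given group and location *except* for
one explicit dependence: P(complement methylated | anchor unmethylated),
default 0.88 — this is what plants the complementarity the screen recovers.
The discovery-scale default is 391 cases / 45 controls with per-subsite
anchor positivity shaped after the published per-site single-marker
sensitivities.

**Ct cohorts.** ACTB Ct is truncated-normal per group with means ordered
CRC (26.0) < adenoma (27.5) < normal (29.0), SD 1.5 — cancer stools shed
the most exfoliated epithelial cells, so they carry the most template. The
means themselves are not published; they were chosen as plausible qPCR
values realizing that ordering with a clearly detectable (~3-cycle)
separation. Methylated targets amplify at ACTB + ΔCt (ΔCt ≈ 5.0 ± 1.8 for
SDC2, 5.5 ± 1.8 for TFPI2), censored to NO_AMP past 45 cycles; unmethylated
targets are NO_AMP with probability 0.97, otherwise they amplify late,
uniformly above the 38-cycle cutoff (the ~3% late-amplification background
mirrors the published normal-stool complement positivity of 2.89%).
Stool-scale defaults: 289 CRC / 190 adenoma / 217 normal; per-location
anchor positivity and complement-given-anchor-negative probabilities are
taken from the published subsite tables (the right-colon values, absent
from those tables, were back-solved from the printed overall sensitivities
and per-site n's: anchor positivity 0.93 for cancer, 0.63 for adenoma).
Under these defaults the expected single/dual cancer sensitivities are
≈ 0.87 / 0.94 and dual specificity ≈ 0.96, approximately — binomial noise
of 1–3 points applies at cohort size.

The group-dependent ACTB load is also the mechanism that makes the raw Ct
a better ROC indicator than the load-normalized ML: a methylation-positive
normal sample has the same ML distribution as a positive cancer sample
(AUC contribution ½), but its target Ct sits ~3 cycles later. The
replicated simulations confirm Ct-AUC ≥ ML-AUC in essentially every
cohort.

**What the generator does not emulate:** probe-level spatial correlation
along the island, bisulfite-conversion error, batch/array effects, FFPE
degradation, PCR inhibition in stool, and covariate structure (age, sex,
stage). Passing tests therefore demonstrate that the *pipeline* recovers
planted structure under the stated statistical model, not that the panel
achieves the published clinical accuracy on real specimens — the clinical
stool/tissue cohorts are not publicly deposited, so those headline numbers
cannot be recomputed from raw data here.

## Problem sizes and determinism

Replicated checks use 50 replicates at study-scale n (289/190/217 stool;
391 + 45 discovery with 50 decoy islands), which keeps every Monte-Carlo
estimate's sampling error at or below the tolerance it is tested against.
All randomness flows through explicit `numpy` `Generator` seeds; there is
no global random state, and identical seeds give byte-identical outputs.

## Known limitations

* The exact Mann–Whitney path is only taken for tie-free data; heavily tied
  small samples fall back to the tie-corrected normal approximation.
* DeLong CIs are Wald-type on the AUC scale and are clipped to [0, 1]; near
  AUC = 1 a logit-scale or bootstrap CI would be better calibrated.
* One published normal-stool rate prints as 2.89% while its own counts
  (6/208) give 2.8846% → 2.9% at one decimal; the counts are treated as
  authoritative and recomputed rates agree with the printed value within
  one unit in the last printed place.
* The per-location report conditions on the simulated location labels;
  locations with no valid cases in a replicate are omitted rather than
  shown as empty rows.
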