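# Methods

## The inference model

EpiRAD-style methylation inference is indirect: two libraries from one DNA
aliquot differ only in the common cutter (MspI vs HpaII), so methylation at a
CCGG site manifests as locus dropout from the methylation-sensitive library.
`epiradkit` treats methylation as binary per (locus, sample):

- **Retention.** After CPM standardisation, a locus is retained iff its CPM
  is ≥ 15 in *every* methylation-insensitive (RAD) library. The threshold is
  applied on the CPM scale, not raw counts: retention must not depend on
  library depth. A locus that is poorly captured in the RAD libraries cannot
  distinguish "methylated" from "badly sampled", so it is excluded before
  calling. Retention is monotone in the threshold (retained(21) ⊆
  retained(15) ⊆ retained(7)), which the sensitivity analysis exploits.
- **Calling.** A retained locus is methylated in a sample iff its *raw*
  EpiRAD count is exactly 0 (zero is zero on any scale, so the rule needs no
  normalisation). A count of 1 is unmethylated. This is deliberately
  conservative: a uniform positive cut-off cannot be correct across samples,
  because a more methylated sample concentrates its fixed sequencing budget
  on fewer unmethylated loci and inflates their counts. Zero avoids that
  compositional trap at the cost of classifying partially methylated loci
  (hemi-methylation, cell mosaicism) as unmethylated — called proportions
  are therefore systematic *under*estimates of any-methylation proportions,
  and the test suite asserts that direction on simulated data.

Downstream accounting works on the binary call matrix: differential loci
(call not constant over all 64 samples), counts of loci uniformly
(un)methylated within sample groups as percentages of the differential
universe, and per-individual fin–gonad shared-methylated counts.

## Statistical layer

Small-n cross-sectional tables (one row per individual) are analysed with
OLS. Factors are treatment-coded with AGE1 and female as references, so the
SEX coefficient is an additive male effect. Candidate sets follow the study
design — intercept-only, AGE + SEX, AGE × SEX (plus body size for
telomeres), and for the surrogate question gonad ~ fin (+ SEX, + fin × SEX)
— and are compared by AICc computed from the Gaussian ML log-likelihood
(variance RSS/n), with k = number of coefficients + 1 for the residual
variance. ML rather than REML keeps likelihoods comparable across fixed-
effects structures. Ties within 1e-8 resolve to the smaller model.

Term tests are marginal (Type II) drop-term F tests; a main effect whose
interaction is in the model is tested with the interaction excluded from
both nested models (respecting marginality), and the exclusion is logged.
For the additive AGE + SEX model on 32 individuals this yields the familiar
F(2, 28) layout for AGE. The test suite cross-checks the implementation
against statsmodels' `anova_lm(typ=2)` on additive models. Whether sums of
squares should be sequential instead is not determinable for this design
family; Type II is recorded as the package's assumption.

Welch's t-test (Satterthwaite fractional df) handles two-tissue mean
comparisons; its type-I error is verified at 0.05 ± 0.01 under a 10 000-
replicate unequal-variance null. Residual normality is checked via Q-Q
tables (plotting positions (i − 0.5)/n). Two-sided p-values throughout; no
multiple-testing correction is applied in this layer.

Classical MDS is the textbook double-centering eigendecomposition
(B = −½·J·D²·J), authored here and cross-checked against scikit-bio's PCoA
in the tests. The dissimilarity is Euclidean distance on the binary call
vectors (√Hamming-count), the canonical input for classical scaling;
Hamming-proportion and Jaccard are available alternatives. Axis percent
variance is taken over positive eigenvalues only, keeping percentages in
[0, 100] for non-Euclidean metrics.

## The synthetic-data generator

`simdata` emulates the study conditions, not raw reads:

- **Design.** 32 individuals — 15 F / 17 M, age groups of 10/11/11 with
  5/6/4 females (the sacrifice schedule) — two tissues each, paired RAD and
  EpiRAD libraries: 128 libraries. Library sizes are gamma-distributed
  around 3.76M (RAD) / 4.45M (EpiRAD) reads with CV 0.15 (a typical
  between-library spread for pooled Illumina runs).
- **States.** Per sample, each of the 8 000 loci is independently
  methylation-designated with probability `meth_prob(tissue, sex, age)`; a
  designated locus is partial with probability `partial_frac = 0.2`, drawing
  its methylated cell fraction f uniformly on (0, 1).
- **Counts.** Per-locus capture propensities are gamma (shape 2.0, mean 1),
  drawn once per dataset and shared by all libraries — RAD/EpiRAD pairs come
  from one aliquot, so capture bias is common; without this the zero-read
  call would be meaningless. No per-locus depth distribution is reported for
  the emulated assay, so the gamma shape is a modelling choice: shape 2
  gives the right qualitative behaviour (a minority of weakly captured loci
  that the retention filter removes, median retention ~96% at threshold 15).
  RAD counts are multinomial over the propensities; EpiRAD propensities are
  zeroed for fully methylated loci and scaled by
  `partial_retention × (1 − f)` (read depth proportional to the unmethylated
  cell fraction, `partial_retention = 0.5` for HpaII's reduced efficiency on
  hemi-methylated templates) before renormalisation and the multinomial
  draw. Column sums equal library sizes exactly.
- **Telomeres.** Fin medians are Normal per sex × age with an AGE2 dip and a
  female surplus (means 7.9/7.0/7.9 kb for females, 7.3/6.4/7.3 kb for
  males, sd 0.9 kb — overall mean ≈ 7.3 kb, range matching TRF medians of a
  few to ten kb). Gonad medians follow
  `a + 0.97·fin − 1.36·[male] + ε`, ε ~ N(0, 0.75² kb²). The intercept
  `a = (1 − slope)·(female fin mean)` makes female gonad means equal female
  fin means exactly; male gonad means differ from fin + offset by
  `(1 − slope)·(fin_F − fin_M)` ≈ 0.01 kb, which is negligible. The residual
  sd 0.75 kb was chosen analytically so the gonad ~ fin + SEX fit has
  adjusted R² ≈ 0.73 at the default fin variance.
- **Seeding.** One global seed feeds a `SeedSequence` hierarchy (metadata,
  states, counts, telomeres), so identical configs are bit-identical and
  each stage can be regenerated independently.

### Calibration

Target mean *called* proportions are 1.36% (fins, with an age trend
1.14/1.36/1.56% weighted by group sizes) and 2.15% (gonads, sex split
1.85/2.41% weighted 15:17). Generating designation probabilities are these
targets divided by the effective call rate
`(1 − partial_frac) + partial_frac·z`, where z is the probability that a
*partially* methylated retained locus still yields zero EpiRAD reads at
default depth. z was measured once by simulation at the default
configuration (946/172 297 ≈ 0.0055 over 80 replicates), giving an
effective rate of 0.8011; fully methylated loci always call correctly and
no unmethylated retained locus produced a false zero in 3.8 × 10⁷ trials.
This calibration is frozen in the defaults and not tuned thereafter.

### What the generator does **not** emulate

Locus identity is exchangeable: methylation is drawn independently per
sample with no locus-level effects shared within a tissue, sex or
individual beyond the rate differences. Consequently group-level *rate*
statistics (proportions, t-tests, AGE/SEX models, slope/offset recovery)
are faithful, but pattern-level quantities are weaker than in real data:
per-individual fin–gonad concordance is near its chance level, MDS axes
carry only a few percent of variance each, and tissue clustering reflects
rate separation rather than shared marks. Passing tests therefore validate
the *operations*, and rate-level recovery — not the biological pattern
structure of any real dataset. Restriction-site placement, sequencing
error, allelic dropout and survival/mortality are likewise out of scope.

## Problem sizes in the test and acceptance runs

Most tests run the default 32-individual design at 600 loci and ~3 × 10⁵
reads per library — deep enough (~500× per locus) that depth-driven dropout
of unmethylated retained loci is negligible, which is the regime the zero-
read rule assumes. Parameter-recovery checks use 200 replicates at the full
default configuration; the acceptance script uses 50. These sizes give
Monte-Carlo standard errors a few times smaller than the effects being
recovered.

## Numerical choices and degenerate inputs

- CPM requires a positive library total; empty libraries raise with the
  library named. Loci missing from a count matrix are treated as zero
  counts.
- RAD↔EpiRAD pairing is by (individual, tissue) key, never column order;
  unpaired EpiRAD libraries raise.
- AICc is undefined for n ≤ k + 2; a bare fit records NaN, and model
  selection refuses to rank such candidates.
- Rank-deficient designs raise with the aliased columns listed; rows with
  missing covariates are dropped listwise with a logged count; estimated
  means refuse unseen factor levels.
- MDS validates symmetry, zero diagonal and non-negativity at 1e-8; with
  fewer positive eigenvalues than requested axes it returns what exists
  with a warning.
- Non-positive simulated telomere medians are redrawn (bounded retries).

## Known limitations

Binary calls cannot quantify methylation level; the package deliberately
refuses a continuous EpiRAD-depth readout, which would need a subjective,
sample-specific cut-off. The shared-locus percentages are exact arithmetic
on the differential universe; group comparisons of such counts carry no
significance machinery here. The statistical layer is fixed-effects only —
no longitudinal or mixed models — matching the cross-sectional design it
serves.
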