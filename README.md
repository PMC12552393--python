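# epiradkit

Presence/absence DNA-methylation inference from paired RAD/EpiRAD
reduced-representation sequencing libraries, with the comparative
fin-versus-gonad analysis used to evaluate fins as a surrogate tissue for
age-related change in a short-lived fish (turquoise killifish,
*Nothobranchius furzeri*), and a synthetic-data generator so the whole
analysis is testable without the original sequencing data.

## Who this is for

Researchers running EpiRADseq-style experiments: each DNA sample is digested
twice, once with a methylation-insensitive common cutter (MspI, the "RAD"
library) and once with its methylation-sensitive isoschizomer (HpaII, the
"EpiRAD" library). Methylated CCGG sites are not cut by HpaII, so methylated
loci *drop out* of the EpiRAD library. Given per-locus read-count matrices
for the paired libraries, `epiradkit` infers binary methylation states and
runs the downstream comparative statistics.

## The method

1. **CPM standardisation** — each library's counts are scaled to counts per
   million: `cpm[i,j] = count[i,j] / library_size[j] * 1e6`.
2. **Locus retention** — a locus is kept iff its CPM is at least 15 in
   *every* RAD library (thresholds 7 and 21 are run as a sensitivity check).
   Loci poorly covered in the methylation-insensitive libraries cannot
   support a dropout interpretation.
3. **Zero-read calling** — a retained locus is called methylated in a sample
   iff its raw EpiRAD count is exactly 0. This avoids false positives at the
   cost of missing partially methylated loci (hemi-methylation, cell
   mosaicism), so called proportions underestimate total methylation.
4. **Proportion statistics** — per-sample percentage of retained loci called
   methylated; Welch two-tailed t-tests between tissues; OLS models with AGE
   (3 groups) and SEX as treatment-coded factors, compared by AICc
   (`AICc = -2ℓ + 2k + 2k(k+1)/(n-k-1)`, k counting coefficients plus the
   residual variance); marginal (Type II) term F tests; model-estimated
   means with 95% CI.
5. **Shared-locus accounting** — differentially methylated loci (call not
   identical across all samples), counts of loci uniformly (un)methylated
   within sample groups, and per-individual fin–gonad concordance.
6. **Ordination** — classical multidimensional scaling (principal
   coordinates) of samples from Euclidean distances on the binary call
   vectors over the differential loci, with percent variance per axis.
7. **Telomere layer** — the same model set applied to terminal restriction
   fragment (TRF) telomere-length medians per individual and tissue,
   including the fin→gonad regression `gonad ~ fin + SEX`.

The simulator (`epiradkit.simdata`) generates the full study design — 32
individuals (15 F / 17 M) in age groups of 10/11/11, two tissues, paired
libraries of ~3.76M (RAD) and ~4.45M (EpiRAD) reads over 8 000 loci with
shared gamma capture propensities, true methylation states including
partial methylation, and telomere medians with a positive fin→gonad slope
(0.97) and an additive male deficit (−1.36 kb) — so every inference step can
be checked against known truth.

## Worked example

```python
from epiradkit.pipeline import RunConfig, run
from epiradkit.simdata import SimConfig

report = run(RunConfig(sim=SimConfig(seed=1), out_dir="demo_run"))
```

or equivalently `epiradkit run --seed 1 --out demo_run` from the shell.
The run writes every intermediate artifact (counts, retained loci, calls,
proportions, model tables, MDS coordinates) plus `report.json` and
`report.md`. For seed 1 the report reads:

```
- retained loci: 7676 of 8000 (CPM >= 15.0 in all RAD libraries)
- differential loci: 5159
- fin: 1.37 +/- 0.04% (range 0.98-1.72, n=32)
- gonad: 2.19 +/- 0.06% (range 1.62-2.74, n=32)
- fin vs gonad Welch t-test: t_51.4 = -11.87, p = 2.38e-16
- fin->gonad slope 0.91 +/- 0.16, male offset -1.46 +/- 0.30, adj R^2 = 0.684
```

Reading: 7 676 loci were covered well enough in all 64 RAD libraries to be
interpretable; fins call ~1.4% of them methylated and gonads ~2.2%
(methylation is scarcer in fins); the fitted telomere fin→gonad slope
(0.91 ± 0.16) and male offset (−1.46 ± 0.30 kb) recover this seed's view of
the generating values 0.97 and −1.36, with fin telomere length explaining
~68% of gonad variance — fins are an informative surrogate.

Individual stages are available as functions (`cpm_normalize`,
`filter_loci`, `call_methylation`, `methylation_proportion`, ...) and as
scikit-learn estimators (`CPMNormalizer`, `MinCPMLocusFilter`,
`ZeroReadCaller`, `ClassicalMDS`) that compose in sklearn pipelines.

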