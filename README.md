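# protmr

Proteome-wide two-sample Mendelian randomization (MR) with Bayes-factor
colocalization, on GWAS summary statistics.

## The problem

Circulating plasma proteins are attractive biomarkers and drug targets, but
observational protein–disease associations are confounded. `protmr`
implements the summary-statistics workflow used to screen a plasma proteome
for *causal* effects on a binary disease outcome (the motivating application
is primary biliary cholangitis, PBC):

1. **Instrument selection.** Protein quantitative trait loci (pQTLs) are
   filtered to genome-wide-significant (p < 5×10⁻⁸), strong (F ≥ 10),
   non-MHC, non-pleiotropic (≤ 5 proteins per SNP), non-protein-coding
   variants, then organized into four instrument groups per protein:
   **A** sentinel cis-pQTL only, **B** sentinel plus conditionally
   independent cis-pQTLs (summary-statistic joint analysis), **C**
   trans-pQTLs, **D** all pQTLs; groups B–D are LD-clumped at r² < 0.1.
2. **MR.** Per group: the Wald ratio `β_y/β_x` for single instruments,
   inverse-variance-weighted (IVW) regression otherwise — fixed effects, or
   multiplicative random effects when Cochran's Q signals heterogeneity —
   with Egger regression and the weighted median as sensitivity references,
   the Steiger directionality test, leave-one-out, MR-PRESSO outlier
   removal, and analytic power for binary outcomes (the mRnd formula).
3. **Two-cohort decision rule.** Proteins must pass Benjamini–Hochberg
   FDR < 0.05 in a large discovery cohort *and* replicate (nominal p < 0.05,
   concordant direction) in an independent cohort.
4. **Colocalization.** For each surviving protein, per-SNP Wakefield
   approximate Bayes factors (`log ABF = ½[log(1−r) + r z²]`,
   `r = W/(V+W)`) over the 2 Mb cis region are combined into posterior
   probabilities for hypotheses H0–H4. PP.H3 > 0.8 (distinct causal
   variants) marks the MR hit as LD-confounded and excludes it; PP.H4 > 0.8
   (shared variant) reinforces it.

Real pQTL/outcome GWASs are not shipped: a first-class synthetic-data
module (`protmr.simulate`) generates summary statistics with regional LD,
cis/trans architectures, two case-control cohorts of very different case
counts, pleiotropic instruments and shared/distinct causal variants, with
ground truth emitted alongside so every stage is testable.

## Worked example

```bash
python examples/mr_estimators.py
```

simulates 50 valid instruments with a true causal effect θ = −0.2 (log-OR
per SD of protein) and prints:

```
          ivw_fe: beta=-0.196  OR=0.822 [0.799, 0.845]  p=3.10e-42
           egger: beta=-0.240  OR=0.786 [0.717, 0.862]  p=5.80e-06
 weighted_median: beta=-0.173  OR=0.841 [0.811, 0.873]  p=2.22e-20
heterogeneity: Q=36.4 (p=0.91)
egger intercept p: 0.33
MR-PRESSO global p: 0.912, outliers: none
Steiger direction exposure->outcome: True (p=1.0e-300)
```

All three estimators bracket the truth; the heterogeneity, Egger-intercept
and MR-PRESSO diagnostics are quiet because no pleiotropy was planted.
`examples/coloc_scenarios.py` shows the colocalization decision flipping
from PP.H4 ≈ 1 (shared causal variant) to PP.H3 ≈ 1 (distinct variants in
LD, the architecture that produces false-positive MR hits), and
`examples/full_pipeline.py` runs the whole workflow on a 60-protein
synthetic study — causal proteins come out `replicated_colocalized`, a weak
one stays `discovery_only`, and the planted LD-confounded protein is
`excluded_LD_confounded`.

The same workflow is scriptable from the shell:

```bash
protmr simulate --n-proteins 60 --n-causal 3 --seed 7 --out bundle/
protmr run --bundle bundle/ --out results/
protmr coloc --trait1 pqtl.tsv --trait2 gwas.tsv --sentinel rs123 --half-width 1000000
```

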