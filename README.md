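# lipidcross

Analysis pipeline for plasma shotgun-lipidomics data from two-intervention
crossover trials — built for chrononutrition studies that compare early
versus late time-restricted eating (eTRE/lTRE), where each subject is
measured before and after each diet arm and the question is which lipid
parameters the timing of the eating window changes.

The package takes a species × sample matrix of molar amounts (pmol per µL
plasma), with rows named in shorthand lipid nomenclature
(`PC 34:1;0`, `PI 18:1;0_16:0;0`, `PC O-18:1;0/16:0;0`), and provides:

1. **Nomenclature parsing** — a validating parser for sum species,
   resolved subspecies (`_` unknown / `/` known sn-position), ether (`O-`)
   and hydroxylated chains, over a fixed 14-class plasma taxonomy
   (Chol, CE, TAG, DAG, PC, PC O-, PE, PE O-, PI, LPC, LPC O-, LPE, SM, Cer).
2. **Prevalence filtering** — species present in less than 70% of all
   samples are excluded (presence = non-missing and > 0; exactly 70% stays
   in), with a per-sample report of how much molar content the retained
   species cover.
3. **Six analysis layers** — species; class totals; fatty-acid totals
   within complex lipids (each resolved chain contributes the species'
   amount to its C:DB;OH key); desaturase/elongase activity indices; and
   per-class double-bond and chain-length subgroups. The seven default
   indices are the surrogate enzyme-activity ratios
   D5D = FA 20:4/20:3, D6D = FA 18:3/18:2, D9D(C16) = 16:1/16:0,
   D9D(C18) = 18:1/18:0, D9D(C16+18) = (16:1+18:1)/(16:0+18:0),
   ELOVL5 = 20:3/18:3, ELOVL6 = 18:0/16:0, all user-overridable.
4. **Crossover contrasts** — per feature, the paired Wilcoxon signed-rank
   test on within-arm before/after pairs and on between-arm per-subject
   deltas (Δ = after − before; between-difference = Δ_lTRE − Δ_eTRE), with
   exact sign-flip null for n ≤ 25 untied pairs, Benjamini–Hochberg FDR
   within each (layer × contrast) family, fold changes of mean amounts,
   t-based 95% CIs on deltas, and volcano-ready tables.
5. **Pathway enrichment** — significant species merged to classes, tested
   with a one-sided hypergeometric over-representation analysis against
   GMT-style pathway compound sets, plus an overlay of a differential
   gene-expression table (genes kept when mean FPKM > 1 and p < 0.05)
   onto an enriched pathway's gene set.
6. **Synthetic trials** — a generator with known ground truth: ~300
   species over the 14 classes, log-normal amounts with subject random
   effects, the full crossover design, injectable multiplicative
   intervention effects, and realistic missingness, so every stage is
   testable without any external data.

## Worked example

Simulate a 30-subject crossover trial in which early time-restricted
eating lowers all ceramide species to 0.8× their baseline, then test the
class layer within the eTRE arm:

```python
from lipidcross import (TrialConfig, Effect, Intervention, generate_trial,
                        prevalence_filter, class_totals, within_contrast,
                        results_frame)

cfg = TrialConfig(n_subjects=30, seed=11,
                  effects=[Effect(Intervention.ETRE, "Cer", 0.8)])
matrix, truth = generate_trial(cfg)
filtered, report = prevalence_filter(matrix, 0.70)
print(f"{report.n_species_out}/{report.n_species_in} species retained, "
      f"mean coverage {report.mean_coverage:.3f}")

results = within_contrast(class_totals(filtered), Intervention.ETRE)
table = results_frame(results)
print(table[["feature", "n_pairs", "fold_change", "p_raw", "q_bh",
             "direction"]].round(4).to_string(index=False))
```

Output:

```
300/300 species retained, mean coverage 1.000
feature  n_pairs  fold_change  p_raw   q_bh direction
   Chol       29       0.9483 0.1195 0.4302      none
     CE       30       0.9703 0.3135 0.6572      none
    TAG       30       0.9920 0.3655 0.6572      none
    DAG       30       1.0160 0.5647 0.6808      none
     PC       30       1.0108 0.5509 0.6808      none
  PC O-       30       0.9729 0.6509 0.6808      none
     PE       30       0.9948 0.6808 0.6808      none
  PE O-       30       0.9643 0.0136 0.0951      none
     PI       30       0.9988 0.3655 0.6572      none
    LPC       30       1.0215 0.6362 0.6808      none
 LPC O-       30       0.9855 0.3991 0.6572      none
    LPE       30       0.9652 0.4225 0.6572      none
     SM       30       1.0076 0.1229 0.4302      none
    Cer       30       0.7925 0.0000 0.0000      down
```

The injected ceramide reduction is recovered: the Cer class shows a fold
change of 0.79 (true multiplier 0.8) and survives BH correction
(q < 0.05, direction `down`), while every unaffected class stays
non-significant. One Chol pair is lost to simulated missingness, hence
n = 29 there.

The same analysis is available from the shell:

```bash
lipidcross run-all --simulate --effect eTRE:Cer:0.8 --seed 11 --out run/
```

which writes the filter report, the six layer tables, all three contrast
result sets, volcano tables, enrichment results and a JSON run manifest;
re-running with the same seed reproduces every file byte for byte.
Individual stages are exposed as `simulate`, `parse-check`, `filter`,
`layers`, `contrast` and `enrich` subcommands.

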