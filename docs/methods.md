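# Methods

## The analysis problem

A two-intervention crossover trial measures each subject's plasma
lipidome four times: before and after an early time-restricted-eating arm
(eTRE) and before and after a late arm (lTRE). Shotgun lipidomics reports
each lipid species as a molar amount (pmol per µL plasma). The analysis
asks, per lipid parameter, whether the parameter changed within an arm
(after vs before) and whether the two arms changed it differently, while
controlling the false discovery rate across the many parameters tested.

`lipidcross` implements this as a fixed sequence: parse → filter →
derive layers → paired contrasts → enrichment. Every step consumes and
emits plain TSV, so stages can be rerun and audited independently.

## Nomenclature and taxonomy

The parser implements the shorthand grammar used by shotgun-lipidomics
annotation: a class code from the fixed 14-class plasma taxonomy followed
by chain information. A single `C:DB;OH` block denotes a *sum species*
(totals only, chains unresolved); two or three blocks denote a
*subspecies*, joined by `_` when the sn-position on the glycerol is
unknown and `/` when it is resolved. Ether classes carry `O-` in the
class code and their first resolved chain is an alkyl ether. Totals of a
subspecies are defined as the chain sums and validated exactly; chain
bounds (C ≥ 1, 0 ≤ DB < C, 0 ≤ OH ≤ C) are enforced at construction.

Deliberate conventions, chosen where annotation exports vary:

- A missing `;OH` suffix is read as `;0` — exports frequently omit the
  hydroxylation count for glycerophospholipids.
- `CER` and `Cer` are aliases of the single class code `Cer`.
- Cholesterol is a chain-free species; it is excluded from all
  chain-derived layers.
- Single-block annotations are always classified sum species, including
  single-chain classes (CE, the lyso classes). Their chain identity is
  recoverable from the totals but is not treated as resolved.
- Sphingolipid (SM, Cer) totals include the long-chain base; the grammar
  never distinguishes sphingoid base from N-acyl, so their chains are
  considered unresolved unless written as an explicit two-chain form.
- Canonical form uses exactly one space between class code and chain
  block (none after `O-`); the parser tolerates repeated spaces.

## Prevalence filter

A species is *present* in a sample when its value is non-missing **and**
strictly positive — shotgun exports encode non-detects as blanks or
zeros interchangeably (`count_zero_as_present=True` switches to
missing-only semantics). Species present in less than the threshold
fraction (default 0.70) of **all** samples, pooled across arms and
timepoints, are excluded; a species at exactly the threshold is
retained, since the exclusion rule is "less than". The filter report
gives, per sample, retained molar sum / total molar sum — the fraction
of measured lipid content the analysis keeps.

## Analysis layers

All layers are feature × sample tables. Class totals and the double-bond
and chain-length subgroups (keys `PC`, `PC|db=1`, `PC|C=34`) partition
the species layer, so their per-sample sums equal the grand total
(asserted at 1e-9 relative in the tests). Missing member values are
excluded from sums; a feature whose members are all missing in a sample
stays missing there rather than becoming a spurious zero.

Fatty-acid totals are assessed *within complex lipids*: each resolved
chain contributes the full species amount to its `C:DB;OH` key, so a
two-chain species contributes twice. Sum species, cholesterol and
sphingolipids contribute nothing and are tallied in a skip report along
with their share of total content. Alkyl ether chains contribute under
their key by default (flagged in the report, switchable off); their mass
is minor and the indices use OH = 0 keys dominated by acyl chains.
Published index conventions often use free fatty acids; here the FA pool
is esterified FAs within complex lipids, which is what direct-infusion
lipidomics measures — the two conventions are not interchangeable and
this one is stated prominently for that reason.

The enzyme-activity indices are product/substrate amount ratios matched
on `C:DB` with OH = 0, pooled across all classes (one FA pool per
sample): D5D 20:4/20:3, D6D 18:3/18:2, D9D(C16) 16:1/16:0, D9D(C18)
18:1/18:0, D9D(C16+18) (16:1+18:1)/(16:0+18:0), ELOVL5 20:3/18:3,
ELOVL6 18:0/16:0. The two composite D9D variants follow the conventional
formulas for stearoyl-CoA desaturase surrogate indices; all definitions
are overridable via `IndexDefinition`, since conventions differ between
laboratories. An index is missing wherever its denominator is absent or
zero — missingness is the contract, not an error.

## Paired contrasts

Within-arm: per subject, Δ = after − before; between-arm: paired
comparison of Δ_eTRE vs Δ_lTRE per subject, with the additive summary
mean(Δ_lTRE − Δ_eTRE) (late-minus-early convention). Tests are two-sided
Wilcoxon signed-rank: zero differences are discarded before ranking
(classic convention; Pratt's method available via `zero_method`), the
null is the exact 2^n sign-flip distribution when the effective n ≤ 25
with untied |differences|, and a normal approximation with tie and
continuity correction otherwise. The reported statistic W is the smaller
of the two signed-rank sums.

Benjamini–Hochberg runs within each (layer × contrast) family — species,
classes, FAs, indices and subgroups are separate testing families, as
each layer answers a different scientific question; a global correction
across layers would double-penalize the same underlying signal. Missing
p-values pass through as missing and do not count toward the family
size. Significance is α = 0.05 throughout.

Fold change is the ratio of mean amounts, mean(after)/mean(before); for
the between contrast two conventions are emitted side by side, because
an "eTRE versus lTRE" fold-change axis does not determine one: the ratio
of within-arm fold changes FC_eTRE/FC_lTRE (`fold_change`) and the ratio
of mean deltas mean(Δ_eTRE)/mean(Δ_lTRE) (`delta_fold_change`). Additive
deltas carry Student-t 95% CIs on the per-subject deltas (CI undefined
below 2 pairs). Features with fewer than 3 complete pairs are flagged
underpowered but still tested when n ≥ 1. Subjects missing one arm
contribute to within-arm contrasts where complete and are dropped from
the between contrast. Descriptive output reports mean (SD) and median
(IQR) per feature with a Shapiro–Wilk normality label at α = 0.05,
purely for presentation.

Volcano tables carry fold change, −log10(raw p), BH significance, and
the largest raw p among BH-significant features (the plotted threshold
line); when nothing survives correction the threshold is reported as
undefined rather than invented.

## Pathway enrichment and gene overlay

Significant species are merged to their classes and tested pathway by
pathway with the one-sided hypergeometric tail P(X ≥ k) for k hit
classes among K pathway members in a universe of N classes, BH-corrected
across pathways. The universe must be restricted to classes mappable to
at least one pathway — unmappable members would silently deflate every
p-value, so the implementation rejects them instead. This is a
transparent re-implementation of class-level over-representation
analysis with user-supplied GMT annotations; equivalence with any
specific web tool's backend statistic or universe is not claimed.

The packaged annotation (`data/synthetic_pathways_*.gmt`) is a
hand-constructed miniature covering glycerophospholipid, sphingolipid,
glycerolipid, steroid and ether-lipid metabolism with domain-plausible
compound and gene membership. It exists so tests and examples run
without downloads; real analyses should supply a current annotation
export.

The overlay keeps differential-expression rows with mean FPKM strictly
greater than 1 and raw p strictly below 0.05 (both configurable; raw
rather than adjusted p is the default), intersects them with the
pathway's gene set, and labels direction by the sign of log2FC. The
filter is idempotent and order-independent; output is sorted by gene
symbol.

With ~200 true species-level discoveries at 5% FDR, the ~10 expected
false discoveries scatter across otherwise unaffected classes, so a
class-merged hit set can approach the whole universe and the
hypergeometric test loses resolution. This is an inherent property of
merging to 14 classes, not an implementation artifact; the enriched
pathway's rank is more stable than its p-value in that regime.

## Synthetic trials

The generator emulates the statistical structure the contrasts assume:

- **Panel** — 300 species by default, allocated over the 14 classes in
  proportions resembling shotgun plasma panels (TAG and PC largest,
  cholesterol a single species), with deterministic per-class name pools
  mixing sum species, `_` and `/` subspecies, ether and sphingolipid
  forms. Requesting a different n_species rescales the allocation.
- **Amounts** — log-normal:
  amount = exp(μ_class + a_i + b_s + ε) × m, with per-species offsets
  a_i ~ N(0, σ_species = 0.8), subject random effects
  b_s ~ N(0, σ_subject = 0.35) shared across a subject's four samples,
  replicate noise ε ~ N(0, σ_noise = 0.1), and m the product of
  applicable effect multipliers. Right-skewed molar amounts with
  within-subject correlation are exactly what the paired nonparametric
  analysis is designed for; the class-level log locations are set so
  per-sample totals land near 10⁴ pmol/µL with cholesterol, CE, TAG and
  PC dominating, as in plasma.
- **Effects** — multiplicative, applied only to "after" samples of the
  targeted arm, targeting a class code or an fnmatch species pattern;
  the ground truth records every affected species and the aggregate
  features it rolls into.
- **Missingness** — missing-completely-at-random dropout (rate 0.03)
  plus a deterministic detection floor (0.01 pmol/µL), exercising both
  presence definitions of the prevalence filter.

Everything derives from one seed through a single `default_rng` stream,
so a fixed (config, seed) pair reproduces the matrix exactly.

What the generator does **not** emulate: correlation between species
beyond shared class locations and subject effects, abundance-dependent
missingness beyond the hard floor, period or carry-over effects of the
crossover, batch/drift structure, and circadian variation. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed sampling model, not robustness to those real-data features.

## Verification sizes and expectations

The test suite checks the Wilcoxon implementation against exhaustive
2^n sign-flip enumeration (500 random datasets, n ≤ 12, agreement to
1e-12), BH against the direct step-up formula (1000 random vectors), the
hypergeometric tail against subset enumeration (universes to N = 12),
and conservation on the 300-species panel. Calibration experiments use
the trial sizes the generator defaults encode: a 500-feature null trial
at n = 30 for type-I rate and BH behaviour, and 100 simulated trials for
the recovery of a 0.8× ceramide effect in one arm (expected detection in
≥ 90% of trials; observed in practice ~100%, with the non-targeted arm
at its nominal family-wise error). `scripts/acceptance.py` re-runs all
of this from scratch and writes the measured numbers as JSON.

## Known limitations

- Sum species dominate classes like CE and TAG, so fatty-acid totals
  (and hence indices) draw only on the resolved subspecies fraction of
  the panel; the skip report quantifies the blind spot.
- No mixed-effects or sequence/period modeling of the crossover; the
  paired tests condition on subject and ignore order effects.
- The enrichment module's class-level universe is small (≤ 14), which
  bounds the achievable significance of any single pathway.
- Amounts are absolute molar quantities throughout; no mol%
  renormalization is offered.
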