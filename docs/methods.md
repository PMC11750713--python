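# Methods

## Model and assumptions

The assay model treats a plasma sample as a pool of unique cfDNA molecules.
Each panel target t contributes M_t observed unique molecules; a molecule is
alt-supporting either because it is tumor-derived (probability f, the tumor
fraction) or through a background conversion specific to the target's
substitution class (probability e_t per molecule). Aggregating over targets,
the observed signal k is modeled as Poisson with mean λ + f·M under the
null-plus-signal decomposition, where λ = Σ e_t·M_t. Detection is the
one-tailed test p = P(Poisson(λ) ≥ k), inclusive at the boundary
(p = 0.001 calls positive). This assumes target-level independence and that
per-molecule error events are rare enough for the Poisson approximation to
binomial sums to be exact for practical purposes (e_t ≤ 10⁻², M_t ~ 10³).

The ppm estimate 10⁶·k/M deliberately reports detected signal even below
the sample's LOD; detection status comes only from the p-value, never from a
tumor-fraction cutoff, so reported low-positive burdens remain comparable
across panels of different size and noise.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| AF threshold | 0.10 (strict >) | fraction | only confidently clonal tumor variants are worth tracking |
| GC window | 121 bp centered | bp | probe-scale window; ≥0.80 GC excluded |
| panel cap | 1,800 | targets | genome-wide panel size at which aggregation saturates assay CV |
| QA SNVs | 43 | SNVs | population frequency ≥0.20, HWE pass, outside HLA; chosen to minimize max−min subpopulation-frequency spread (seeded tie-break) |
| rate floor | 10⁻⁸ | per molecule | zero-observation classes keep a finite rate so λ never degenerates to 0 and p-values stay in (0,1] |
| Q mask | 29 | Phred | bases below Q29 masked before any comparison |
| read mask cap | 0.20 | fraction | reads dominated by masked bases are uninformative |
| divergence cap | 0.025 | fraction | reads >2.5% different from the provisional consensus are treated as contaminants of the positional group |
| agreement | 0.90 | fraction | consensus positions below 90% concordance are masked |
| p threshold | 0.001 | — | enforces ≥99.9% analytical specificity by construction |
| sensitivity target | 0.95 | — | defines the 95% LOD |

Ranking uses score = AF / e(s), descending — high tumor signal, low class
noise — with deterministic tie-breaks (lower error rate, higher AF, then
coordinate). A literal product AF·e(s) would preferentially select the
noisiest substitution classes and cannot produce ppm-scale detection limits;
the signal-to-noise ratio is the only ordering consistent with the assay's
stated performance, so it is the one implemented.

## Consensus rule order

The masking/filtering rules are applied in a fixed order: quality masking →
removal of heavily masked reads → provisional majority consensus →
divergence filter → final consensus with agreement masking → duplex check.
Quality masks must precede the divergence computation, otherwise low-quality
tails dominate the mismatch fraction. The divergence denominator counts only
positions unmasked in both the read and the provisional consensus. Group
splitting runs before consensus building: one split per group per pass
(most-supported allele first, deterministic tie-break), iterated to a
fixpoint; cross-group support counts any group in which the allele is
observed, including groups where it is the unanimous base — a genuine tumor
molecule elsewhere on the panel is exactly the kind of independent evidence
the rule is meant to capture. The duplex requirement is enforced per
molecule, not per base. Consensus reads are not re-aligned; coordinates pass
through from the input alignments.

A consequence worth knowing: split-off subgroups that isolate a single
error-bearing read fail the duplex rule and are discarded. This is the
intended behavior — the parent molecule survives with the error removed —
but it means the single-strand rejection counter grows with sequencing error
rate, not only with genuine single-strand families.

## LOD construction

The vendor's LOD formula is not public, so the package uses the natural
construction implied by the caller: k_crit = min{k : P(Poisson(λ) ≥ k) ≤
0.001}, then μ* = min{μ : P(Poisson(μ) ≥ k_crit) ≥ 0.95} by bisection, and
LOD₉₅ = 10⁶(μ* − λ)/M. A Monte-Carlo variant simulates detection on a
tumor-fraction grid and agrees within sampling error. Because k_crit is
discrete, the LOD is a sawtooth in λ: non-decreasing across k_crit
transitions but falling at slope 10⁶/M inside a plateau. At the reference
configuration (M = 3×10⁶, λ = 0.3) the LOD is ≈2.5 ppm, inside the 1–3 ppm
regime the assay targets.

## What the simulator emulates — and what it does not

The simulator generates: somatic call sets with a smoking-like,
transversion-heavy substitution spectrum (C>A/G>T 25% each) and Beta(5,5)
allele fractions; background cohorts with class-specific per-molecule error
rates (deamination-like transitions C>T/G>A at 5×10⁻⁶, A>G/T>C at 10⁻⁶,
transversions at 10⁻⁷ — post-consensus duplex-scale noise); and per-target
duplex read families with Poisson molecule yields (default 1,666
molecules/target, so a 1,800-target panel observes M ≈ 3×10⁶, the scale at
which the printed LODs arise), zero-truncated Poisson family sizes per
strand (mean 2), mononucleosomal fragments (166 ± 10 bp), uniform per-base
sequencing error 10⁻³, and a three-level Phred profile (94% Q37 / 5% Q25 /
1% Q11). All outputs are bit-reproducible from their seed.

Not emulated: sequencer-specific error spectra and context effects, GC and
mappability bias, FFPE damage, indels and structural variants,
overlapping-mate artifacts, CHIP variants beyond positional exclusion, and
alignment itself (reads are emitted pre-aligned; simulated fragment
coordinates are exact). Passing tests therefore demonstrate the statistical
machinery — noise suppression, calibration of the null, specificity, LOD,
and unbiased recovery — under idealized mapping, not robustness to
alignment or chemistry artifacts in real plasma.

## Numerical choices and degenerate inputs

- Poisson tails via `scipy.stats.poisson.sf(k−1, λ)`; equal to brute-force
  pmf summation within 10⁻¹² on the tested grid. Underflowing tails are
  clamped to the smallest positive double rather than 0.
- Majority/consensus ties resolve alphabetically (deterministic); a
  position with zero unmasked coverage is masked.
- Zero-yield targets contribute M_t = 0 and nothing to λ; an empty or
  all-inactive observation set is an error, as is M = 0 for ppm.
- Cohort stratification: detected samples exactly at the median go to the
  low group (conservative risk assignment); with no detections the median
  is unset and all samples are negative.
- Tumor molecules per ml = k / plasma ml with extraction efficiency fixed
  at 1; the constant cancels in any rank-based use.
- Problem sizes in the test suite are chosen for seconds-to-minutes desk
  runs: full-scale panels are exercised at the molecule-count level
  (M ≈ 3×10⁶ as in production), while read-level simulations use 10–25
  targets at a few hundred molecules each, which already yields >5,000
  confident consensus base calls for bounding the post-consensus error.

## Known limitations

- Positional consensus without UMIs undercounts molecules when two
  fragments share both endpoints and carry identical alleles; the splitter
  only separates collisions that differ at a corroborated allele.
- The error model is a single pooled rate per substitution class; real
  background varies by trinucleotide context and position.
- AF is used as the raw variant allele fraction, not a purity-adjusted
  cancer cell fraction.
- The LOD construction is a principled stand-in for an undisclosed
  proprietary formula; its outputs land in the published range but are not
  a reimplementation of the vendor's computation.
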