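# Methods

This note documents the models and procedures implemented in `polyshift`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Array preprocessing

One array compares mutant (channel 1) against wild type (channel 2) for a
single RNA pool (NP, P or T). The chain is:

1. **Background correction** — local, per spot: `I = fg − bg`. A spot where
   either channel is ≤ 0 after subtraction is flagged `negative_after_bg`
   and excluded rather than clamped to a floor; a clamped intensity would
   fabricate an extreme ratio where the data carry no signal.
2. **Intensity filter** — a spot is flagged `low_intensity` only when BOTH
   channels fall below the threshold (default: twice the median background).
   A spot with one bright channel is kept, because a strong ratio against a
   dim partner is exactly the kind of observation the downstream z-score is
   meant to find. Filtering changes membership only, never values.
3. **MA computation** — `M = log2(I1/I2)`, `A = (log2 I1 + log2 I2)/2`.
   Duplicate spots for one gene are averaged after the log transform: the
   log-ratio is the modeled quantity, so averaging happens on its scale.
4. **Lowess normalization** — `M′ = M − lowess(M ~ A)` with span 0.4 and
   3 robustness iterations (a common two-color default; the method choice
   is standard, the span is ours). Below 10 points the function refuses and
   advises a global-median fallback. A is never modified.

## Sliding-window z-score

Genes are sorted by A (ties broken by gene id for reproducibility) and each
gene's `M′` is standardized against the mean and sample (n−1) SD of the
`window_size` genes centered on it in A-rank space (default 50). A
point-count window rather than an A-width keeps the neighborhood size
stable in sparse intensity regions. The window always contains the focal
gene.

**Edge policy.** Default `slide`: windows at the ends of the A-order slide
inward so every window keeps its full point count (with `window_size = n`
the z-score reduces exactly to the global standardization of M). The
alternative `truncate` (symmetric windows clipped at the ends, never below
⌈w/2⌉ points) is available as configuration. Slide is the default because
truncated edge windows are both noisier (fewer points) and biased when a
real shift is present: a shifted gene's A moves by half its log-ratio, so
shifted genes pile up at the extremes of the A-order and a clipped edge
window can be dominated by them, deflating their own z-scores.

A window with zero spread yields z = 0 and a `degenerate_window` flag.
Replicates are z-scored independently and combined by the arithmetic mean;
genes seen in one replicate keep that value (`single_replicate` flag) and
sign-discordant replicates are averaged but flagged `discordant`.

## Classification

With combined z-scores per fraction and inclusive cutoffs
(`cutoff_shift = 1.5`, `cutoff_total = 2.0`):

* group I: `z_P ≤ −1.5` and `z_NP ≥ +1.5` and total unchanged;
* group II: `z_P ≥ +1.5` and `z_NP ≤ −1.5` and total unchanged;
* transcriptional up/down: `|z_T| > 2`, which vetoes a group call — a gene
  satisfying both rules is `indeterminate` with reasons
  `{concomitant_shift, total_changed}`, since transcription and translation
  cannot be separated for it;
* a missing `z_T` (transcript undetected on the total-RNA array) counts as
  total-unchanged: the validation panel keeps three such transcripts in the
  translational groups, so missingness must not veto;
* non-finite inputs give `indeterminate` with a named reason.

The total-RNA exclusion threshold is set to the transcriptome cutoff (2.0)
and is configurable; the boundary is inclusive on the shift side (a z of
exactly ±1.5 counts) because panel members sit exactly at 1.6/−1.6 while
1.58 must also pass.

## qPCR quantitation

* Relative expression (Pfaffl form): `R = E_t^ΔCt_t / E_ref^ΔCt_ref` with
  `ΔCt = Ct(control) − Ct(sample)` and efficiencies in (1, 2]. With both
  efficiencies 2 this is exactly `2^−ΔΔCt`.
* Relative quantity: `q = 2^−(ct − ct_ref)`.
* Fraction profiles: per gene and line, `q_f = E^−ct_f` per fraction,
  replicates averaged on the quantity scale (percentages are linear-scale
  statistics), then `%_f = 100·q_f / Σq`. Adding a constant to all Ct
  values cancels. An optional reference track (an unaffected transcript
  such as eIF4A measured over the same fractions) divides each fraction's
  quantity by the same-fraction control quantity before percentages,
  correcting fraction-to-fraction recovery; both modes are provided because
  published fold tables do not always state which was used.
* Signed fold change: ratio `r ≥ 1 → +r`, `r < 1 → −1/r`; no values exist
  in (−1, 1).
* A primer with unmeasured efficiency defaults to 2.0.

## Validation concordance

The packaged 23-transcript panel carries microarray z-triples, qPCR signed
folds, and printed verdicts. The rule applied is **P-fraction sign
agreement only**. This rule is an inference, not a published formula: the
panel prints rows with discordant NP folds as validated, while its three
"lack of correspondence" rows all disagree in P — P-sign agreement is the
only simple rule consistent with every printed label, and the test suite
pins exactly that correspondence (20/23 validated, 87%, the three l.c.
rows and no others failing). The confidence level is the raw validated
proportion rounded to an integer percent.

## UTR features

Coordinates in reports are 1-based inclusive; U and T are interchangeable
on input. Features per 5′UTR: length class (≥100 nt, boundary inclusive),
every AUG start (overlaps included), and uORFs — a uAUG followed in frame
by a stop codon wholly inside the UTR, with at least `min_internal_codons`
(default 1) codons between start and stop. 3′UTRs get length class and
motif scans.

**Folding.** The builtin engine is a Nussinov-style dynamic program over
nested structures: pair energies G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol, a
+4.0 kcal/mol penalty per hairpin loop, minimum loop 3 nt, sequences
shorter than 8 nt score 0. It is a deliberately simple additive surrogate
for a full thermodynamic folder; the −20 kcal/mol stability threshold is
meaningful only per engine, so the engine name is stamped into every
output row, and an external folder (e.g. RNAfold) can be plugged in — its
ΔG values are not interchangeable with the builtin's. Two exact symmetries
of the builtin model are tested: sequence reversal always preserves the
MFE, and reverse complementation preserves it only in the absence of G:U
wobble pairs (a G:U pair reverse-complements onto A:C, which cannot pair) —
so reverse-complement invariance is asserted on G/C-only sequences.

**Motifs.** The shipped patterns are documented stand-ins, fully
overridable: `cpe` is the canonical consensus UUUUUAU matched literally on
3′UTRs; `ires_like` is a pyrimidine-tract proxy (any window of ≥25 nt with
≥80% C/U, overlapping windows merged) on 5′UTRs. The original web-scanner
descriptors are not public and are not reproduced.

**Summaries.** Per group and feature, the percentage of records carrying
the feature; the random baseline column annotates a seeded sample
(default 80) from a user-supplied pool with the same engine and patterns.
Length-class percentages are complementary and sum to 100 per group. The
full-length filter is a pure membership filter with both `keep_listed` and
`drop_listed` modes; `keep_listed` is the default (retain accessions
verified full-length) but neither reading is asserted as canonical.

## Synthetic data

The generator exists to make every stage testable against planted truth.

* **Universe**: gene classes (group I/II, transcriptional up/down,
  unchanged) assigned by seeded permutation so planted genes scatter over
  the intensity range; base abundances `2^U(7, 13)` — the floor sits above
  the default low-intensity filter so the simulated universe models the
  detectable transcriptome. Shift effects are planted with the class's sign
  pattern (group I: NP +, P −, T 0; transcriptional: same sign everywhere).
* **Arrays**: `ch = background + base · 2^(shift + bias + ε)` with
  independent `ε ~ N(0, noise_sd)` per channel (lognormal intensity noise,
  the standard two-color error model) and an additive constant background.
  The dye bias is linear in the gene's true mean log2 intensity — the
  minimal trend Lowess must remove — and is computed from the true A rather
  than the observed one so the noise-free log-ratio has the exact closed
  form `b0 + b1·log2(base)`. Channel 1 is always the mutant; no dye swap is
  simulated. Defaults: 1000 genes, 2 replicates, noise sd 0.25, effect 1.5
  log2 — the recovery operating point exercised by the tests. The noise
  magnitude is our own choice (no published per-channel value exists for
  this array platform); 0.25 per channel gives a log-ratio SD of ≈0.35,
  typical of spotted two-color arrays.
* **Ct tables**: per gene, fraction weights drawn from a seeded Dirichlet
  around class-specific mean profiles (an ordinary transcript carries ~70%
  of its molecules on polysomes; group I moves mass to NP/M, group II to
  LP/HP), then `Ct = intercept − log_E(abundance) + noise`. The planted
  percentage profiles are returned alongside the records, which is what
  makes the noise-free round-trip test exact.
* **UTR sets**: background sequences use the {A, C} alphabet only — no
  base pair and no AUG or stop codon can occur by chance under the builtin
  model, so every feature present is planted. Planted uORFs are
  AUG + k codons + UAA; planted hairpins are a 10-pair G:C stem over a
  4-nt loop (ΔG ≤ −26 under the builtin model, safely below −20).

**What the synthetic tests do not show.** Real arrays have print-tip and
spatial structure, non-constant background, correlated channel noise, and
dye biases that are not linear in A; real UTRs have composition the {A,C}
background deliberately lacks; real Ct noise is heteroscedastic. Passing
the closed-loop tests demonstrates the correctness of the transformations
and the self-consistency of the pipeline at a realistic operating point,
not field performance on any particular scanner's output.

## Problem sizes and numerical choices

* Recovery is measured at the study conditions (1000 genes, 2 replicates,
  effect 1.5 log2, noise 0.25) pooled over 10 seeds; the pooled operating
  characteristic is sensitivity ≈ 0.92, FDP ≈ 0.001 at default cutoffs.
* The per-decile Lowess bias property uses 5000 genes: a decile's random
  mean scales as `0.35/√(n/10)`, and 500-point deciles make the 0.05 bound
  a test of systematic bias rather than of sampling noise.
* The folding oracle (exhaustive enumeration of nested structures) is run
  for lengths ≤ 12; the z-score brute-force oracle for n ≤ 200; both must
  agree with the engines to numerical precision (1e-9 / 1e-12).
* Degenerate inputs are flagged, not dropped: zero-spread windows
  (z = 0, flagged), negative-after-background spots, non-finite z-scores
  (indeterminate calls with named reasons).

## Known limitations

* Intensity-windowed z-scores weaken at the extremes of the A-order when
  planted (or real) shifts are large and numerous: the shift itself moves A
  by half the log-ratio, so strongly shifted genes congregate at the edges
  and inflate their own window statistics. At the study's effect size this
  is negligible; at effects ≳2.5 log2 with dense planting it measurably
  deflates edge z-scores.
* With zero noise and a planted dye bias, total-fraction window SDs
  collapse to the scale of Lowess fit wiggles and z_T becomes unstable;
  this is an artifact of exactly-zero residual noise and does not occur at
  any realistic noise level.
* The builtin folding model ignores stacking context, loop-size dependence
  and dangles; its ΔG ranks hairpin-rich sequences sensibly but is not
  comparable to thermodynamic folders.
* The concordance rule is reverse-engineered from the packaged panel (see
  above) and is only as authoritative as that panel.
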