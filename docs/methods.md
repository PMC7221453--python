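# Methods

## The selection model

One round of covalent selection is simulated per member with `n` input
molecules, in four stages whose counts form the audit trail
(`input ≥ bound ≥ post-wash ≥ post-elution`, asserted on every run):

1. **Binding + capture.** A covalent binder is labeled within incubation time
   `t` with probability `p_cov = 1 − exp(−k_obs·t)`, `k_obs =
   k_inact·[P]/(K_I + [P])` — the standard two-parameter description of
   time-dependent irreversible inhibition. A reversible binder occupies the
   target with probability `θ = [P]/([P] + K_d)`. Specifically bound
   molecules are recovered on the matrix with probability
   `capture_efficiency`, so the specific channel is
   `Binomial(n, p_spec · capture_efficiency)`.
2. **Matrix background.** Independently of protein binding, every molecule
   can adhere to the support: `Binomial(n, background_stick_prob)`, capped so
   the bound total never exceeds `n`. Background is modelled independently of
   the specific channel — adhesion is to the support, not the protein — which
   makes a binder's background identical to a nonbinder's by construction.
3. **Washes.** Background survives the wash series with
   `wash_retention^n_washes`; specifically bound molecules are not washed
   off. Only the *net* background probability is identified by the data, so
   the split between sticking and washing is a convention.
4. **Heat elution.** Each protein-bound reversible molecule is released with
   `reversible_release_prob` (default 1.0: complete elution at 80–95 °C,
   which is the premise of the single-round workflow; set it below 1 to model
   incomplete elution). Each covalent molecule is retained with
   `covalent_retention_prob` (default 0.95, allowing slight lability of the
   covalent adduct under heat). Matrix-stuck background is adhesion, not a
   protein–ligand complex, and survives elution unchanged.

Every retained molecule then receives an i.i.d. uniform UMI from the
`4^12 = 16,777,216`-sequence N12 space; collisions occur naturally and are
never prevented.

Design choice worth recording: an alternative formulation couples the
background channel to the same elution release probability as reversible
binders. That coupling cannot simultaneously keep a no-protein arm populated
(needed for any background comparison) and make reversible binders
indistinguishable from background after complete elution, so this package
treats background as elution-inert and puts the whole elution effect on the
protein-bound channels.

## Amplification and sequencing

* **qPCR.** The retained-molecule total is observed through lognormal noise
  of mean 1 and coefficient of variation `qpcr_cv` (default 0.1; 0 gives the
  truth).
* **Cycle selection.** The smallest cycle count `c` with expected amplicon
  concentration `n·(1+e)^c/(N_A·V)` at or above the lower edge of the
  3–40 nM loading window; the routine reports the achieved concentration and
  flags overshoot of the upper edge. For 10⁶ molecules at `e = 0.9` in 50 µL
  this gives 18 cycles and ≈3.46 nM.
* **PCR.** Per-molecule copy number follows a Galton–Watson process with
  offspring `1 + Bernoulli(e)`: mean `m^c` with `m = 1+e`, variance
  `e(1−e)·m^(c−1)(m^c−1)/(m−1)`. Exact per-cycle simulation is used when the
  expected total copies are ≤ 10⁴ (and serves as the oracle in tests);
  above that each molecule draws from a lognormal matched to both moments —
  exact simulation of ~1.9¹⁸ copies per molecule is not a sensible use of a
  desk machine, and the moment-matched approximation is verified against the
  exact mode at small scale.
* **Sequencing.** Exactly `n_reads` reads are sampled with probability
  proportional to copy number; each read is the error-free assembled tag of
  its source molecule with i.i.d. substitution errors at `seq_error_rate`
  per base (an erroneous base is uniform over the other three). Quality is a
  constant 'I'; no indels, no quality model, no paired ends.

## Decoding

Reads are sliced at fixed offsets (the schema tolerates up to 2 substitutions
per constant region; shorter reads are "truncated"). Each codon is matched
exactly or corrected to a unique Hamming-distance-1 codon; with books at
minimum pairwise distance 3 a single substitution can never cross to another
codon, which the tests verify exhaustively. The collapse key is
**(member, UMI)**, not the UMI alone: N12 identity marks duplicates *within*
a member's reads; the same N12 under two different members is a coincidence
of the random UMI space, not a duplicate. UMIs are compared by exact string
equality — errors inside the N12 therefore create phantom events and bias
`unique_events` upward, which is reported, not silently corrected (an
optional directional Hamming-1 clustering exists behind `cluster_umis=True`,
off by default). The collision-corrected `estimated_molecules =
−S·ln(1 − u/S)` is reported alongside the raw event count, never in place of
it.

## Enrichment

Counts are normalised to events per million assigned events. The score is
`log10((norm_t + α)/(norm_c + α))` with pseudocount α = 0.5 for stability at
zero counts; the z statistic `(c_t − r·c_c)/√(c_t + r²·c_c)` (r = depth
ratio) is a Poisson approximation cross-checked against the exact conditional
binomial test at small counts. No multiple-testing correction is applied by
default (a Benjamini–Hochberg option exists behind `fdr=True`): the goal is a
reproducible ranking, and "specifically enriched" is operationalised as a
spike-in score above the 99th percentile of the library-background score
distribution. Recovery uses the collision-corrected molecule estimate when
available and says so in its output column.

## The demo scenario and what it does (not) show

Defaults: 10,000 members at 10⁴ molecules each; two covalent tool compounds
× four tags at 10³–10⁶ molecules (the experimental 10⁶–10⁹ titration scaled
down three orders); 2 µM vs 0 µM protein; resin (capture 0.5, five washes,
80 °C) vs beads (capture 0.2, one wash, 95 °C); net background 10⁻³ per
molecule; 10⁶ reads per arm; per-base error 0.005. Tool-compound kinetics
are package conventions — compound A (k_inact 0.01 s⁻¹, K_I 1 µM) saturates
within the 1 h incubation, compound B (k_inact 2×10⁻⁴ s⁻¹) labels ~20 % — so
that event counts order with potency. The capture-matrix comparison runs the
tool compounds alone at 10³–10⁵ molecules with near-saturating coverage,
mirroring the titration design of the experiment it emulates; with the
library present, differential read-depth dilution between matrices would
confound per-tag recovery at low counts.

The generator emulates binding statistics, PCR duplication through shared
UMIs, and substitution errors. It does **not** emulate synthesis yield
variation, sequence-dependent PCR bias or chimeras, indels, quality-score
structure, protein denaturation kinetics, or rebinding during washes.
Passing tests therefore validate the counting and scoring machinery and the
internal consistency of the selection model — not the behaviour of any real
library on any real target.

## Numerical and scale choices

* All randomness flows from one `numpy` generator per run; identical config
  and seed reproduce outputs byte-identically.
* The cycle-selection ceiling is computed in log space with an integer guard
  against floating-point edge cases.
* Simulation sizes in the tests (2,000-member libraries at 2–4×10⁵ reads for
  the titration/recovery/null checks; the full 10,000-member, 10⁶-read demo
  for the signal-window and enrichment checks; 20 seed pairs for averaged
  statistics) were chosen as the smallest sizes at which the relevant
  statistics are stable, so the whole suite runs comfortably on one CPU.
* Degenerate inputs fail loudly: an empty retained pool cannot be sequenced,
  an empty count table cannot be normalised, a saturated UMI space cannot be
  inverted, and `signal_window` returns ±inf/NaN flags rather than raising.

## Known limitations

* The no-indel, fixed-offset read model makes decoding exact but brittle to
  real-world indel errors; an aligner-based decoder is out of scope.
* The branching-process approximation ignores PCR jackpot heterogeneity
  beyond its variance (no per-sequence efficiency differences).
* The background model is a single net probability; it cannot represent
  members with sequence-specific stickiness.
* Library diversity in the emulated experiment is quoted inconsistently at
  the million scale in its source (7.6 vs 7.2 million); diversity here is
  simply a free parameter.
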