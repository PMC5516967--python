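# Methods

## Model

The simulator evolves a fixed population of *N* compartments, each holding
exactly *M* strand slots. A slot holds a binary strand of length 0..*L*
(length 0 is the empty strand from which new polymers start). One time step
is one synchronous **elongation phase** followed by one **division phase**;
all reported round counts use this unit.

**Elongation.** The compartment's bias state is computed once per round from
a snapshot taken at the start of the round, so within-round update order
cannot matter and the update vectorizes cleanly. Every slot below the cap
then independently elongates with probability *r*; the added monomer is 0
with the compartment's zero-probability *p₀* and 1 otherwise. The bias rule:

* neutral, or no motif-containing strand: *p₀* = 0.5;
* single motif present (one or more motif-containing strands — presence, not
  abundance): *p₀* = *b* if the motif favors 0, else 1 − *b*;
* paired motifs (a pattern and its bitwise complement, equal intensities):
  the pattern contained in strictly more strands governs; equal counts
  (including 0–0) behave as neutral. Dominance is decided by counts of
  motif-containing strands, not occurrence counts or concentrations —
  presence/dominance is the modeled mechanism, and at *L* = 7 no strand can
  contain both members of a complementary length-5 pair, so the two count
  readings coincide apart from self-overlap multiplicity.

The bias applies to *every* addition in the compartment, including the first
monomer of an empty slot; each added monomer records a provenance label
(which motif governed, or none, at the snapshot).

**Division (Moran step).** A compartment chosen uniformly at random divides;
each of its non-empty strands is assigned independently and uniformly to one
of two daughters (binomial partition — the minimal reading of random
content distribution, matching protocell fission models); daughters are
padded back to *M* empty slots. One compartment chosen uniformly among the
resulting *N* + 1 (both daughters included; the parent no longer exists) is
eliminated. Strands are conserved through division: they are never
shortened, mutated, or duplicated.

Division rates are content-independent by construction — any selection in
this model is emergent through strand content alone.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| *N* | compartments | 100 | population size of the Moran process |
| *M* | strand slots per compartment | 100 | empty slots seed new polymers |
| *L* | maximum strand length | 7 | capped so a length-5 motif cannot repeat within a strand |
| *r* | per-round elongation probability per slot | 0.05 | ~ elongation:division ratio of *NMr* = 500 additions per division |
| *b* | probability of the favored monomer under motif governance | swept over [0.5, 1.0] | *b* = 0.5 is neutral |
| motif length | | 5 | 32 possible patterns |
| rounds / window | | 7000, sample (1000, 7000] | steady state is reached well before round 1000 |
| trials | independent replicates | 50 | reduced in the test suite (see below) |

## Observables

* **Motif frequency**: motif-containing strands / (*N* × *M*). The
  denominator is all slots (empty included) — the conserved system size —
  keeping frequencies comparable across rounds; a non-empty-strand
  denominator is exposed as an option.
* **Compartment motif frequency**: compartments with ≥ 1 motif strand / *N*.
* **Completion events**: a strand "completes" a motif when it newly becomes
  motif-containing during elongation (the completing occurrence necessarily
  ends at the terminus). Strands arriving via division are not new
  completions; events are pooled population-globally for inter-arrival
  statistics (gaps between consecutive completion rounds, from the first
  completion; simultaneous completions give gaps of 0).
* **Provenance histograms**: for each completed motif, the labels of its k
  positions — `+`/`-` (governed / not) in single-motif runs, `A`/`B`/`X` in
  paired runs, `X` also covering additions under a tie. Reported fractions
  are thresholded at 0.005 by default (raw distribution available).
* **Steady-state summaries**: per-trial time average over the window, then
  cross-trial mean with a two-sided 95% *t*-interval (conservative at
  moderate trial counts; the interval method is otherwise unconstrained).

## Analytics

* `containment_probability(pattern, l, p0)` — exact probability that an
  i.i.d. bit-string (0 w.p. *p₀* per position) contains the pattern,
  computed by a dynamic program over the pattern's KMP failure-function
  automaton with the accept state absorbing; correct for self-overlapping
  patterns. `enumerate_containment` computes the same quantity by brute
  force and exists purely as the independent oracle (they agree to < 1e-12
  over the verification grid).
* `primer_yield_fraction(k, pattern, ...)` — the fraction of the 2ᵏ
  equiprobable neutral strands of length *k* that come to contain the
  pattern under deterministic favored-monomer extension (the *b* = 1,
  *r* = 1 limit): 1/2, 3/4, 7/8, 7/16 for 10000 at *k* = 1..4, *L* = 7.
* `strand_length_distribution` — stationary law of the per-slot birth–death
  chain: elongate w.p. *r* below *L*; die (reset to empty) w.p. 1/(*N*+1),
  the per-round compartment-elimination probability, applied after
  elongation to match the round order. This chain is exact for expected
  slot counts because elimination is uniform over compartments, and the
  empirical length histogram of a neutral run matches it within Monte-Carlo
  error (tested at 3 SE per bin).
* `approx_motif_frequency` — Σ_l P(length = l) · P(contain | l, p₀) with
  p₀ = *b* for a 0-favoring motif: the primer-ignoring approximation of the
  per-slot motif probability. The neutral length distribution is used; a
  bias-dependent length distribution was considered and rejected as the
  less parsimonious reading (strand survival is content-independent, so
  bias does not alter lengths). Being an i.i.d. model it is
  reversal-invariant, hence identical for mirrored patterns — it tracks the
  unprimed member of a mirror pair, which is the point of the comparison.

## Numerical choices

* **Strand encoding**: a strand is the integer `(1 << l) | bits` with the
  first-added monomer as the most significant data bit; appending monomer
  *m* is `code*2 + m`, and the empty strand is code 1. Motif content of all
  2^(L+1) − 1 strand states is precomputed into a boolean table (built level
  by level with the automaton), so a round is a few vectorized table
  lookups over the N×M code matrix. Provenance labels pack the same way in
  base 3. L is capped at 16 to keep tables dense.
* **RNG**: three named PCG64 streams per trial (elongation mask, monomer
  type, division), spawned from one trial seed; trial seeds are 31-bit
  words derived from the experiment's base `SeedSequence`. Identical
  config + seed reproduces trajectories bitwise. The monomer draw is
  `0 iff u < p₀`, which makes the complement symmetry an exact coupling:
  complementing the motifs and replacing u by 1 − u (exact in binary
  floating point, u being a multiple of 2⁻⁵³) flips every monomer while
  leaving elongation and division draws untouched.
* **Ties and degenerate inputs**: paired-mode count ties are neutral by
  definition; balanced patterns (no strict monomer majority) are rejected
  when constructing cooperative/competitive pairs; elongating a strand at
  the cap is a contract violation (the simulator never attempts it);
  empty motif patterns are rejected everywhere.
* **Stationary distribution** of the length chain is solved as the
  least-squares solution of π(P − I) = 0 with Σπ = 1, clipped at 0.

## Test-suite scales

The suite reproduces the headline steady-state findings at the standard
conditions (N = 100, M = 100, L = 7, r = 0.05, motif length 5) with 3000
rounds, a (1000, 3000] sampling window, and 20 trials per experiment —
steady state is reached by ~600 rounds, so the shortened window measures
the same regime while keeping the full grid (12 experiments) to a few
minutes. `scripts/acceptance.py` uses the same conditions at 10 trials.
Exact checks (primer fractions, automaton vs enumeration) run at full size.

## What the simulations do and do not show

The generator *is* the model: all inputs are configurations, and every
reported number is an emergent property of the simulated dynamics, so
passing tests show internal consistency of the model and reproduction of
its qualitative findings (rank orders, maxima, symmetry breaking), not
statements about real chemistry. Real prebiotic systems have larger
alphabets, concentration-dependent (not presence/dominance) bias, strand
degradation, monomer-pool depletion, and non-binary division — all outside
this model's scope by design. Figure-level frequency *values* are
plot-read quantities; the package asserts the orderings and shapes they
support, not their pixel values.

## Known limitations

* Alphabet fixed to {0, 1}; contiguous motifs only; at most two motifs.
* Bias intensity is shared within a pair; no concentration dependence.
* L ≤ 16 (dense state tables); for the standard L = 7 this is irrelevant.
* The complement-coupling equality can in principle miss at a draw landing
  exactly on the bias boundary (probability ~2⁻⁵² per draw).
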