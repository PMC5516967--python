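"""Exact combinatorics and the enumeration-weighted frequency approximation.

This module is the simulator's independent analytical counterpart:

* the probability that an i.i.d. random bit-string contains a pattern,
  computed exactly by dynamic programming over the pattern's failure-function
  automaton (correct for self-overlapping patterns), with brute-force
  enumeration kept alongside as the independent oracle;
* primer-yield fractions in the deterministic limiting regime b = 1, r = 1
  (which fraction of the equiprobable neutral strands of a given length
  comes to contain the motif when only the favored monomer is appended);
* the stationary strand-length distribution, either from a per-slot
  birth-death chain (elongate with probability r below the cap; die with the
  per-round compartment-elimination probability 1/(N+1)) or harvested from a
  neutral simulation;
* the primer-ignoring approximation of the steady-state motif frequency:
  containment probability under the motif's biased composition, averaged
  over the strand-length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .compartments import BiasConfig
from .sequence import pattern_automaton
from .simulate import ExperimentConfig, division_phase, elongation_phase, initiate

__all__ = [
    "LengthDistribution",
    "containment_probability",
    "enumerate_containment",
    "primer_yield_fraction",
    "strand_length_distribution",
    "approx_motif_frequency",
    "approx_curve",
]


def containment_probability(pattern: str, length: int, p0: float) -> float:
    """Exact P(an i.i.d. bit-string of ``length`` contains ``pattern``).

    Each position is 0 with probability ``p0`` independently. The automaton
    dynamic program tracks the longest pattern prefix matched so far, with
    the full match absorbing, so self-overlapping patterns (101, 10101, ...)
    are handled exactly.
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    trans = pattern_automaton(pattern)
    k = trans.shape[0] - 1
    dist = np.zeros(k + 1)
    dist[0] = 1.0
    step = np.zeros((k + 1, k + 1))
    for s in range(k + 1):
        step[s, trans[s, 0]] += p0
        step[s, trans[s, 1]] += 1.0 - p0
    for _ in range(length):
        dist = dist @ step
    return float(dist[k])


def enumerate_containment(pattern: str, length: int, p0: float) -> float:
    """Same quantity by brute-force enumeration of all 2**length strings.

    Kept as the independent oracle for :func:`containment_probability`;
    guarded at length <= 20 for tractability.
    """
    if not 0 <= length <= 20:
        raise ValueError(f"enumeration is limited to lengths 0..20, got {length}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if len(pattern) > length:
        return 0.0
    total = 0.0
    for bits in product("01", repeat=length):
        s = "".join(bits)
        if pattern in s:
            zeros = s.count("0")
            total += p0**zeros * (1.0 - p0) ** (length - zeros)
    return total


def primer_yield_fraction(
    primer_length: int,
    pattern: str,
    cap: int | None = None,
    favored: int = 0,
    steps: int | None = None,
) -> float:
    """Fraction of the 2**k neutral strands of length k that come to contain
    ``pattern`` under deterministic favored-monomer elongation (the b = 1
    limit).

    Extension appends ``favored`` until the strand reaches ``cap``, or for
    exactly ``steps`` additions when ``steps`` is given.
    """
    if primer_length < 0:
        raise ValueError(f"primer_length must be >= 0, got {primer_length}")
    if favored not in (0, 1):
        raise ValueError(f"favored must be 0 or 1, got {favored!r}")
    if steps is None:
        if cap is None:
            raise ValueError("give either cap or steps")
        if cap < len(pattern):
            raise ValueError(f"cap {cap} is shorter than the pattern {pattern!r}")
        n_extra = max(cap - primer_length, 0)
    else:
        n_extra = steps
    tail = str(favored) * n_extra
    hits = sum(
        1
        for bits in product("01", repeat=primer_length)
        if pattern in "".join(bits) + tail
    )
    return hits / 2**primer_length


@dataclass(frozen=True)
class LengthDistribution:
    """Probability mass over strand lengths 0..L."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("probs must be a 1-d array over lengths 0..L")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("length masses must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def L(self) -> int:
        return self.probs.size - 1


def strand_length_distribution(
    r: float,
    N: int,
    L: int = 7,
    mode: str = "markov",
    M: int = 100,
    rounds: int = 1200,
    burn_in: int = 400,
    trials: int = 4,
    seed: int = 0,
) -> LengthDistribution:
    """Stationary distribution of per-slot strand length.

    ``mode="markov"``: stationary law of the birth-death chain in which a
    slot elongates with probability r per round while below L and is reset
    to empty with the per-round compartment-elimination probability
    1/(N+1) (elongation applied before death, matching the round order).
    ``mode="empirical"``: length histogram harvested from a neutral
    simulation over the rounds after ``burn_in``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if mode == "markov":
        if r == 0.0:
            probs = np.zeros(L + 1)
            probs[0] = 1.0
            return LengthDistribution(probs)
        d = 1.0 / (N + 1)
        P = np.zeros((L + 1, L + 1))
        for l in range(L + 1):
            if l < L:
                P[l, l + 1] += (1.0 - d) * r
                P[l, l] += (1.0 - d) * (1.0 - r)
            else:
                P[l, l] += 1.0 - d
            P[l, 0] += d
        # stationary law: solve pi (P - I) = 0 with sum(pi) = 1
        A = np.vstack([(P - np.eye(L + 1)).T, np.ones(L + 1)])
        b = np.zeros(L + 2)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return LengthDistribution(pi / pi.sum())
    if mode == "empirical":
        config = ExperimentConfig(
            bias=BiasConfig.neutral(),
            N=N,
            M=M,
            L=L,
            r=r,
            rounds=rounds,
            burn_in=burn_in,
            sample_end=rounds,
            trials=trials,
            seed=seed,
        )
        counts = np.zeros(L + 1)
        from .simulate import derive_trial_seeds

        for trial_seed in derive_trial_seeds(seed, trials):
            state = initiate(config, seed=trial_seed)
            for t in range(rounds):
                elongation_phase(state, config)
                division_phase(state, config)
                if t >= burn_in:
                    counts += np.bincount(
                        state.lengths().ravel(), minlength=L + 1
                    )
        return LengthDistribution(counts / counts.sum())
    raise ValueError(f"mode must be 'markov' or 'empirical', got {mode!r}")


def approx_motif_frequency(
    pattern: str, p0: float, length_dist: LengthDistribution
) -> float:
    """Primer-ignoring approximation of the per-slot motif probability.

    Every position is drawn i.i.d. with the motif's biased composition
    (0 with probability ``p0``); containment probabilities are weighted by
    the probability that a strand reaches each length. Because the i.i.d.
    model is reversal-invariant, mirrored patterns get identical curves —
    the approximation tracks the non-primed member of a mirror pair.
    """
    return float(
        sum(
            length_dist.probs[l] * containment_probability(pattern, l, p0)
            for l in range(length_dist.L + 1)
        )
    )


def approx_curve(
    pattern: str,
    biases,
    length_dist: LengthDistribution,
    favored_monomer: int = 0,
) -> pd.DataFrame:
    """Approximation swept over a bias grid, as a tidy table.

    ``b`` is the probability of the favored monomer, so the i.i.d. position
    composition is p0 = b for a 0-favoring motif and p0 = 1 - b otherwise.
    """
    if favored_monomer not in (0, 1):
        raise ValueError(f"favored_monomer must be 0 or 1, got {favored_monomer!r}")
    rows = []
    for b in biases:
        p0 = b if favored_monomer == 0 else 1.0 - b
        rows.append(
            {
                "pattern": pattern,
                "b": float(b),
                "length_cap": length_dist.L,
                "approx_frequency": approx_motif_frequency(pattern, p0, length_dist),
            }
        )
    return pd.DataFrame(rows, columns=["pattern", "b", "length_cap", "approx_frequency"])
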