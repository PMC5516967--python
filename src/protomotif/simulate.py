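"""Population-level engine: initiation, elongation, Moran division, trials.

One round (time step) is one synchronous elongation phase followed by one
division phase:

* **Elongation** — each compartment's bias is computed once from a snapshot
  taken at the start of the round, so within-round update order cannot
  matter. Every slot below the length cap L (empty slots included)
  independently elongates with probability r; the added monomer is 0 with
  the compartment's zero-probability, else 1, and the monomer's provenance
  label records which motif (if any) governed the compartment.
* **Division** — a compartment chosen uniformly at random divides; each of
  its non-empty strands goes independently and uniformly to one of two
  daughters (each padded back to M empty slots); then one compartment chosen
  uniformly among the resulting N+1 is eliminated, returning the count to N.

The population is held as integer-coded arrays (see :mod:`.sequence`), so a
round is a handful of vectorized table lookups and arithmetic ops over the
N x M slot matrix.

Randomness is split into three named streams (elongation mask, monomer type,
division) spawned from one trial seed, which keeps trajectories bitwise
reproducible and makes the complement-coupling symmetry exact: the monomer
draw is ``0 iff u < P(0)``, so flipping u -> 1-u together with complementing
the motifs flips every monomer while leaving all other draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .compartments import BiasConfig, Compartment
from .sequence import (
    EMPTY_CODE,
    LABEL_NONE,
    Strand,
    code_lengths,
    containment_table,
    decode_bits,
    decode_provenance,
    encode_bits,
    encode_provenance,
)

__all__ = [
    "ExperimentConfig",
    "PopulationState",
    "TrajectoryRecord",
    "initiate",
    "elongation_phase",
    "division_phase",
    "run_trial",
    "run_experiment",
    "derive_trial_seeds",
]

_MAX_L = 16  # containment tables are dense over 2**(L+1) strand states


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one experiment (shared by all its trials).

    Defaults are the standard study conditions: N = 100 compartments of
    M = 100 slots, length cap L = 7, per-round elongation probability
    r = 0.05, motifs of length 5, steady-state window (1000, 7000] sampled
    over 50 trials.
    """

    bias: BiasConfig = field(default_factory=BiasConfig.neutral)
    N: int = 100
    M: int = 100
    L: int = 7
    r: float = 0.05
    rounds: int = 7000
    burn_in: int = 1000
    sample_end: int = 7000
    trials: int = 50
    seed: int = 0
    track_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.N < 1 or self.M < 1:
            raise ValueError(f"N and M must be >= 1, got N={self.N}, M={self.M}")
        if not 1 <= self.L <= _MAX_L:
            raise ValueError(f"L must be in [1, {_MAX_L}], got {self.L}")
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"r must be in (0, 1], got {self.r}")
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        if not 0 <= self.burn_in < self.sample_end <= self.rounds:
            raise ValueError(
                f"need 0 <= burn_in < sample_end <= rounds, got "
                f"burn_in={self.burn_in}, sample_end={self.sample_end}, rounds={self.rounds}"
            )
        if self.trials < 1:
            raise ValueError(f"trials must be >= 1, got {self.trials}")
        for motif in self.bias.motifs:
            if len(motif.pattern) > self.L:
                raise ValueError(
                    f"motif pattern {motif.pattern!r} longer than the strand cap L={self.L}"
                )
        for pat in self.track_patterns:
            if len(pat) > self.L:
                raise ValueError(f"tracked pattern {pat!r} longer than L={self.L}")

    @property
    def patterns(self) -> tuple[str, ...]:
        """All patterns whose statistics are recorded: bias motifs, then extras."""
        pats = [m.pattern for m in self.bias.motifs]
        for p in self.track_patterns:
            if p not in pats:
                pats.append(p)
        return tuple(pats)


@dataclass
class PopulationState:
    """N compartments of M integer-coded strand slots plus the round counter."""

    codes: np.ndarray  # (N, M) int64, sentinel-prefixed strand codes
    prov: np.ndarray  # (N, M) int64, base-3 packed provenance labels
    comp_ids: np.ndarray  # (N,) int64, lineage bookkeeping
    round: int = 0
    next_id: int = 0
    rng: dict | None = None  # named Generator streams, set by initiate()

    @property
    def N(self) -> int:
        return self.codes.shape[0]

    @property
    def M(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def empty(cls, N: int, M: int) -> "PopulationState":
        return cls(
            codes=np.full((N, M), EMPTY_CODE, dtype=np.int64),
            prov=np.zeros((N, M), dtype=np.int64),
            comp_ids=np.arange(N, dtype=np.int64),
            round=0,
            next_id=N,
        )

    @classmethod
    def from_bits(cls, compartments: list[list[str]], M: int) -> "PopulationState":
        """Build a state from explicit strand strings (tests and fixtures)."""
        N = len(compartments)
        state = cls.empty(N, M)
        for i, strands in enumerate(compartments):
            if len(strands) > M:
                raise ValueError(f"compartment {i} holds {len(strands)} strands > M={M}")
            for j, bits in enumerate(strands):
                state.codes[i, j] = encode_bits(bits)
        return state

    def lengths(self) -> np.ndarray:
        return code_lengths(self.codes)

    def to_compartments(self) -> list[Compartment]:
        out = []
        for i in range(self.N):
            strands = []
            for j in range(self.M):
                bits = decode_bits(int(self.codes[i, j]))
                labels = decode_provenance(int(self.prov[i, j]), len(bits))
                strands.append(Strand(bits, labels))
            out.append(Compartment(strands, id=int(self.comp_ids[i])))
        return out

    def copy(self) -> "PopulationState":
        return PopulationState(
            codes=self.codes.copy(),
            prov=self.prov.copy(),
            comp_ids=self.comp_ids.copy(),
            round=self.round,
            next_id=self.next_id,
            rng=self.rng,
        )


class _Runtime:
    """Precomputed per-config constants for the vectorized round."""

    def __init__(self, config: ExperimentConfig):
        self.patterns = config.patterns
        self.tables = [containment_table(p, config.L) for p in self.patterns]
        self.pow3 = [3 ** len(p) for p in self.patterns]
        self.full_min = 1 << config.L  # codes >= this are at the cap
        self.mode = config.bias.mode
        if self.mode != "neutral":
            self.p0_a = config.bias.motif_a.zero_probability
        if self.mode == "paired":
            self.p0_b = config.bias.motif_b.zero_probability


def initiate(config: ExperimentConfig, seed: int | None = None) -> PopulationState:
    """Fresh population of N compartments with M empty slots each, round 0."""
    state = PopulationState.empty(config.N, config.M)
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    elong, monomer, division = [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3)]
    state.rng = {"elongation": elong, "monomer": monomer, "division": division}
    return state


def _zero_prob_and_labels(state, runtime):
    """Per-compartment P(0) and provenance label from the start-of-round snapshot."""
    if runtime.mode == "neutral":
        p0 = np.full(state.N, 0.5)
        labels = np.zeros(state.N, dtype=np.int64)
        contains = None
    elif runtime.mode == "single":
        contains = runtime.tables[0][state.codes]
        present = contains.any(axis=1)
        p0 = np.where(present, runtime.p0_a, 0.5)
        labels = present.astype(np.int64)  # LABEL_A where governed
    else:
        contains = None
        c_a = runtime.tables[0][state.codes].sum(axis=1)
        c_b = runtime.tables[1][state.codes].sum(axis=1)
        p0 = np.full(state.N, 0.5)
        labels = np.zeros(state.N, dtype=np.int64)
        a_dom = c_a > c_b
        b_dom = c_b > c_a
        p0[a_dom] = runtime.p0_a
        p0[b_dom] = runtime.p0_b
        labels[a_dom] = 1
        labels[b_dom] = 2
    return p0, labels


def elongation_phase(
    state: PopulationState,
    config: ExperimentConfig,
    runtime: _Runtime | None = None,
    _flip_monomer_u: bool = False,
):
    """One synchronous elongation phase, in place.

    Returns completion events for strands that newly became motif-containing
    this round, as a list with one ``(comp_index, comp_id, prov_pattern)``
    array triple per tracked pattern. ``_flip_monomer_u`` replaces every
    monomer uniform u by 1 - u (the exact bit-flip coupling used by the
    complement-symmetry checks).
    """
    if runtime is None:
        runtime = _Runtime(config)
    if state.rng is None:
        raise ValueError("state has no RNG streams; build it with initiate()")
    codes = state.codes
    prov = state.prov
    before = [table[codes] for table in runtime.tables]
    p0, labels = _zero_prob_and_labels(state, runtime)

    u_grow = state.rng["elongation"].random(codes.shape)
    u_mono = state.rng["monomer"].random(codes.shape)
    if _flip_monomer_u:
        u_mono = 1.0 - u_mono  # exact: u is a multiple of 2**-53
    grow = (u_grow < config.r) & (codes < runtime.full_min)
    monomer = (u_mono >= p0[:, None]).astype(np.int64)  # 0 iff u < P(0)
    np.copyto(codes, codes * 2 + monomer, where=grow)
    np.copyto(prov, prov * 3 + labels[:, None], where=grow)

    events = []
    for k, table in enumerate(runtime.tables):
        new = table[codes] & ~before[k]
        if new.any():
            ci, si = np.nonzero(new)
            events.append(
                (ci, state.comp_ids[ci], prov[ci, si] % runtime.pow3[k])
            )
        else:
            empty = np.empty(0, dtype=np.int64)
            events.append((empty, empty, empty))
    return events


def division_phase(state: PopulationState, config: ExperimentConfig) -> None:
    """One Moran division step, in place.

    A uniformly chosen compartment divides; its strands are partitioned
    binomially between two daughters; one of the N+1 compartments (both
    daughters included — the parent no longer exists) is eliminated
    uniformly at random.
    """
    if state.rng is None:
        raise ValueError("state has no RNG streams; build it with initiate()")
    rng = state.rng["division"]
    N, M = state.N, state.M
    parent = int(rng.integers(N))
    kill = int(rng.integers(N + 1))
    u = rng.random(M)

    row_c = state.codes[parent]
    row_p = state.prov[parent]
    nonempty = row_c != EMPTY_CODE
    to0 = nonempty & (u < 0.5)
    to1 = nonempty & (u >= 0.5)

    d_codes = [np.full(M, EMPTY_CODE, dtype=np.int64) for _ in range(2)]
    d_prov = [np.zeros(M, dtype=np.int64) for _ in range(2)]
    for d, sel in ((0, to0), (1, to1)):
        n = int(sel.sum())
        d_codes[d][:n] = row_c[sel]
        d_prov[d][:n] = row_p[sel]
    id0, id1 = state.next_id, state.next_id + 1
    state.next_id += 2

    # the N+1 candidates for elimination: rows != parent, daughter 0 (in the
    # parent's row), and daughter 1 (virtual index N)
    def place(row, d):
        state.codes[row] = d_codes[d]
        state.prov[row] = d_prov[d]
        state.comp_ids[row] = (id0, id1)[d]

    if kill == N:  # daughter 1 eliminated
        place(parent, 0)
    elif kill == parent:  # daughter 0 eliminated
        place(parent, 1)
    else:  # another compartment eliminated; both daughters survive
        place(parent, 0)
        place(kill, 1)


@dataclass
class TrajectoryRecord:
    """Per-round observables and event logs of one trial.

    Row t of the frequency arrays is the state at the end of round t+1.
    ``prov_counts[k]`` counts, for each base-3 packed label pattern, the
    motif completions of tracked pattern k over the whole trial.
    """

    config: ExperimentConfig
    trial_seed: int
    patterns: tuple[str, ...]
    motif_freq: np.ndarray  # (rounds, n_patterns)
    comp_freq: np.ndarray  # (rounds, n_patterns)
    event_rounds: np.ndarray  # (E,) round index of each completion
    event_comp_ids: np.ndarray  # (E,)
    event_pattern_idx: np.ndarray  # (E,) index into patterns
    prov_counts: list[np.ndarray]

    def completion_rounds(self, pattern: str) -> np.ndarray:
        """Rounds at which new copies of ``pattern`` were completed (sorted)."""
        k = self.patterns.index(pattern)
        return self.event_rounds[self.event_pattern_idx == k]


def run_trial(
    config: ExperimentConfig,
    trial_seed: int,
    _flip_monomer_u: bool = False,
) -> TrajectoryRecord:
    """Execute one trial of ``config.rounds`` rounds and record observables."""
    runtime = _Runtime(config)
    state = initiate(config, seed=trial_seed)
    n_pat = len(runtime.patterns)
    slots = config.N * config.M
    motif_freq = np.zeros((config.rounds, n_pat))
    comp_freq = np.zeros((config.rounds, n_pat))
    ev_rounds: list[np.ndarray] = []
    ev_comp: list[np.ndarray] = []
    ev_pat: list[np.ndarray] = []
    prov_counts = [np.zeros(runtime.pow3[k], dtype=np.int64) for k in range(n_pat)]

    for t in range(config.rounds):
        events = elongation_phase(state, config, runtime, _flip_monomer_u)
        for k, (_, comp_ids, pats) in enumerate(events):
            if comp_ids.size:
                ev_rounds.append(np.full(comp_ids.size, t + 1, dtype=np.int64))
                ev_comp.append(comp_ids.astype(np.int64))
                ev_pat.append(np.full(comp_ids.size, k, dtype=np.int64))
                np.add.at(prov_counts[k], pats, 1)
        division_phase(state, config)
        state.round = t + 1
        for k, table in enumerate(runtime.tables):
            contains = table[state.codes]
            motif_freq[t, k] = contains.sum() / slots
            comp_freq[t, k] = contains.any(axis=1).sum() / config.N

    cat = lambda parts: (
        np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    )
    return TrajectoryRecord(
        config=config,
        trial_seed=trial_seed,
        patterns=runtime.patterns,
        motif_freq=motif_freq,
        comp_freq=comp_freq,
        event_rounds=cat(ev_rounds),
        event_comp_ids=cat(ev_comp),
        event_pattern_idx=cat(ev_pat),
        prov_counts=prov_counts,
    )


def derive_trial_seeds(base_seed: int, trials: int) -> list[int]:
    """Deterministic per-trial seeds: 31-bit words drawn from the base
    SeedSequence's state stream (documented, reproducible derivation)."""
    words = np.random.SeedSequence(base_seed).generate_state(trials, dtype=np.uint64)
    return [int(w >> 33) for w in words]


def run_experiment(config: ExperimentConfig) -> list[TrajectoryRecord]:
    """Run ``config.trials`` independent trials with derived seeds."""
    seeds = derive_trial_seeds(config.seed, config.trials)
    return [run_trial(config, s) for s in seeds]
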