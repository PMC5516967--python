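"""Statistics over population states and trial trajectories.

Covers the reported observables of the model: motif frequency (fraction of
strand slots whose strand contains the motif), compartment-level motif
frequency (fraction of compartments holding at least one motif strand),
inter-arrival times of motif completions, provenance (elongation-pattern)
histograms, and steady-state time averages with cross-trial confidence
intervals.

Frequency denominators default to all N x M slots (empty included) — the
conserved system size — which keeps frequencies comparable across rounds;
the non-empty-strand denominator is exposed as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sequence import EMPTY_CODE, containment_table
from .simulate import ExperimentConfig, PopulationState, TrajectoryRecord

__all__ = [
    "SteadyStateSummary",
    "motif_frequency",
    "compartment_motif_frequency",
    "interarrival_times",
    "provenance_histogram",
    "steady_state_summary",
]


def motif_frequency(
    state: PopulationState, pattern: str, denominator: str = "slots"
) -> float:
    """Fraction of strand slots whose strand contains ``pattern``.

    ``denominator="slots"`` divides by N x M (all slots, empty included);
    ``denominator="nonempty"`` divides by the current number of non-empty
    strands (0 if there are none).
    """
    table = containment_table(pattern, _max_len(state))
    count = int(table[state.codes].sum())
    if denominator == "slots":
        return count / state.codes.size
    if denominator == "nonempty":
        nonempty = int((state.codes != EMPTY_CODE).sum())
        return count / nonempty if nonempty else 0.0
    raise ValueError(f"denominator must be 'slots' or 'nonempty', got {denominator!r}")


def compartment_motif_frequency(state: PopulationState, pattern: str) -> float:
    """Fraction of compartments containing at least one motif strand."""
    table = containment_table(pattern, _max_len(state))
    return int(table[state.codes].any(axis=1).sum()) / state.N


def _max_len(state: PopulationState) -> int:
    return int(state.lengths().max(initial=0))


def interarrival_times(event_rounds) -> np.ndarray:
    """Round gaps between consecutive motif completions.

    Measured from the first completion onwards; completions in the same
    round give gaps of 0; fewer than two events give an empty array.
    """
    rounds = np.asarray(event_rounds, dtype=np.int64)
    if rounds.size and np.any(np.diff(rounds) < 0):
        raise ValueError("event rounds must be sorted (non-decreasing)")
    if rounds.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(rounds)


# provenance label rendering per bias mode: single-motif runs mark each
# position +/- for governed/ungoverned; paired runs mark A/B/X
_PAIRED_CHARS = {0: "X", 1: "A", 2: "B"}
_SINGLE_CHARS = {0: "-", 1: "+"}


def _render_pattern(packed: int, length: int, chars: dict[int, str]) -> str:
    digits = []
    for _ in range(length):
        digits.append(chars[packed % 3])
        packed //= 3
    return "".join(reversed(digits))


def provenance_histogram(
    records: list[TrajectoryRecord],
    pattern: str | None = None,
    min_frequency: float = 0.005,
) -> dict[str, float]:
    """Fractions of completed motif strands by exact provenance label pattern.

    Pools completions across the given trials. Each completed motif
    contributes the labels of its k motif positions (the occurrence that
    completes a motif always ends at the terminus, so these are the last k
    labels at completion time). Patterns below ``min_frequency`` are dropped
    from the mapping; pass ``min_frequency=0`` for the raw distribution.
    """
    if not records:
        raise ValueError("no trajectory records given")
    patterns = records[0].patterns
    if pattern is None:
        if len(patterns) != 1:
            raise ValueError(f"records track several patterns {patterns}; pick one")
        pattern = patterns[0]
    k = patterns.index(pattern)
    counts = np.zeros_like(records[0].prov_counts[k])
    for rec in records:
        if rec.patterns != patterns:
            raise ValueError("records track different pattern sets")
        counts = counts + rec.prov_counts[k]
    total = int(counts.sum())
    if total == 0:
        return {}
    chars = _PAIRED_CHARS if records[0].config.bias.mode == "paired" else _SINGLE_CHARS
    length = len(pattern)
    out = {}
    for packed in np.nonzero(counts)[0]:
        frac = counts[packed] / total
        if frac >= min_frequency:
            out[_render_pattern(int(packed), length, chars)] = float(frac)
    return out


@dataclass(frozen=True)
class SteadyStateSummary:
    """Cross-trial summary of a steady-state time-averaged frequency."""

    pattern: str
    mean: float
    ci_half_width: float
    per_trial: np.ndarray  # (trials,) per-trial window means
    burn_in: int
    sample_end: int

    @property
    def ci_low(self) -> float:
        return self.mean - self.ci_half_width

    @property
    def ci_high(self) -> float:
        return self.mean + self.ci_half_width


def steady_state_summary(
    records: list[TrajectoryRecord],
    pattern: str,
    burn_in: int | None = None,
    sample_end: int | None = None,
    which: str = "motif",
) -> SteadyStateSummary:
    """Steady-state frequency of ``pattern``: window mean per trial, then
    cross-trial mean with a two-sided 95% t-interval.

    The window is the rounds in ``(burn_in, sample_end]`` (defaults from the
    records' config). ``which`` selects strand-level (``"motif"``) or
    compartment-level (``"compartment"``) frequency.
    """
    if not records:
        raise ValueError("no trajectory records given")
    cfg = records[0].config
    burn_in = cfg.burn_in if burn_in is None else burn_in
    sample_end = cfg.sample_end if sample_end is None else sample_end
    rounds = records[0].motif_freq.shape[0]
    if not 0 <= burn_in < sample_end <= rounds:
        raise ValueError(
            f"window ({burn_in}, {sample_end}] not covered by trajectories of "
            f"{rounds} rounds"
        )
    k = records[0].patterns.index(pattern)
    field = {"motif": "motif_freq", "compartment": "comp_freq"}[which]
    # row t is the end of round t+1, so rounds (burn_in, sample_end] are rows
    # burn_in .. sample_end-1
    per_trial = np.array(
        [getattr(rec, field)[burn_in:sample_end, k].mean() for rec in records]
    )
    mean = float(per_trial.mean())
    n = per_trial.size
    if n > 1 and per_trial.std(ddof=1) > 0:
        half = float(
            stats.t.ppf(0.975, n - 1) * per_trial.std(ddof=1) / np.sqrt(n)
        )
    else:
        half = 0.0
    return SteadyStateSummary(
        pattern=pattern,
        mean=mean,
        ci_half_width=half,
        per_trial=per_trial,
        burn_in=burn_in,
        sample_end=sample_end,
    )
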