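"""Compartments and the rule mapping motif content to monomer-addition bias.

A compartment is a fixed-capacity container of M strand slots (empty slots
are empty strands). Its current bias — the probability that the next added
monomer is a 0, applied to every strand it holds — derives from its motif
content:

* neutral mode, or no motif-containing strand present: P(0) = 0.5;
* single-motif mode with at least one motif-containing strand: the motif's
  bias applies (presence suffices; abundance beyond one does not matter);
* paired mode (a pattern and its bitwise complement): the more frequent
  motif — counted as motif-containing strands — dictates the direction and
  intensity of bias; with equal counts (including zero) the compartment
  behaves as neutral.

A complement pair is *cooperative* when each motif biases the compartment
toward the majority monomer of its complement's composition (so each builds
the other's precursors), and *competitive* when each biases toward its own
majority monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .sequence import MotifSpec, Strand, complement, contains_motif

__all__ = [
    "Compartment",
    "BiasConfig",
    "count_motif_strands",
    "zero_probability",
    "majority_monomer",
    "make_cooperative_pair",
    "make_competitive_pair",
]


@dataclass
class Compartment:
    """A fixed-capacity container of strand slots.

    The slot count is fixed at construction; empty slots hold empty strands
    and are what seed new polymers.
    """

    strands: list[Strand]
    id: int = 0

    def __post_init__(self):
        if not self.strands:
            raise ValueError("a compartment needs at least one strand slot")

    @property
    def capacity(self) -> int:
        return len(self.strands)

    @classmethod
    def empty(cls, capacity: int, id: int = 0) -> "Compartment":
        return cls([Strand() for _ in range(capacity)], id=id)


def count_motif_strands(compartment: Compartment, pattern: str) -> int:
    """Number of non-empty strand slots whose bits contain ``pattern``."""
    return sum(
        1
        for s in compartment.strands
        if not s.is_empty and contains_motif(s.bits, pattern)
    )


def majority_monomer(pattern: str) -> int:
    """The strictly more common monomer in a pattern; balanced patterns are rejected."""
    ones = pattern.count("1")
    zeros = len(pattern) - ones
    if ones == zeros:
        raise ValueError(
            f"pattern {pattern!r} has no strict monomer majority; "
            "its own composition is undefined"
        )
    return 1 if ones > zeros else 0


@dataclass(frozen=True)
class BiasConfig:
    """Which motifs are active and how they bias their host compartment."""

    mode: str = "neutral"  # neutral | single | paired
    motif_a: Optional[MotifSpec] = None
    motif_b: Optional[MotifSpec] = None
    relationship: Optional[str] = None  # cooperative | competitive (paired only)

    def __post_init__(self):
        if self.mode not in ("neutral", "single", "paired"):
            raise ValueError(f"mode must be neutral, single or paired, got {self.mode!r}")
        if self.mode == "neutral":
            if self.motif_a is not None or self.motif_b is not None:
                raise ValueError("neutral mode takes no motifs")
        elif self.mode == "single":
            if self.motif_a is None or self.motif_b is not None:
                raise ValueError("single mode takes exactly motif_a")
        else:  # paired
            if self.motif_a is None or self.motif_b is None:
                raise ValueError("paired mode needs motif_a and motif_b")
            if self.motif_b.pattern != complement(self.motif_a.pattern):
                raise ValueError(
                    f"paired motifs must be complements: {self.motif_a.pattern!r} vs "
                    f"{self.motif_b.pattern!r}"
                )
            if self.motif_a.bias != self.motif_b.bias:
                raise ValueError("both motifs of a pair must have the same bias intensity")
            if self.relationship not in ("cooperative", "competitive"):
                raise ValueError(
                    "paired mode requires relationship 'cooperative' or 'competitive', "
                    f"got {self.relationship!r}"
                )

    @classmethod
    def neutral(cls) -> "BiasConfig":
        return cls(mode="neutral")

    @classmethod
    def single(cls, motif: MotifSpec) -> "BiasConfig":
        return cls(mode="single", motif_a=motif)

    @property
    def motifs(self) -> tuple[MotifSpec, ...]:
        if self.mode == "neutral":
            return ()
        if self.mode == "single":
            return (self.motif_a,)
        return (self.motif_a, self.motif_b)


def zero_probability(compartment: Compartment, bias: BiasConfig) -> float:
    """P(next added monomer is 0) for every strand in this compartment.

    Total on valid inputs; returns 0.5 whenever no motif strand governs.
    """
    if bias.mode == "neutral":
        return 0.5
    if bias.mode == "single":
        if count_motif_strands(compartment, bias.motif_a.pattern) >= 1:
            return bias.motif_a.zero_probability
        return 0.5
    c_a = count_motif_strands(compartment, bias.motif_a.pattern)
    c_b = count_motif_strands(compartment, bias.motif_b.pattern)
    if c_a > c_b:
        return bias.motif_a.zero_probability
    if c_b > c_a:
        return bias.motif_b.zero_probability
    return 0.5  # ties (including 0 == 0) behave as neutral


def _pair(pattern: str, bias: float, relationship: str) -> BiasConfig:
    comp = complement(pattern)
    if relationship == "cooperative":
        fav_a = majority_monomer(comp)  # toward the complement's composition
        fav_b = majority_monomer(pattern)
    else:
        fav_a = majority_monomer(pattern)  # toward its own composition
        fav_b = majority_monomer(comp)
    return BiasConfig(
        mode="paired",
        motif_a=MotifSpec(pattern, favored_monomer=fav_a, bias=bias),
        motif_b=MotifSpec(comp, favored_monomer=fav_b, bias=bias),
        relationship=relationship,
    )


def make_cooperative_pair(pattern: str, bias: float = 0.5) -> BiasConfig:
    """Pattern + complement, each favoring its partner's majority monomer.

    ``bias`` follows the reporting convention of the paired sweeps: it is the
    probability of adding the favored monomer for either motif, so the
    0-promoting motif adds 0 with probability b and the 1-promoting motif
    adds 0 with probability 1 - b.
    """
    return _pair(pattern, bias, "cooperative")


def make_competitive_pair(pattern: str, bias: float = 0.5) -> BiasConfig:
    """Pattern + complement, each favoring its own majority monomer."""
    return _pair(pattern, bias, "competitive")
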