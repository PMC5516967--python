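"""Binary strands, motifs, and pattern utilities.

Strands are directional binary polymers over the alphabet {0, 1}: position 1
is the first monomer added and growth appends one monomer at a time at the
terminus. Every monomer carries a provenance label recording which motif (if
any) governed its compartment when it was added.

Integer encoding
----------------
A strand of length ``l`` with bits ``b1 b2 ... bl`` (b1 = first added) is
stored as the integer ``(1 << l) | bits`` with b1 the most significant data
bit. The leading sentinel bit makes lengths unambiguous: the empty strand is
code 1, and appending monomer ``m`` is simply ``code * 2 + m``. All motif
matching respects elongation order — matching is literal and directional, with
no reverse or complement matching.

Provenance labels are packed the same way in base 3 (without a sentinel; the
length is always known from the paired strand code).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LABEL_NONE",
    "LABEL_A",
    "LABEL_B",
    "EMPTY_CODE",
    "Strand",
    "MotifSpec",
    "contains_motif",
    "complement",
    "mirror",
    "encode_bits",
    "decode_bits",
    "code_length",
    "code_lengths",
    "complement_codes",
    "encode_provenance",
    "decode_provenance",
    "pattern_automaton",
    "containment_table",
]

# provenance labels: which motif governed the compartment when a monomer was
# added. Single-motif runs use only NONE / MOTIF_A.
LABEL_NONE = 0
LABEL_A = 1
LABEL_B = 2

#: integer code of the empty strand (just the sentinel bit).
EMPTY_CODE = 1


def _check_pattern(pattern: str) -> str:
    if not isinstance(pattern, str) or len(pattern) == 0:
        raise ValueError("pattern must be a non-empty 0/1 string")
    if set(pattern) - {"0", "1"}:
        raise ValueError(f"pattern must contain only 0/1 characters, got {pattern!r}")
    return pattern


def contains_motif(strand_bits: str, pattern: str) -> bool:
    """True iff ``pattern`` occurs as a contiguous substring of the strand.

    Matching is read in elongation order (position 1 first); there is no
    reverse or complement matching. Presence is boolean — multiple
    occurrences of a self-overlapping pattern do not count extra.
    """
    _check_pattern(pattern)
    if set(strand_bits) - {"0", "1"}:
        raise ValueError(f"strand bits must be a 0/1 string, got {strand_bits!r}")
    return pattern in strand_bits


def complement(pattern: str) -> str:
    """Bitwise complement of a pattern: 10000 -> 01111."""
    _check_pattern(pattern)
    return pattern.translate(str.maketrans("01", "10"))


def mirror(pattern: str) -> str:
    """Reversal of a pattern: 10000 -> 00001 (composition-preserving)."""
    _check_pattern(pattern)
    return pattern[::-1]


# ---------------------------------------------------------------------------
# integer strand codes


def encode_bits(bits: str) -> int:
    """Encode a 0/1 string as a sentinel-prefixed integer code."""
    if set(bits) - {"0", "1"}:
        raise ValueError(f"strand bits must be a 0/1 string, got {bits!r}")
    return int("1" + bits, 2)


def decode_bits(code: int) -> str:
    """Inverse of :func:`encode_bits`."""
    if code < 1:
        raise ValueError(f"invalid strand code {code}")
    return bin(code)[3:]


def code_length(code: int) -> int:
    """Strand length of an integer code (0 for the empty strand)."""
    if code < 1:
        raise ValueError(f"invalid strand code {code}")
    return code.bit_length() - 1


def code_lengths(codes: np.ndarray) -> np.ndarray:
    """Vectorized strand lengths for an array of codes."""
    # frexp exponent is exact for integers below 2**53; codes are < 2**21
    return np.frexp(codes.astype(np.float64))[1] - 1


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Bit-flip every strand in a code array, preserving lengths."""
    lengths = code_lengths(np.asarray(codes))
    mask = (np.int64(1) << lengths.astype(np.int64)) - 1
    return np.asarray(codes) ^ mask


def encode_provenance(labels) -> int:
    """Pack a label sequence into a base-3 integer (first label most significant)."""
    value = 0
    for lab in labels:
        if lab not in (LABEL_NONE, LABEL_A, LABEL_B):
            raise ValueError(f"invalid provenance label {lab!r}")
        value = value * 3 + lab
    return value


def decode_provenance(value: int, length: int) -> tuple[int, ...]:
    """Unpack ``length`` labels from a base-3 provenance code."""
    labels = []
    for _ in range(length):
        labels.append(value % 3)
        value //= 3
    return tuple(reversed(labels))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Strand:
    """A directional binary polymer with per-position provenance labels.

    ``bits`` and ``provenance`` always have equal length; strands only grow,
    one terminal monomer at a time, and existing positions never change.
    """

    bits: str = ""
    provenance: tuple[int, ...] = ()

    def __post_init__(self):
        if set(self.bits) - {"0", "1"}:
            raise ValueError(f"strand bits must be a 0/1 string, got {self.bits!r}")
        if len(self.bits) != len(self.provenance):
            raise ValueError(
                f"provenance length {len(self.provenance)} != strand length {len(self.bits)}"
            )
        for lab in self.provenance:
            if lab not in (LABEL_NONE, LABEL_A, LABEL_B):
                raise ValueError(f"invalid provenance label {lab!r}")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def is_empty(self) -> bool:
        return len(self.bits) == 0

    @property
    def code(self) -> int:
        return encode_bits(self.bits)

    def elongate(self, monomer: int, label: int = LABEL_NONE, max_length: int | None = None) -> "Strand":
        """Return a new strand with one monomer appended at the terminus.

        Attachment is directed: the monomer always goes at the growing end.
        Elongating a strand already at ``max_length`` is a contract violation.
        """
        if monomer not in (0, 1):
            raise ValueError(f"monomer must be 0 or 1, got {monomer!r}")
        if max_length is not None and len(self.bits) >= max_length:
            raise ValueError(
                f"cannot elongate a strand of length {len(self.bits)} at the cap {max_length}"
            )
        return Strand(self.bits + str(monomer), self.provenance + (label,))

    def contains(self, pattern: str) -> bool:
        return contains_motif(self.bits, pattern)


@dataclass(frozen=True)
class MotifSpec:
    """A motif pattern together with the bias it induces.

    ``bias`` is the probability of adding ``favored_monomer`` when this motif
    governs a compartment (b = 0.5 is neutral; the sweeps of interest cover
    b in [0.5, 1.0]).
    """

    pattern: str
    favored_monomer: int = 0
    bias: float = 0.5

    def __post_init__(self):
        _check_pattern(self.pattern)
        if self.favored_monomer not in (0, 1):
            raise ValueError(f"favored_monomer must be 0 or 1, got {self.favored_monomer!r}")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias must be in [0, 1], got {self.bias!r}")

    @property
    def zero_probability(self) -> float:
        """P(added monomer is 0) while this motif governs the compartment."""
        return self.bias if self.favored_monomer == 0 else 1.0 - self.bias


# ---------------------------------------------------------------------------
# pattern automaton and containment tables


def pattern_automaton(pattern: str) -> np.ndarray:
    """KMP transition table for substring recognition, accept state absorbing.

    Returns an int64 array of shape (k+1, 2): ``trans[s, b]`` is the longest
    suffix of the seen text (after reading bit ``b`` in state ``s``) that is a
    prefix of ``pattern``; state k (full match) is absorbing. Correct for
    self-overlapping patterns such as 101 and 10101.
    """
    _check_pattern(pattern)
    pat = [int(c) for c in pattern]
    k = len(pat)
    trans = np.zeros((k + 1, 2), dtype=np.int64)
    for b in (0, 1):
        trans[0, b] = 1 if pat[0] == b else 0
    # prefix (failure) function
    fail = [0] * k
    for i in range(1, k):
        j = fail[i - 1]
        while j > 0 and pat[i] != pat[j]:
            j = fail[j - 1]
        if pat[i] == pat[j]:
            j += 1
        fail[i] = j
    for s in range(1, k):
        for b in (0, 1):
            trans[s, b] = s + 1 if pat[s] == b else trans[fail[s - 1], b]
    trans[k, :] = k
    return trans


def containment_table(pattern: str, max_length: int) -> np.ndarray:
    """Boolean lookup table over all strand codes up to ``max_length``.

    ``table[code]`` is True iff the strand encoded by ``code`` contains
    ``pattern``. Built level by level with the pattern automaton, so every
    strand state is classified in O(1) afterwards.
    """
    _check_pattern(pattern)
    if max_length < 0:
        raise ValueError("max_length must be >= 0")
    k = len(pattern)
    trans = pattern_automaton(pattern)
    size = 1 << (max_length + 1)
    table = np.zeros(size, dtype=bool)
    states = np.zeros(1, dtype=np.int64)  # state of the empty strand
    offset = 1  # code of first strand at current length
    for _ in range(max_length):
        # children of code c are 2c (append 0) and 2c+1 (append 1); the
        # accept state is absorbing, so state == k marks containment
        parent_states = np.repeat(states, 2)
        bits = np.tile(np.array([0, 1], dtype=np.int64), states.size)
        states = trans[parent_states, bits]
        offset *= 2
        table[offset : 2 * offset] = states == k
    return table
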