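"""Alignment-based channel-residue analysis.

Operates on pre-computed protein alignments (gap character ``-``) with a
user-supplied set of channel columns.  Channel columns are classified as

* ``identical`` — all sequences carry the same residue;
* ``similar`` — not identical, but every residue pair scores positive under
  the similarity rule (default: BLOSUM62 score > 0; alternative: membership
  of one physicochemical group);
* ``dissimilar`` — otherwise; any gap in a column makes it dissimilar, and a
  column that is entirely gaps is excluded from the counts with a warning.

Mutation bookkeeping uses specs in the conventional ``W86T`` notation:
wild-type residue, 1-based ungapped position in the reference sequence,
mutant residue.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from functools import lru_cache

from .errors import (
    InvalidParameterError,
    InvalidSpecError,
    NoAnchorError,
    UndefinedIdentityError,
    WildTypeMismatchError,
)
from .synthetic_data import SIMILARITY_GROUPS

__all__ = [
    "ChannelAlignment",
    "ColumnClassCounts",
    "MutationSpec",
    "pairwise_identity",
    "classify_channel_columns",
    "apply_mutations",
    "map_column_to_reference",
]

GAP = "-"
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ChannelAlignment:
    """Aligned homologs with a channel-column mask.

    ``channel_columns`` are 1-based alignment columns; ``reference`` names
    the sequence whose ungapped numbering anchors residue positions.
    """

    sequences: dict[str, str]
    channel_columns: tuple[int, ...]
    reference: str

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(self.sequences) < 1 or len(lengths) != 1:
            raise InvalidSpecError("sequences must be non-empty and equal-length")
        n_cols = lengths.pop()
        if any(not (1 <= c <= n_cols) for c in self.channel_columns):
            raise InvalidSpecError("channel columns outside alignment length")
        if self.reference not in self.sequences:
            raise InvalidSpecError(f"reference {self.reference!r} not in alignment")
        object.__setattr__(self, "channel_columns", tuple(self.channel_columns))

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, col: int) -> list[str]:
        return [seq[col - 1] for seq in self.sequences.values()]


@dataclass(frozen=True)
class ColumnClassCounts:
    identical: int
    similar: int
    dissimilar: int
    per_column_labels: tuple[tuple[int, str], ...]  # (column, label)
    n_excluded: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "identical": self.identical,
            "similar": self.similar,
            "dissimilar": self.dissimilar,
        }


_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


@dataclass(frozen=True)
class MutationSpec:
    """Point substitution, e.g. ``W86T``: W at ungapped position 86 -> T."""

    wild_type: str
    position: int  # 1-based, ungapped reference numbering
    mutant: str

    def __post_init__(self):
        if self.wild_type not in _AA or self.mutant not in _AA:
            raise InvalidSpecError("mutation letters must be standard amino acids")
        if self.position < 1:
            raise InvalidSpecError("position must be >= 1")

    @classmethod
    def from_string(cls, text: str) -> "MutationSpec":
        match = _MUTATION_RE.match(text.strip().upper())
        if not match:
            raise InvalidSpecError(f"cannot parse mutation {text!r}")
        return cls(match.group(1), int(match.group(2)), match.group(3))

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"

    def inverse(self) -> "MutationSpec":
        return MutationSpec(self.mutant, self.position, self.wild_type)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither sequence is gapped."""
    if len(a) != len(b):
        raise InvalidParameterError("aligned sequences must have equal length")
    comparable = matches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    if comparable == 0:
        raise UndefinedIdentityError("no column with both sequences ungapped")
    return 100.0 * matches / comparable


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def _all_pairs_positive(residues: list[str]) -> bool:
    mat = _blosum62()
    for i, ri in enumerate(residues):
        for rj in residues[i + 1:]:
            if mat[ri][rj] <= 0:
                return False
    return True


def _one_group(residues: list[str]) -> bool:
    return any(set(residues) <= group for group in SIMILARITY_GROUPS)


def classify_channel_columns(
    alignment: ChannelAlignment, similarity_rule: str = "blosum62"
) -> ColumnClassCounts:
    """Classify each channel column as identical / similar / dissimilar."""
    if len(alignment.sequences) < 2:
        raise InvalidParameterError("classification needs >= 2 sequences")
    if similarity_rule not in ("blosum62", "groups"):
        raise InvalidParameterError(f"unknown similarity rule {similarity_rule!r}")
    similar_fn = (
        _all_pairs_positive if similarity_rule == "blosum62" else _one_group
    )

    counts = {"identical": 0, "similar": 0, "dissimilar": 0}
    labels: list[tuple[int, str]] = []
    n_excluded = 0
    for col in alignment.channel_columns:
        residues = alignment.column(col)
        if all(r == GAP for r in residues):
            warnings.warn(f"channel column {col} is all gaps; excluded", stacklevel=2)
            n_excluded += 1
            continue
        if any(r == GAP for r in residues):
            label = "dissimilar"
        elif len(set(residues)) == 1:
            label = "identical"
        elif similar_fn(residues):
            label = "similar"
        else:
            label = "dissimilar"
        counts[label] += 1
        labels.append((col, label))

    return ColumnClassCounts(
        identical=counts["identical"],
        similar=counts["similar"],
        dissimilar=counts["dissimilar"],
        per_column_labels=tuple(labels),
        n_excluded=n_excluded,
    )


def apply_mutations(sequence: str, mutations) -> str:
    """Apply point mutations sequentially; wild types are validated first.

    ``mutations`` may contain :class:`MutationSpec` objects or strings like
    ``"W86T"``.  Double mutants are simply lists of two specs.
    """
    seq = list(sequence)
    for spec in mutations:
        if isinstance(spec, str):
            spec = MutationSpec.from_string(spec)
        if spec.position > len(seq):
            raise WildTypeMismatchError(spec.position, spec.wild_type, "<end>")
        found = seq[spec.position - 1]
        if found != spec.wild_type:
            raise WildTypeMismatchError(spec.position, spec.wild_type, found)
        seq[spec.position - 1] = spec.mutant
    return "".join(seq)


def map_column_to_reference(
    alignment: ChannelAlignment, column: int
) -> tuple[int, bool]:
    """Map an alignment column to ungapped reference numbering.

    Returns ``(position, gap_flag)``: the count of non-gap reference
    characters up to and including the column.  If the reference is gapped at
    the column, the nearest preceding residue position is returned with
    ``gap_flag=True``.
    """
    if not (1 <= column <= alignment.n_cols):
        raise InvalidParameterError(f"column {column} outside alignment")
    ref = alignment.sequences[alignment.reference]
    prefix = ref[:column]
    position = sum(1 for c in prefix if c != GAP)
    if position == 0:
        raise NoAnchorError(f"column {column} precedes every reference residue")
    return position, ref[column - 1] == GAP
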