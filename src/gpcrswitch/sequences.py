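"""Pairwise global alignment and percent-identity computation.

Alignment is deterministic Needleman–Wunsch (Gotoh affine gaps) backed by
``Bio.Align.PairwiseAligner`` with BLOSUM62, gap open 10 and gap extend 0.5
by default. A gap of length L costs ``open + (L - 1) * extend``; terminal
gaps are penalized like any other (classic global alignment).

Percent identity is convention-dependent; both the aligned-columns
(terminal gaps excluded) and shorter-sequence denominators are always
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinSequence",
    "IdentityResult",
    "read_fasta",
    "global_align",
    "alignment_score",
    "percent_identity",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    """A named, uppercase amino-acid sequence (X allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _AA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IdentityResult:
    """Percent identity of one pairwise alignment, both conventions."""

    aligned_length: int
    matches: int
    percent_identity: float  # aligned columns, terminal gaps excluded
    percent_identity_shorter: float  # matches / shorter sequence length
    denominator_convention: str = "aligned_columns"


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read all records of a FASTA file, preserving order.

    Lowercase input is uppercased; duplicate ids get a ``.2``, ``.3``, ...
    suffix with a warning; a record with no sequence lines is an error.
    """
    path = Path(path)
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                records.append((line[1:].split()[0] if len(line) > 1 else "", []))
            else:
                if not records:
                    raise ValueError(f"{path}: sequence data before first header")
                records[-1][1].append(line)
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    seen: dict[str, int] = {}
    out = []
    for rid, chunks in records:
        if not chunks:
            raise ValueError(f"{path}: record {rid!r} has no sequence lines")
        seen[rid] = seen.get(rid, 0) + 1
        if seen[rid] > 1:
            warnings.warn(f"duplicate FASTA id {rid!r}; disambiguating")
            rid = f"{rid}.{seen[rid]}"
        out.append(ProteinSequence(id=rid, residues="".join(chunks)))
    return out


def _make_aligner(substitution: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(substitution)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {substitution!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[str, str]:
    """Globally align two sequences; returns a pair of equal-length gapped strings.

    Deterministic: of all optimal alignments the aligner's first is returned.
    """
    aligner = _make_aligner(substitution, gap_open, gap_extend)
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    ga, gb = str(alignment[0]), str(alignment[1])
    assert ga.replace("-", "") == a.residues and gb.replace("-", "") == b.residues
    return ga, gb


def alignment_score(
    alignment: tuple[str, str],
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Column-wise score of a gapped alignment (same gap convention as
    :func:`global_align`: a gap of length L costs open + (L-1)·extend,
    terminal gaps included). Used as an independent check that the DP score
    equals the returned alignment's score."""
    ga, gb = alignment
    if len(ga) != len(gb):
        raise ValueError("gapped strings differ in length")
    matrix = substitution_matrices.load(substitution)
    score = 0.0
    in_gap_a = in_gap_b = False
    for i, (x, y) in enumerate(zip(ga, gb)):
        if x == "-" and y == "-":
            raise ValueError(f"column {i} is gap-gap")
        if x == "-":
            score += -gap_extend if in_gap_a else -gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += -gap_extend if in_gap_b else -gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[x, y]
            in_gap_a = in_gap_b = False
    return score


def _interior_span(ga: str, gb: str) -> tuple[int, int]:
    """[start, stop) of columns where both sequences have started and not ended."""
    n = len(ga)
    first_a = n - len(ga.lstrip("-"))
    first_b = n - len(gb.lstrip("-"))
    last_a = len(ga.rstrip("-"))
    last_b = len(gb.rstrip("-"))
    return max(first_a, first_b), min(last_a, last_b)


def percent_identity(alignment: tuple[str, str]) -> IdentityResult:
    """Percent identity of a gapped alignment.

    Default convention: matches / aligned columns with terminal gap columns
    excluded. The shorter-sequence convention is reported alongside.
    Symmetric in its arguments.
    """
    ga, gb = alignment
    if len(ga) != len(gb):
        raise ValueError("gapped strings differ in length")
    if len(ga) == 0:
        raise ValueError("zero-length alignment")
    start, stop = _interior_span(ga, gb)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    aligned_cols = stop - start
    if aligned_cols <= 0:
        raise ValueError("alignment has no aligned columns")
    len_a = len(ga.replace("-", ""))
    len_b = len(gb.replace("-", ""))
    shorter = min(len_a, len_b)
    return IdentityResult(
        aligned_length=aligned_cols,
        matches=matches,
        percent_identity=100.0 * matches / aligned_cols,
        percent_identity_shorter=100.0 * matches / shorter,
    )
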