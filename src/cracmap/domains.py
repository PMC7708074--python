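"""Protein-domain toolkit for the conservation analysis of R3H-SUZ proteins.

Covers the deterministic sequence steps: scanning for the conserved SUZ
consensus motif EERXXXYXXXRX+IF (X any residue, '+' a positively charged
residue), global pairwise identity/similarity over the R3H-SUZ region, and
greedy redundancy reduction of a sequence set at an identity threshold.
Profile searches, multiple alignment and tree building are out of scope.

In Rbs1-family numbering the R3H domain spans residues 5-90 and the SUZ
domain 124-195 (1-based inclusive), with the RNA-contacting Arg57/His61
pair inside R3H; the cross-species comparison region defaults to the union,
residues 5-195.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SUZ_MOTIF = "EERXXXYXXXRX+IF"

#: Rbs1 domain coordinates (1-based inclusive residue spans)
RBS1_R3H_SPAN = (5, 90)
RBS1_SUZ_SPAN = (124, 195)
RBS1_R3H_SUZ_SPAN = (5, 195)


class DomainError(ValueError):
    pass


def _check_protein(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise DomainError(f"{what} contains non-amino-acid characters: "
                          f"{''.join(sorted(bad))}")
    return seq


@dataclass(frozen=True)
class ConsensusPattern:
    """An ordered consensus: literal residues, wildcard X, or '+' = {K, R}.

    Histidine is only marginally protonated at physiological pH; include it
    in the positive class with ``plus_includes_histidine=True``.
    """

    symbols: tuple[str, ...]
    plus_includes_histidine: bool = False

    @classmethod
    def parse(cls, text: str,
              plus_includes_histidine: bool = False) -> "ConsensusPattern":
        if not text:
            raise DomainError("empty consensus pattern")
        symbols = []
        for ch in text.upper():
            if ch in AMINO_ACIDS or ch in ("X", "+"):
                symbols.append(ch)
            else:
                raise DomainError(f"invalid pattern symbol {ch!r}")
        return cls(tuple(symbols), plus_includes_histidine)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def positive_class(self) -> str:
        return "KRH" if self.plus_includes_histidine else "KR"

    def matches_at(self, seq: str, i: int) -> bool:
        """Does the pattern fit at 0-based position ``i``?"""
        if i < 0 or i + len(self) > len(seq):
            return False
        for sym, res in zip(self.symbols, seq[i:i + len(self)]):
            if sym == "X":
                continue
            if sym == "+":
                if res not in self.positive_class:
                    return False
            elif res != sym:
                return False
        return True

    def to_regex(self) -> str:
        parts = []
        for sym in self.symbols:
            if sym == "X":
                parts.append(f"[{AMINO_ACIDS}]")
            elif sym == "+":
                parts.append(f"[{self.positive_class}]")
            else:
                parts.append(sym)
        return "".join(parts)


def scan_motif(seq: str, pat: ConsensusPattern | str) -> list[int]:
    """All (possibly overlapping) match start positions, 1-based."""
    if isinstance(pat, str):
        pat = ConsensusPattern.parse(pat)
    seq = _check_protein(seq)
    rx = re.compile(f"(?=({pat.to_regex()}))")
    return [m.start() + 1 for m in rx.finditer(seq)]


@dataclass(frozen=True)
class DomainAnnotation:
    """Residue spans of the R3H and SUZ domains on one protein (1-based)."""

    protein_id: str
    r3h_span: tuple[int, int] = RBS1_R3H_SPAN
    suz_span: tuple[int, int] = RBS1_SUZ_SPAN
    key_residues: Mapping[str, int] = field(
        default_factory=lambda: {"Arg": 57, "His": 61})

    def validate_against(self, seq: str) -> None:
        n = len(seq)
        for name, (s, e) in (("R3H", self.r3h_span), ("SUZ", self.suz_span)):
            if not (1 <= s <= e <= n):
                raise DomainError(
                    f"{self.protein_id}: {name} span {s}-{e} outside 1-{n}")


def extract_region(seq: str, span: tuple[int, int]) -> str:
    """Slice a 1-based inclusive residue span."""
    s, e = span
    if not (1 <= s <= e <= len(seq)):
        raise DomainError(f"span {s}-{e} outside sequence of length {len(seq)}")
    return seq[s - 1:e]


@dataclass(frozen=True)
class PairwiseResult:
    identity: float       # percent of aligned columns with identical residues
    similarity: float     # percent with a positive substitution score
    aligned_length: int   # alignment columns (gap columns included)
    gap_count: int        # gap characters over both rows

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= self.similarity <= 100:
            raise DomainError("expected 0 <= identity <= similarity <= 100")


def pairwise_identity_similarity(a: str, b: str,
                                 matrix_name: str = "BLOSUM62",
                                 open_gap: float = -10.0,
                                 extend_gap: float = -0.5) -> PairwiseResult:
    """Global alignment statistics for two protein sequences.

    Needleman-Wunsch with an affine gap model (BLOSUM62, open 10,
    extend 0.5 by default). Identity counts identical residue pairs and
    similarity pairs with a positive substitution score; both use all
    alignment columns as denominator, gap columns counting as neither
    identical nor similar.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not a or not b:
        raise DomainError("empty sequence")
    a = _check_protein(a, "first sequence")
    b = _check_protein(b, "second sequence")

    matrix = substitution_matrices.load(matrix_name)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    ident = simil = gaps = 0
    for ra, rb in zip(row_a, row_b):
        if ra == "-" or rb == "-":
            gaps += 1
            continue
        if ra == rb:
            ident += 1
        if matrix[ra, rb] > 0:
            simil += 1
    ncols = len(row_a)
    return PairwiseResult(
        identity=100.0 * ident / ncols,
        similarity=100.0 * simil / ncols,
        aligned_length=ncols,
        gap_count=gaps,
    )


def reduce_redundancy(seqs: Mapping[str, str],
                      threshold: float = 60.0) -> dict[str, str]:
    """Greedy redundancy reduction at a percent-identity threshold.

    Scanning in input order, a sequence is kept iff its global pairwise
    identity to every already-kept sequence is below ``threshold``; output
    preserves input order. With the default 60% this mirrors representative-
    set construction before profile searches.
    """
    kept: dict[str, str] = {}
    for name, seq in seqs.items():
        seq = _check_protein(seq, name)
        redundant = any(
            pairwise_identity_similarity(seq, other).identity >= threshold
            for other in kept.values()
        )
        if not redundant:
            kept[name] = seq
    return kept
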