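"""Alignment-column conservation scoring.

Two scores drive classification:

* **WPC** (weighted protein conservation): at the variant's column of the
  combined ortholog+paralog protein alignment, the percentage of valid
  (non-gap, non-human) homolog rows whose residue equals the *unmutated*
  human residue.  It measures conservation of the human allele, not overall
  column conservation.

* **PSIC-style profile delta**: a per-column, per-residue log-odds profile
  with sequence-redundancy weighting; the score of a substitution is the
  absolute profile difference between reference and alternate residues.

The same column-matching percentage is also computed for nucleotide
alignments and for the separate ortholog/paralog alignments, feeding the
conservation report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .types import (
    AMINO_ACIDS,
    GAP,
    ConsistencyError,
    GeneRecord,
    MultipleAlignment,
    UndefinedScoreError,
    VariantQuery,
)

# ---------------------------------------------------------------------------
# WPC

@dataclass(frozen=True)
class ColumnStats:
    """Counts underlying one WPC value."""

    position_i: int
    a_i: int  # homolog rows matching the unmutated human residue
    n_h: int  # valid (non-gap) homolog rows at the column
    wpc: float

    def __post_init__(self) -> None:
        if not (0 <= self.a_i <= self.n_h):
            raise ConsistencyError("a_i outside 0..n_h")


def column_stats(
    aln: MultipleAlignment, pos: int, human_ref: Optional[str] = None
) -> ColumnStats:
    """Match/valid counts for reference position ``pos`` (1-based).

    ``human_ref``, when given, is checked against the human row.  The human
    row itself contributes to neither count; gapped homolog rows are excluded
    from both (gaps carry no residue evidence).
    """
    col = aln.column_for(pos)
    human_char = aln.human_aligned[col]
    if human_ref is not None and human_char != human_ref.upper():
        raise ConsistencyError(
            f"human row has {human_char} at position {pos}, expected {human_ref}"
        )
    a = n = 0
    for _, seq in aln.homolog_rows():
        ch = seq[col]
        if ch == GAP:
            continue
        n += 1
        if ch == human_char:
            a += 1
    if n == 0:
        raise UndefinedScoreError(
            f"no valid homolog rows at position {pos}: WPC undefined"
        )
    return ColumnStats(position_i=pos, a_i=a, n_h=n, wpc=100.0 * a / n)


def wpc_score(
    aln: MultipleAlignment, prot_pos: int, human_ref_aa: Optional[str] = None
) -> float:
    """WPC percentage (0-100) at a protein position of the combined alignment."""
    return column_stats(aln, prot_pos, human_ref_aa).wpc


def percent_conservation(aln: MultipleAlignment, pos: int) -> float:
    """Percent of valid homolog rows matching the human character at ``pos``.

    Definitionally equal to :func:`wpc_score` on a protein alignment; also
    valid for nucleotide alignments.
    """
    return column_stats(aln, pos).wpc


# ---------------------------------------------------------------------------
# PSIC-style profile

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _row_weights(seqs: Sequence[str], identity_threshold: float) -> np.ndarray:
    """Redundancy weights: single-linkage identity clusters share unit weight.

    Identity between two rows is computed over columns where both are
    ungapped.  An exact duplicate of a row always joins that row's cluster,
    so duplication leaves every weighted column frequency unchanged.
    """
    n = len(seqs)
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    gaps = [a == GAP.encode() for a in arrs]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            both = ~(gaps[i] | gaps[j])
            shared = int(both.sum())
            if shared == 0:
                continue
            ident = float((arrs[i][both] == arrs[j][both]).sum()) / shared
            if ident >= identity_threshold:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    roots = [find(i) for i in range(n)]
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    return np.array([1.0 / sizes[r] for r in roots])


class PsicProfile:
    """Log-odds residue profile of a protein alignment.

    For column *c* and residue *r* with weighted count ``W_r`` and total
    non-gap weight ``N`` at the column::

        value(c, r) = ln( ((W_r + q) / (N + 20 q)) / (1/20) )

    with pseudocount ``q`` (default 1) and a uniform 1/20 background.  Row
    weights down-weight redundant sequences (identical-by-threshold clusters
    share one unit of weight), so ``N`` approximates the effective number of
    independent observations.  Values are finite for all 20 residues at every
    column.
    """

    def __init__(
        self,
        aln: MultipleAlignment,
        pseudocount: float = 1.0,
        identity_threshold: float = 0.94,
    ):
        if len(aln.rows) < 2:
            raise ConsistencyError("PSIC profile requires >= 2 alignment rows")
        self.alignment = aln
        self.pseudocount = float(pseudocount)
        self.identity_threshold = float(identity_threshold)
        seqs = [seq for _, seq in aln.rows]
        weights = _row_weights(seqs, identity_threshold)
        width = aln.width
        counts = np.zeros((width, len(AMINO_ACIDS)))
        totals = np.zeros(width)
        for seq, w in zip(seqs, weights):
            for col, ch in enumerate(seq):
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[col, idx] += w
                    totals[col] += w
        q = self.pseudocount
        freq = (counts + q) / (totals[:, None] + 20.0 * q)
        self.values = np.log(freq * 20.0)  # (width, 20)
        self.row_weights = weights

    def value(self, prot_pos: int, residue: str) -> float:
        """Profile value of ``residue`` at 1-based human position ``prot_pos``."""
        residue = residue.upper()
        if residue not in _AA_INDEX:
            raise ConsistencyError(f"not a standard amino acid: {residue!r}")
        col = self.alignment.column_for(prot_pos)
        return float(self.values[col, _AA_INDEX[residue]])


def psic_profile(
    aln: MultipleAlignment,
    pseudocount: float = 1.0,
    identity_threshold: float = 0.94,
) -> PsicProfile:
    return PsicProfile(aln, pseudocount, identity_threshold)


def psic_delta(
    profile: PsicProfile, prot_pos: int, ref_aa: str, alt_aa: str
) -> float:
    """Absolute ref-vs-alt profile difference at a position (symmetric, >= 0).

    Stop-gains are handled upstream and are not scored here.
    """
    if "*" in (ref_aa, alt_aa):
        raise ConsistencyError("stop codons are not scored by the profile")
    return abs(profile.value(prot_pos, ref_aa) - profile.value(prot_pos, alt_aa))


# ---------------------------------------------------------------------------
# BLOSUM62

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(aa1: str, aa2: str) -> int:
    """Published BLOSUM62 substitution score (symmetric)."""
    aa1, aa2 = aa1.upper(), aa2.upper()
    for aa in (aa1, aa2):
        if aa not in _BLOSUM62.alphabet:
            raise ConsistencyError(f"unknown amino-acid letter {aa!r}")
    return int(_BLOSUM62[aa1, aa2])


# ---------------------------------------------------------------------------
# Conservation report

@dataclass(frozen=True)
class ConservationReport:
    """Per-variant conservation summary across the four alignments.

    Nucleotide-level percentages are ``None`` when the codon mapping is
    ambiguous (no definitive DNA location) or the alignment is absent.
    """

    query: VariantQuery
    wpc: float
    psic: Optional[float]
    blosum: Optional[int]
    protein_ortholog_pct: Optional[float]
    protein_paralog_pct: Optional[float]
    nucleotide_ortholog_pct: Optional[float]
    nucleotide_paralog_pct: Optional[float]
    known_in_window: int

    def __post_init__(self) -> None:
        for v in (
            self.wpc,
            self.protein_ortholog_pct,
            self.protein_paralog_pct,
            self.nucleotide_ortholog_pct,
            self.nucleotide_paralog_pct,
        ):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ConsistencyError(f"percentage {v} outside [0, 100]")
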