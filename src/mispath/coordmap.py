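"""Protein <-> spliced-CDS coordinate mapping and the stop-gain (NMD) rule.

The protein-to-DNA direction anchors a ten-residue peptide starting at the
variant (taken backwards when the variant lies within ten residues of the
C-terminus) and searches the CDS for the unique in-register position whose
codons translate to that peptide.  All single-nucleotide edits of the
reference codon producing the alternate residue are enumerated; when more
than one exists the nucleotide-level location is ambiguous and DNA-level
conservation is suppressed downstream (protein-level classification is
unaffected).

Everything operates in spliced CDS space under the standard genetic code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .types import (
    NUCLEOTIDES,
    STOP,
    AmbiguityError,
    ConsistencyError,
    GeneRecord,
    PipelineConfig,
)

ANCHOR_LEN = 10  # residues used for unique in-CDS identification


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class CodonMapping:
    """Where a protein variant lands in the CDS, with all causal nt edits."""

    prot_pos: int
    cds_codon_start: int  # 1-based position of the codon's first nt
    ref_codon: str
    candidate_changes: tuple[tuple[int, str, str], ...]  # (offset 1..3, ref, alt)
    ambiguous: bool

    @property
    def cds_pos(self) -> Optional[int]:
        """1-based CDS position of the causal change, if unambiguous."""
        if self.ambiguous or not self.candidate_changes:
            return None
        offset = self.candidate_changes[0][0]
        return self.cds_codon_start + offset - 1


def enumerate_codon_changes(
    ref_codon: str, alt_aa: str
) -> tuple[tuple[int, str, str], ...]:
    """All single-nucleotide edits of ``ref_codon`` that translate to ``alt_aa``."""
    out = []
    for offset in range(3):
        for nt in NUCLEOTIDES:
            if nt == ref_codon[offset]:
                continue
            mutated = ref_codon[:offset] + nt + ref_codon[offset + 1 :]
            if _translate_codon(mutated) == alt_aa:
                out.append((offset + 1, ref_codon[offset], nt))
    return tuple(out)


def map_protein_to_cds(
    gene: GeneRecord, prot_pos: int, ref_aa: str, alt_aa: str
) -> CodonMapping:
    """Locate a protein variant's codon in the CDS via a ten-residue anchor.

    Raises :class:`ConsistencyError` on a reference mismatch and
    :class:`AmbiguityError` when the anchor peptide occurs more than once in
    the CDS (in any reading register).
    """
    n = gene.protein_length
    if not (1 <= prot_pos <= n):
        raise ConsistencyError(
            f"{gene.symbol}: protein position {prot_pos} outside 1..{n}"
        )
    if gene.protein_seq[prot_pos - 1] != ref_aa:
        raise ConsistencyError(
            f"{gene.symbol}: residue at {prot_pos} is "
            f"{gene.protein_seq[prot_pos - 1]}, not {ref_aa}"
        )
    k = min(ANCHOR_LEN, n)
    if prot_pos + k - 1 <= n:  # forward anchor starting at the variant
        a_start = prot_pos
    else:  # within ten residues of the terminus: anchor taken backwards
        a_start = n - k + 1
    anchor = gene.protein_seq[a_start - 1 : a_start - 1 + k]

    # search every position of the CDS for a codon window translating to the
    # anchor; correctness is order-independent (unique-match contract)
    cds = gene.cds_seq
    hits = []
    for p in range(len(cds) - 3 * k + 1):
        window = cds[p : p + 3 * k]
        if _translate_codon(window[:3]) != anchor[0]:
            continue
        if _translate_codon(window) == anchor:
            hits.append(p + 1)
    if not hits:
        raise ConsistencyError(
            f"{gene.symbol}: anchor peptide {anchor!r} not found in CDS"
        )
    if len(hits) > 1:
        raise AmbiguityError(
            f"{gene.symbol}: anchor peptide {anchor!r} matches CDS "
            f"{len(hits)} times"
        )
    anchor_codon_start = hits[0]
    codon_start = anchor_codon_start + 3 * (prot_pos - a_start)
    ref_codon = cds[codon_start - 1 : codon_start + 2]
    changes = enumerate_codon_changes(ref_codon, alt_aa)
    if not changes:
        raise ConsistencyError(
            f"{gene.symbol}: no single-nucleotide change of codon {ref_codon} "
            f"({ref_aa}{prot_pos}) yields {alt_aa}"
        )
    return CodonMapping(
        prot_pos=prot_pos,
        cds_codon_start=codon_start,
        ref_codon=ref_codon,
        candidate_changes=changes,
        ambiguous=len(changes) > 1,
    )


def map_cds_to_protein(
    gene: GeneRecord, cds_pos: int, ref_nt: str, alt_nt: str
) -> tuple[int, str, str]:
    """Translate a CDS substitution into (prot_pos, ref_aa, alt_aa).

    A synonymous change simply returns ``alt_aa == ref_aa``.
    """
    if not (1 <= cds_pos <= len(gene.cds_seq)):
        raise ConsistencyError(
            f"{gene.symbol}: CDS position {cds_pos} outside 1..{len(gene.cds_seq)}"
        )
    ref_nt, alt_nt = ref_nt.upper(), alt_nt.upper()
    if gene.cds_seq[cds_pos - 1] != ref_nt:
        raise ConsistencyError(
            f"{gene.symbol}: CDS nt at {cds_pos} is "
            f"{gene.cds_seq[cds_pos - 1]}, not {ref_nt}"
        )
    prot_pos = math.ceil(cds_pos / 3)
    codon_start = 3 * (prot_pos - 1)
    ref_codon = gene.cds_seq[codon_start : codon_start + 3]
    offset = cds_pos - 1 - codon_start
    alt_codon = ref_codon[:offset] + alt_nt + ref_codon[offset + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    return prot_pos, ref_aa, alt_aa


def locate_flank(gene: GeneRecord, flank: str) -> int:
    """Find the unique CDS position at which ``flank`` starts.

    The first nucleotide of the flank is the mutated base, so the search
    restores position 1 to each of the four possible reference nucleotides
    before matching.  Zero or multiple matches raise :class:`AmbiguityError`.
    """
    flank = flank.upper()
    if len(flank) < 100:
        raise ConsistencyError(f"flank must be >= 100 nt (got {len(flank)})")
    cds = gene.cds_seq
    tail = flank[1:]
    hits = []
    for nt in NUCLEOTIDES:
        probe = nt + tail
        start = 0
        while True:
            i = cds.find(probe, start)
            if i < 0:
                break
            hits.append(i + 1)
            start = i + 1
    hits = sorted(set(hits))
    if not hits:
        raise AmbiguityError(f"{gene.symbol}: flanking sequence not found in CDS")
    if len(hits) > 1:
        raise AmbiguityError(
            f"{gene.symbol}: flanking sequence matches CDS at "
            f"{len(hits)} positions {hits[:5]}"
        )
    return hits[0]


def stop_gain_auto_pathogenic(
    gene: GeneRecord, mapping: CodonMapping, config: PipelineConfig
) -> bool:
    """Nonsense-mediated-decay rule for premature stop codons.

    True iff the stop codon's first nucleotide lies strictly more than
    ``config.nmd_distance_nt`` (default 50) nt upstream of the last exon-exon
    junction in spliced CDS coordinates.  Stops in the final exon (negative
    distance) and single-exon genes are not auto-pathogenic and fall through
    to the rest of the pipeline.
    """
    junction = gene.last_junction_cds_pos()
    if junction is None:
        return False
    distance = junction - mapping.cds_codon_start
    return distance > config.nmd_distance_nt
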