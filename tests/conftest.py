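"""Shared programmatic fixtures (no data files)."""

from __future__ import annotations

import numpy as np
import pytest

from mispath.synthetic import _codon_tables
from mispath.types import AMINO_ACIDS, GeneRecord, MultipleAlignment


def gene_from_protein(
    protein: str,
    symbol: str = "TG1",
    exons: tuple[int, ...] | None = None,
    seed: int = 0,
) -> GeneRecord:
    """Deterministic gene whose CDS encodes ``protein`` (+ a TAA stop)."""
    rng = np.random.default_rng(seed)
    tables = _codon_tables()
    cds = "".join(sorted(tables[aa])[int(rng.integers(len(tables[aa])))] for aa in protein)
    cds += "TAA"
    if exons is None:
        exons = (len(cds),)
    return GeneRecord(symbol=symbol, protein_seq=protein, cds_seq=cds, exons=exons)


def protein_alignment(
    human: str,
    homologs: list[str],
    human_id: str = "HUMAN",
) -> MultipleAlignment:
    rows = [(human_id, human)] + [(f"h{i}", s) for i, s in enumerate(homologs)]
    return MultipleAlignment(kind="protein", rows=tuple(rows), human_row_id=human_id)


def aln_with_counts(
    gene: GeneRecord, pos: int, matching: int, mismatching: int, gapped: int = 0
) -> MultipleAlignment:
    """Alignment whose WPC at ``pos`` is exactly 100*matching/(matching+mismatching).

    Homolog rows equal the human sequence except at column ``pos``, where the
    requested numbers of rows mismatch (cycling through non-human residues)
    or are gapped.
    """
    human = gene.protein_seq
    others = [a for a in AMINO_ACIDS if a != human[pos - 1]]
    homologs = []
    for _ in range(matching):
        homologs.append(human)
    for i in range(mismatching):
        row = list(human)
        row[pos - 1] = others[i % len(others)]
        homologs.append("".join(row))
    for _ in range(gapped):
        row = list(human)
        row[pos - 1] = "-"
        homologs.append("".join(row))
    return protein_alignment(human, homologs)


@pytest.fixture
def toy_gene() -> GeneRecord:
    rng = np.random.default_rng(42)
    protein = "M" + "".join(rng.choice(list(AMINO_ACIDS), 39))
    return gene_from_protein(protein, symbol="TOY1", seed=7)


@pytest.fixture
def random_alignment_factory():
    """Factory for random alignments with gaps, for oracle-equivalence tests."""

    def make(seed: int, n_rows: int | None = None, length: int | None = None):
        rng = np.random.default_rng(seed)
        n_rows = n_rows or int(rng.integers(2, 12))
        length = length or int(rng.integers(5, 30))
        aa = list(AMINO_ACIDS)
        rows = []
        human = "".join(rng.choice(aa, length))
        rows.append(("HUMAN", human))
        for i in range(n_rows):
            chars = rng.choice(aa + ["-"], length, p=[0.9 / 20] * 20 + [0.1])
            rows.append((f"h{i}", "".join(chars)))
        return MultipleAlignment(
            kind="protein", rows=tuple(rows), human_row_id="HUMAN"
        )

    return make
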