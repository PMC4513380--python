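"""Seeded synthetic-data generators: the offline test surface.

These generators stand in for the curated variant catalogues and
NCBI-derived alignments the original workflow downloads.  They emulate the
*structure* of those inputs — reference sequences, homolog alignments with
controllable per-column conservation, exon tables, and variant catalogues
with planted hotspots and phenotypes — not their evolutionary realism: a
homolog residue simply matches the human residue with a per-column target
probability and is otherwise uniform over the remaining 19 residues, and
gaps fall independently per cell.

Everything is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation
from .conservation import wpc_score
from .io import GeneBundle
from .types import (
    AMINO_ACIDS,
    GAP,
    Classification,
    ConfigurationError,
    GeneRecord,
    KnownVariantRecord,
    MultipleAlignment,
)

_CODONS_FOR: dict[str, list[str]] = {}


def _codon_tables() -> dict[str, list[str]]:
    if not _CODONS_FOR:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS_FOR.setdefault(aa, []).append(codon)
        _CODONS_FOR["*"] = list(standard_dna_table.stop_codons)
    return _CODONS_FOR


PHENOTYPE_POOL = (
    "Achromatopsia",
    "Cardiomyopathy",
    "Deafness",
    "Epilepsy",
    "Marfan syndrome",
    "Neuropathy",
    "Retinitis pigmentosa",
    "Thalassemia",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the desk-scale benchmark: 100 genes of 400 residues,
    30 homologs per alignment with 5 % independent gaps, one hotspot region
    per gene, per-column conservation drawn uniformly on [0, 1], and a
    generative pathogenicity threshold of 0.55 on that conservation.
    """

    seed: int = 0
    n_genes: int = 100
    protein_length: int = 400
    n_homologs: int = 30
    gap_rate: float = 0.05
    conservation_profile: Optional[tuple[float, ...]] = None
    hotspot_regions: Optional[tuple[tuple[int, int, str], ...]] = None
    hotspot_width: int = 60
    n_variants: int = 2000
    known_pathogenic_per_gene: int = 8
    known_benign_per_gene: int = 8
    pathogenic_rule: float = 0.55
    range_aa: int = 100

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.protein_length < 12 or self.n_homologs < 1:
            raise ConfigurationError("fixture spec dimensions too small")
        if self.conservation_profile is not None:
            if len(self.conservation_profile) != self.protein_length:
                raise ConfigurationError("profile length != protein length")
            if any(not (0 <= p <= 1) for p in self.conservation_profile):
                raise ConfigurationError("profile probabilities outside [0, 1]")
        if self.hotspot_regions is not None:
            for s, e, _ in self.hotspot_regions:
                if not (1 <= s <= e <= self.protein_length):
                    raise ConfigurationError(f"region ({s}, {e}) outside protein")


def make_gene(spec: FixtureSpec, seed: int, symbol: str = "GENE1") -> GeneRecord:
    """Random gene: M-initial protein, codon-consistent CDS, random exons."""
    rng = np.random.default_rng(seed)
    tables = _codon_tables()
    protein = "M" + "".join(rng.choice(list(AMINO_ACIDS), spec.protein_length - 1))
    codons = [str(rng.choice(tables[aa])) for aa in protein]
    codons.append(str(rng.choice(tables["*"])))
    cds = "".join(codons)
    n_exons = int(rng.integers(2, 7))
    cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(cds)]
    exons = tuple(bounds[i + 1] - bounds[i] for i in range(n_exons))
    return GeneRecord(symbol=symbol, protein_seq=protein, cds_seq=cds, exons=exons)


def make_homolog_alignment(
    gene: GeneRecord,
    n_homologs: int,
    conservation_profile: Sequence[float],
    seed: int,
    gap_rate: float = 0.05,
    source: str = "combined",
) -> MultipleAlignment:
    """Homolog rows matching the human residue with per-column probability.

    A non-matching cell is uniform over the other 19 residues, so a profile
    of zeros yields zero conservation by construction.  Gaps are independent
    per cell at ``gap_rate``; the human row is ungapped.
    """
    L = gene.protein_length
    profile = np.asarray(conservation_profile, dtype=float)
    if profile.shape != (L,):
        raise ConfigurationError("profile length != protein length")
    rng = np.random.default_rng(seed)
    human = np.array(list(gene.protein_seq))
    aa = np.array(list(AMINO_ACIDS))
    rows: list[tuple[str, str]] = [(f"HUMAN|{gene.symbol}", gene.protein_seq)]
    for h in range(n_homologs):
        match = rng.random(L) < profile
        gapped = rng.random(L) < gap_rate
        # uniform over the 19 non-human residues per column
        offsets = rng.integers(1, len(aa), size=L)
        human_idx = np.searchsorted(aa, human)
        other = aa[(human_idx + offsets) % len(aa)]
        row = np.where(match, human, other)
        row[gapped] = GAP
        rows.append((f"hom{h + 1}|{gene.symbol}", "".join(row)))
    return MultipleAlignment(
        kind="protein",
        rows=tuple(rows),
        human_row_id=f"HUMAN|{gene.symbol}",
        source=source,
    )


def make_nucleotide_alignment(
    gene: GeneRecord, protein_aln: MultipleAlignment, seed: int,
    source: str = "combined",
) -> MultipleAlignment:
    """Codon-level companion of a protein alignment.

    Matching residues reuse the human codon; mismatches get a random codon
    of the homolog residue; gaps become codon gaps.  The stop codon column
    block is copied from the human CDS for all rows.
    """
    rng = np.random.default_rng(seed)
    tables = _codon_tables()
    stop = gene.cds_seq[-3:]
    rows: list[tuple[str, str]] = []
    for rid, seq in protein_aln.rows:
        if rid == protein_aln.human_row_id:
            rows.append((rid, gene.cds_seq))
            continue
        parts = []
        for j, ch in enumerate(seq):
            if ch == GAP:
                parts.append("---")
            elif ch == gene.protein_seq[j]:
                parts.append(gene.codon(j + 1))
            else:
                parts.append(str(rng.choice(tables[ch])))
        parts.append(stop)
        rows.append((rid, "".join(parts)))
    return MultipleAlignment(
        kind="nucleotide",
        rows=tuple(rows),
        human_row_id=protein_aln.human_row_id,
        source=source,
    )


@dataclass
class GeneSim:
    """One simulated gene with its generative ground truth."""

    gene: GeneRecord
    alignment: MultipleAlignment
    profile: np.ndarray  # per-column generative conservation
    region: tuple[int, int, str]  # planted hotspot (start, end, phenotype)


@dataclass
class StudyFixture:
    """A complete simulated study: genes, catalogues and labeled dataset."""

    spec: FixtureSpec
    sims: dict[str, GeneSim]
    records: list[KnownVariantRecord]
    dataset: pd.DataFrame

    def bundles(self, with_nucleotide: bool = False) -> dict[str, GeneBundle]:
        out = {}
        for sym, sim in self.sims.items():
            nt = None
            if with_nucleotide:
                nt = make_nucleotide_alignment(
                    sim.gene, sim.alignment, seed=self.spec.seed + 977
                )
            out[sym] = GeneBundle(
                gene=sim.gene,
                combined_protein=sim.alignment,
                combined_nucleotide=nt,
            )
        return out


def _gene_seed(base: int, i: int, salt: int) -> int:
    return int((base * 1_000_003 + i * 101 + salt) % (2**31 - 1))


def make_variant_catalogue(
    sims: dict[str, GeneSim], spec: FixtureSpec, seed: int
) -> tuple[list[KnownVariantRecord], pd.DataFrame]:
    """Known-variant records with planted hotspots + labeled query dataset.

    Pathogenic records are planted inside each gene's hotspot region with the
    region's phenotype; benign records are scattered.  A query variant is
    truly pathogenic iff it lies within the hotspot window of a planted
    disease record *and* the generative conservation at its column reaches
    ``spec.pathogenic_rule`` — the generative truth mirrors the gated
    pipeline, with score noise only from the finite alignment.
    """
    rng = np.random.default_rng(seed)
    records: list[KnownVariantRecord] = []
    for sym in sorted(sims):
        sim = sims[sym]
        start, end, phenotype = sim.region
        L = sim.gene.protein_length
        for pos in rng.integers(start, end + 1, size=spec.known_pathogenic_per_gene):
            pos = int(pos)
            ref = sim.gene.protein_seq[pos - 1]
            alt = _other_residue(rng, ref)
            records.append(
                KnownVariantRecord(
                    gene=sym, prot_pos=pos, ref_aa=ref, alt_aa=alt,
                    classification=Classification.PATHOGENIC, phenotype=phenotype,
                )
            )
        for pos in rng.integers(1, L + 1, size=spec.known_benign_per_gene):
            pos = int(pos)
            ref = sim.gene.protein_seq[pos - 1]
            records.append(
                KnownVariantRecord(
                    gene=sym, prot_pos=pos, ref_aa=ref,
                    alt_aa=_other_residue(rng, ref),
                    classification=Classification.BENIGN, phenotype="",
                )
            )

    syms = sorted(sims)
    rows = []
    for _ in range(spec.n_variants):
        sym = syms[int(rng.integers(len(syms)))]
        sim = sims[sym]
        pos = int(rng.integers(1, sim.gene.protein_length + 1))
        ref = sim.gene.protein_seq[pos - 1]
        alt = _other_residue(rng, ref)
        hotspot = annotation.in_functional_hotspot(
            records, sym, pos, spec.range_aa
        )
        truth = int(hotspot and sim.profile[pos - 1] >= spec.pathogenic_rule)
        rows.append(
            {
                "gene": sym,
                "prot_pos": pos,
                "ref_aa": ref,
                "alt_aa": alt,
                "truth": truth,
                "wpc": wpc_score(sim.alignment, pos, ref),
                "hotspot": hotspot,
            }
        )
    return records, pd.DataFrame(rows)


def _other_residue(rng: np.random.Generator, ref: str) -> str:
    others = [a for a in AMINO_ACIDS if a != ref]
    return str(others[int(rng.integers(len(others)))])


def simulate_study(spec: FixtureSpec) -> StudyFixture:
    """Generate the full study: genes, alignments, catalogue, dataset."""
    rng = np.random.default_rng(spec.seed)
    sims: dict[str, GeneSim] = {}
    for i in range(spec.n_genes):
        sym = f"GENE{i + 1:03d}"
        gene = make_gene(spec, _gene_seed(spec.seed, i, 1), symbol=sym)
        if spec.conservation_profile is not None:
            profile = np.asarray(spec.conservation_profile, dtype=float)
        else:
            profile = np.random.default_rng(_gene_seed(spec.seed, i, 2)).random(
                spec.protein_length
            )
        aln = make_homolog_alignment(
            gene, spec.n_homologs, profile, _gene_seed(spec.seed, i, 3),
            gap_rate=spec.gap_rate,
        )
        if spec.hotspot_regions is not None:
            region = spec.hotspot_regions[i % len(spec.hotspot_regions)]
        else:
            r = np.random.default_rng(_gene_seed(spec.seed, i, 4))
            width = min(spec.hotspot_width, spec.protein_length)
            start = int(r.integers(1, spec.protein_length - width + 2))
            phenotype = PHENOTYPE_POOL[int(r.integers(len(PHENOTYPE_POOL)))]
            region = (start, start + width - 1, phenotype)
        sims[sym] = GeneSim(gene=gene, alignment=aln, profile=profile, region=region)
    records, dataset = make_variant_catalogue(sims, spec, spec.seed + 7)
    return StudyFixture(spec=spec, sims=sims, records=records, dataset=dataset)


def make_planted_threshold_dataset(
    n_variants: int = 2000,
    n_genes: int = 100,
    seed: int = 0,
    mode: str = "wpc-only",
    wpc_cutoff: float = 55.0,
    psic_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Feature-space dataset labeled by an exact planted decision rule.

    ``wpc`` is uniform on [0, 100] and ``psic`` uniform on [0, 2]; every row
    is in a hotspot.  Labels follow the planted rule exactly (benign when
    psic < ``psic_cutoff`` in two-feature mode; pathogenic iff
    wpc >= ``wpc_cutoff``), so cutpoint optimization has a recoverable
    ground truth.
    """
    rng = np.random.default_rng(seed)
    wpc = rng.random(n_variants) * 100.0
    psic = rng.random(n_variants) * 2.0
    if mode == "wpc-only":
        truth = (wpc >= wpc_cutoff).astype(int)
    elif mode == "wpc+psic":
        truth = ((psic >= psic_cutoff) & (wpc >= wpc_cutoff)).astype(int)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    genes = [f"GENE{i % n_genes + 1:03d}" for i in range(n_variants)]
    return pd.DataFrame(
        {
            "gene": genes,
            "truth": truth,
            "wpc": wpc,
            "psic": psic,
            "hotspot": True,
        }
    )
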