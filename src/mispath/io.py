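"""Readers and writers for every on-disk format the tool touches.

Sequences are FASTA, alignments are aligned FASTA or CLUSTAL ``.aln``
(both parsed through Biopython), tables are TSV with a header row, and
configuration is YAML or JSON.  All coordinates in files are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import AlignIO, SeqIO

from .types import (
    GAP,
    AmbiguityError,
    Classification,
    ClassificationResult,
    ConfigurationError,
    ConsistencyError,
    GeneRecord,
    KnownVariantRecord,
    MultipleAlignment,
    ParseError,
    PipelineConfig,
    VariantQuery,
    translate_cds,
)

#: classification spellings accepted in known-variant tables, mapped onto the
#: closed internal vocabulary (humsavar-style exports load unchanged)
CLASSIFICATION_ALIASES: dict[str, Classification] = {
    "pathogenic": Classification.PATHOGENIC,
    "disease": Classification.PATHOGENIC,
    "likely pathogenic": Classification.PATHOGENIC,
    "benign": Classification.BENIGN,
    "polymorphism": Classification.BENIGN,
    "likely benign": Classification.BENIGN,
    "unspecified_functional": Classification.UNSPECIFIED_FUNCTIONAL,
    "unclassified": Classification.UNSPECIFIED_FUNCTIONAL,
    "functional": Classification.UNSPECIFIED_FUNCTIONAL,
}

#: default id prefix marking the human reference row in alignment files
HUMAN_PREFIX = "HUMAN"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, uppercased sequence), ...]``, in order."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments

def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in (".aln", ".clustal", ".clw"):
        return "clustal"
    return "fasta"


def read_alignment(
    path,
    kind: str,
    dialect: Optional[str] = None,
    human_row: Optional[str] = None,
    source: str = "combined",
) -> MultipleAlignment:
    """Read an aligned FASTA or CLUSTAL file into a :class:`MultipleAlignment`.

    The human reference row is the row whose id equals ``human_row``, or, when
    ``human_row`` is ``None`` (or names no row exactly), the unique row whose
    id starts with it (default prefix ``HUMAN``).
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in ("fasta", "clustal"):
        raise ConfigurationError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    rows = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in aln
    )
    prefix = human_row or HUMAN_PREFIX
    exact = [rid for rid, _ in rows if rid == prefix]
    if exact:
        human_id = exact[0]
    else:
        matches = [rid for rid, _ in rows if rid.startswith(prefix)]
        if len(matches) != 1:
            raise ConfigurationError(
                f"{path}: {len(matches)} rows match human prefix {prefix!r}"
            )
        human_id = matches[0]
    return MultipleAlignment(kind=kind, rows=rows, human_row_id=human_id, source=source)


def write_alignment(path, aln: MultipleAlignment) -> None:
    write_fasta(path, aln.rows)


# ---------------------------------------------------------------------------
# Known-variant and exon tables

_KV_COLUMNS = ["gene", "prot_pos", "ref_aa", "alt_aa", "classification", "phenotype"]


def read_known_variants(
    path, aliases: Mapping[str, Classification] = CLASSIFICATION_ALIASES
) -> list[KnownVariantRecord]:
    """Read a humsavar/ClinVar-like TSV into known-variant records.

    Duplicate rows are preserved; an unknown classification token raises a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _KV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "phenotype" not in df.columns:
        df["phenotype"] = ""
    records = []
    for idx, row in df.iterrows():
        token = row["classification"].strip().lower()
        if token not in aliases:
            raise ParseError(
                f"{path}, line {idx + 2}: unknown classification "
                f"{row['classification']!r}"
            )
        records.append(
            KnownVariantRecord(
                gene=row["gene"],
                prot_pos=int(row["prot_pos"]),
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                classification=aliases[token],
                phenotype=row["phenotype"],
            )
        )
    return records


def write_known_variants(path, records: Sequence[KnownVariantRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "prot_pos": r.prot_pos,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "classification": r.classification.value,
                "phenotype": r.phenotype,
            }
            for r in records
        ],
        columns=_KV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_exon_table(path) -> dict[str, tuple[int, ...]]:
    """Read a spliced-exon-length TSV (gene, exon_index, length_nt)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "exon_index", "length_nt"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out: dict[str, tuple[int, ...]] = {}
    for gene, grp in df.groupby("gene", sort=False):
        grp = grp.sort_values("exon_index")
        out[str(gene)] = tuple(int(x) for x in grp["length_nt"])
    return out


def write_exon_table(path, exons_by_gene: Mapping[str, Sequence[int]]) -> None:
    rows = [
        {"gene": g, "exon_index": i + 1, "length_nt": ln}
        for g, exons in exons_by_gene.items()
        for i, ln in enumerate(exons)
    ]
    pd.DataFrame(rows, columns=["gene", "exon_index", "length_nt"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Variant-query parsing

_P_RE = re.compile(r"^p\.([A-Z\*])(\d+)([A-Z\*])$", re.IGNORECASE)
_C_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$", re.IGNORECASE)
_NT_RE = re.compile(r"^[ACGT]+$", re.IGNORECASE)


def parse_variant_query(text: str, gene: GeneRecord) -> VariantQuery:
    """Normalize one query in ``p.``, ``c.`` or flanking-sequence form.

    A flanking sequence must be at least 100 nt long and start with the
    mutated nucleotide; it is located in the CDS by
    :func:`mispath.coordmap.locate_flank`.
    """
    from . import coordmap  # local import to avoid a cycle

    text = text.strip()
    m = _P_RE.match(text)
    if m:
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        _check_protein_ref(gene, pos, ref)
        return VariantQuery(
            gene=gene.symbol, prot_pos=pos, ref_aa=ref, alt_aa=alt, origin="protein"
        )
    m = _C_RE.match(text)
    if m:
        cds_pos = int(m.group(1))
        ref_nt, alt_nt = m.group(2).upper(), m.group(3).upper()
        prot_pos, ref_aa, alt_aa = coordmap.map_cds_to_protein(
            gene, cds_pos, ref_nt, alt_nt
        )
        return VariantQuery(
            gene=gene.symbol,
            prot_pos=prot_pos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            cds_pos=cds_pos,
            ref_nt=ref_nt,
            alt_nt=alt_nt,
            origin="cds",
        )
    if _NT_RE.match(text):
        flank = text.upper()
        if len(flank) < 100:
            raise ParseError(
                f"flanking sequence must be >= 100 nt (got {len(flank)})"
            )
        cds_pos = coordmap.locate_flank(gene, flank)
        ref_nt = gene.cds_seq[cds_pos - 1]
        alt_nt = flank[0]
        prot_pos, ref_aa, alt_aa = coordmap.map_cds_to_protein(
            gene, cds_pos, ref_nt, alt_nt
        )
        return VariantQuery(
            gene=gene.symbol,
            prot_pos=prot_pos,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            cds_pos=cds_pos,
            ref_nt=ref_nt,
            alt_nt=alt_nt,
            origin="flank",
        )
    raise ParseError(f"unrecognized query {text!r}")


def _check_protein_ref(gene: GeneRecord, pos: int, ref: str) -> None:
    if not (1 <= pos <= gene.protein_length):
        raise ConsistencyError(
            f"{gene.symbol}: position {pos} beyond protein length "
            f"{gene.protein_length}"
        )
    actual = gene.protein_seq[pos - 1]
    if actual != ref:
        raise ConsistencyError(
            f"{gene.symbol}: reference residue at {pos} is {actual}, not {ref}"
        )


def read_batch(path) -> list[tuple[str, str]]:
    """Read a batch TSV (columns: gene, query) into ``[(gene, query), ...]``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "query"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return [(row["gene"], row["query"]) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Config

def read_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def write_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Gene bundles (the per-gene file tree the CLI consumes)

@dataclasses.dataclass
class GeneBundle:
    """One gene's reference sequences plus its alignments.

    The combined ortholog+paralog protein alignment drives classification;
    the separate ortholog/paralog (protein and nucleotide) alignments, when
    present, feed only the conservation report.
    """

    gene: GeneRecord
    combined_protein: MultipleAlignment
    combined_nucleotide: Optional[MultipleAlignment] = None
    ortholog_protein: Optional[MultipleAlignment] = None
    paralog_protein: Optional[MultipleAlignment] = None
    ortholog_nucleotide: Optional[MultipleAlignment] = None
    paralog_nucleotide: Optional[MultipleAlignment] = None


_ALN_FILES = {
    "combined_protein": ("combined.protein.aln.fasta", "protein", "combined"),
    "combined_nucleotide": ("combined.cds.aln.fasta", "nucleotide", "combined"),
    "ortholog_protein": ("ortholog.protein.aln.fasta", "protein", "ortholog"),
    "paralog_protein": ("paralog.protein.aln.fasta", "protein", "paralog"),
    "ortholog_nucleotide": ("ortholog.cds.aln.fasta", "nucleotide", "ortholog"),
    "paralog_nucleotide": ("paralog.cds.aln.fasta", "nucleotide", "paralog"),
}


def load_gene_bundle(gene_dir, symbol: str) -> GeneBundle:
    """Load ``<gene_dir>/genes/<symbol>/`` written by :func:`write_gene_bundle`
    (or by ``mispath simulate``)."""
    root = Path(gene_dir) / "genes" / symbol
    if not root.is_dir():
        raise ParseError(f"no gene directory for {symbol!r} under {gene_dir}")
    protein = read_fasta(root / "protein.fasta")[0][1]
    cds = read_fasta(root / "cds.fasta")[0][1]
    exons_by_gene = read_exon_table(root / "exons.tsv")
    gene = GeneRecord(
        symbol=symbol, protein_seq=protein, cds_seq=cds,
        exons=exons_by_gene[symbol],
    )
    kw: dict[str, Optional[MultipleAlignment]] = {}
    for attr, (fname, kind, source) in _ALN_FILES.items():
        p = root / fname
        if p.exists():
            aln = read_alignment(p, kind=kind, source=source)
            aln.validate_against(gene)
            kw[attr] = aln
        elif attr == "combined_protein":
            raise ParseError(f"{root}: missing required {fname}")
        else:
            kw[attr] = None
    return GeneBundle(gene=gene, **kw)  # type: ignore[arg-type]


def write_gene_bundle(gene_dir, bundle: GeneBundle) -> None:
    root = Path(gene_dir) / "genes" / bundle.gene.symbol
    root.mkdir(parents=True, exist_ok=True)
    write_fasta(root / "protein.fasta", [(bundle.gene.symbol, bundle.gene.protein_seq)])
    write_fasta(root / "cds.fasta", [(bundle.gene.symbol, bundle.gene.cds_seq)])
    write_exon_table(root / "exons.tsv", {bundle.gene.symbol: bundle.gene.exons})
    for attr, (fname, _, _) in _ALN_FILES.items():
        aln = getattr(bundle, attr)
        if aln is not None:
            write_alignment(root / fname, aln)


def list_bundle_genes(gene_dir) -> list[str]:
    root = Path(gene_dir) / "genes"
    if not root.is_dir():
        return []
    return sorted(p.name for p in root.iterdir() if p.is_dir())


# ---------------------------------------------------------------------------
# Results

RESULT_COLUMNS = [
    "gene", "prot_pos", "ref_aa", "alt_aa", "label", "reason", "wpc", "psic",
    "hotspot", "phenotype_status", "phenotype", "support", "total_in_window",
]


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.query.gene,
                "prot_pos": r.query.prot_pos,
                "ref_aa": r.query.ref_aa,
                "alt_aa": r.query.alt_aa,
                "label": r.label.value,
                "reason": r.reason.value,
                "wpc": "" if r.wpc is None else round(r.wpc, 4),
                "psic": "" if r.psic is None else round(r.psic, 4),
                "hotspot": "" if r.hotspot is None else r.hotspot,
                "phenotype_status": r.phenotype.status.value,
                "phenotype": r.phenotype.phenotype,
                "support": r.phenotype.support,
                "total_in_window": r.phenotype.total_in_window,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(path, results: Sequence[ClassificationResult], fmt: str = "tsv") -> None:
    df = results_frame(results)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, default=str)
            fh.write("\n")
    else:
        raise ConfigurationError(f"unknown results format {fmt!r}")
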