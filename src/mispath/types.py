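"""Shared domain types.

All coordinates are 1-based and inclusive, in protein residues or spliced-CDS
nucleotides.  Genomic coordinates, strands and introns are out of scope: the
nonsense-mediated-decay rule only needs the position of the last exon-exon
junction, which is fully determined by the spliced exon lengths.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
STOP = "*"


class MispathError(Exception):
    """Base class for all package errors."""


class ParseError(MispathError):
    """Malformed input file."""


class ConsistencyError(MispathError):
    """Input contradicts the reference sequences."""


class AmbiguityError(MispathError):
    """A lookup that must be unique matched zero or several times."""


class ConfigurationError(MispathError):
    """Invalid or incomplete configuration."""


class UndefinedScoreError(MispathError):
    """A conservation score has an empty denominator (all homologs gapped)."""


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code) and drop the trailing stop if present."""
    if len(cds) % 3 != 0:
        raise ConsistencyError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate())
    if prot.endswith(STOP):
        prot = prot[:-1]
    if STOP in prot:
        raise ConsistencyError("internal stop codon in CDS")
    return prot


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene: protein + spliced CDS reference and exon lengths.

    Invariants (checked on construction): the CDS translates to the protein
    under the standard genetic code (terminal stop dropped) and the exon
    lengths sum to the CDS length.
    """

    symbol: str
    protein_seq: str
    cds_seq: str
    exons: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_seq", self.protein_seq.upper())
        object.__setattr__(self, "cds_seq", self.cds_seq.upper())
        object.__setattr__(self, "exons", tuple(int(e) for e in self.exons))
        if not self.symbol:
            raise ConsistencyError("empty gene symbol")
        if translate_cds(self.cds_seq) != self.protein_seq:
            raise ConsistencyError(
                f"{self.symbol}: CDS does not translate to the protein sequence"
            )
        if any(e <= 0 for e in self.exons):
            raise ConsistencyError(f"{self.symbol}: non-positive exon length")
        if sum(self.exons) != len(self.cds_seq):
            raise ConsistencyError(
                f"{self.symbol}: exon lengths sum to {sum(self.exons)}, "
                f"CDS length is {len(self.cds_seq)}"
            )

    @property
    def protein_length(self) -> int:
        return len(self.protein_seq)

    def last_junction_cds_pos(self) -> Optional[int]:
        """1-based CDS position of the last nt of the penultimate exon.

        ``None`` for single-exon genes (no exon-exon junction).
        """
        if len(self.exons) < 2:
            return None
        return sum(self.exons[:-1])

    def codon(self, prot_pos: int) -> str:
        start = 3 * (prot_pos - 1)
        return self.cds_seq[start : start + 3]


@dataclass(frozen=True)
class MultipleAlignment:
    """An MSA of homologous sequences with a designated human reference row.

    ``kind`` is ``protein`` or ``nucleotide``; ``source`` records whether the
    rows are orthologs, paralogs, or the combined set used for classification.
    """

    kind: str
    rows: tuple[tuple[str, str], ...]
    human_row_id: str
    source: str = "combined"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise ConfigurationError(f"unknown alignment kind {self.kind!r}")
        rows = tuple((rid, seq.upper()) for rid, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ParseError("empty alignment")
        width = len(rows[0][1])
        for rid, seq in rows:
            if len(seq) != width:
                raise ParseError(
                    f"ragged alignment: row {rid!r} has length {len(seq)}, "
                    f"expected {width}"
                )
            bad = set(seq) & {".", "*"}
            if bad:
                raise ParseError(
                    f"row {rid!r} contains {sorted(bad)}; gaps must be '-'"
                )
        if self.human_row_id not in {rid for rid, _ in rows}:
            raise ConfigurationError(
                f"human row {self.human_row_id!r} not present in alignment"
            )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def human_aligned(self) -> str:
        for rid, seq in self.rows:
            if rid == self.human_row_id:
                return seq
        raise AssertionError("unreachable")

    @property
    def human_seq(self) -> str:
        return self.human_aligned.replace(GAP, "")

    def homolog_rows(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, seq in self.rows if rid != self.human_row_id]

    def column_for(self, ref_pos: int) -> int:
        """0-based alignment column holding 1-based ungapped reference position."""
        if ref_pos < 1:
            raise ConsistencyError(f"position {ref_pos} must be >= 1")
        seen = 0
        for col, ch in enumerate(self.human_aligned):
            if ch != GAP:
                seen += 1
                if seen == ref_pos:
                    return col
        raise ConsistencyError(
            f"position {ref_pos} beyond ungapped human length {seen}"
        )

    def column(self, col: int) -> list[str]:
        return [seq[col] for _, seq in self.rows]

    def validate_against(self, gene: GeneRecord) -> None:
        expect = gene.protein_seq if self.kind == "protein" else gene.cds_seq
        if self.human_seq != expect:
            raise ConsistencyError(
                f"{gene.symbol}: ungapped human alignment row differs from the "
                f"reference {self.kind} sequence"
            )


class Classification(str, enum.Enum):
    """Curated-variant classification vocabulary."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNSPECIFIED_FUNCTIONAL = "unspecified_functional"


#: classifications that mark a region as a functional hotspot
DISEASE_ASSOCIATED = frozenset(
    {Classification.PATHOGENIC, Classification.UNSPECIFIED_FUNCTIONAL}
)


@dataclass(frozen=True)
class KnownVariantRecord:
    """One curated variant from the local ClinVar/humsavar-like table."""

    gene: str
    prot_pos: int
    ref_aa: str
    alt_aa: str
    classification: Classification
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.prot_pos < 1:
            raise ConsistencyError("prot_pos must be >= 1")
        object.__setattr__(
            self, "classification", Classification(self.classification)
        )


@dataclass(frozen=True)
class VariantQuery:
    """One nsSNP normalized to gene + protein position + ref/alt residue."""

    gene: str
    prot_pos: int
    ref_aa: str
    alt_aa: str
    cds_pos: Optional[int] = None
    ref_nt: Optional[str] = None
    alt_nt: Optional[str] = None
    origin: str = "protein"

    def __post_init__(self) -> None:
        if self.prot_pos < 1:
            raise ConsistencyError("prot_pos must be >= 1")
        if self.cds_pos is not None and math.ceil(self.cds_pos / 3) != self.prot_pos:
            raise ConsistencyError(
                f"cds_pos {self.cds_pos} does not fall in codon {self.prot_pos}"
            )

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_aa == STOP

    def short(self) -> str:
        return f"{self.gene}:p.{self.ref_aa}{self.prot_pos}{self.alt_aa}"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds and toggles of the decision pipeline.

    WPC cutoffs are percentages on a 0-100 scale; the PSIC cutoff is on the
    log-odds delta scale.  ``range_aa`` is the amino-acid half-width of the
    hotspot/phenotype window.  ``nmd_distance_nt`` is the minimum distance (nt,
    strictly greater-than) between a premature stop and the last exon-exon
    junction for the nonsense-mediated-decay auto-pathogenic call.
    """

    range_aa: int = 100
    use_psic: bool = False
    use_hotspot: bool = True
    use_stop_gain: bool = True
    psic_cutoff: float = 1.03
    wpc_cutoff_with_psic: float = 40.0
    wpc_cutoff_default: float = 49.0
    nmd_distance_nt: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.wpc_cutoff_with_psic <= 100):
            raise ConfigurationError("wpc_cutoff_with_psic outside [0, 100]")
        if not (0 <= self.wpc_cutoff_default <= 100):
            raise ConfigurationError("wpc_cutoff_default outside [0, 100]")
        if self.range_aa < 0:
            raise ConfigurationError("range_aa must be >= 0")

    @property
    def wpc_cutoff(self) -> float:
        return self.wpc_cutoff_with_psic if self.use_psic else self.wpc_cutoff_default

    def to_dict(self) -> dict:
        return {
            "range_aa": self.range_aa,
            "use_psic": self.use_psic,
            "use_hotspot": self.use_hotspot,
            "use_stop_gain": self.use_stop_gain,
            "psic_cutoff": self.psic_cutoff,
            "wpc_cutoff_with_psic": self.wpc_cutoff_with_psic,
            "wpc_cutoff_default": self.wpc_cutoff_default,
            "nmd_distance_nt": self.nmd_distance_nt,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def evolve(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


class PhenotypeStatus(str, enum.Enum):
    PREDICTED = "predicted"
    FUNCTIONAL_ONLY = "functional_only"
    NO_DATA = "no_data"


@dataclass(frozen=True)
class PhenotypePrediction:
    """Outcome of windowed phenotype-frequency ranking."""

    status: PhenotypeStatus
    phenotype: str = ""
    support: int = 0
    total_in_window: int = 0
    nearest_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.support > self.total_in_window:
            raise ConsistencyError("support exceeds window total")
        if (self.status == PhenotypeStatus.NO_DATA) != (self.total_in_window == 0):
            raise ConsistencyError("no_data status inconsistent with window total")


NO_PHENOTYPE_DATA = PhenotypePrediction(status=PhenotypeStatus.NO_DATA)


class Label(str, enum.Enum):
    """Final pathogenicity call."""

    BENIGN_H = "Benign(h)"  # outside any functional hotspot
    BENIGN_A = "Benign(a)"  # low conservation (PSIC and/or WPC)
    PATHOGENIC = "Pathogenic"


class Reason(str, enum.Enum):
    STOP_GAIN = "stop_gain"
    NO_HOTSPOT = "no_hotspot"
    PSIC_LOW = "psic_low"
    WPC_LOW = "wpc_low"
    WPC_HIGH = "wpc_high"


@dataclass(frozen=True)
class ClassificationResult:
    """A labeled call with its full evidence trail."""

    query: VariantQuery
    label: Label
    reason: Reason
    wpc: Optional[float] = None
    psic: Optional[float] = None
    hotspot: Optional[bool] = None
    phenotype: PhenotypePrediction = NO_PHENOTYPE_DATA

    def __post_init__(self) -> None:
        if self.label == Label.BENIGN_H and self.reason != Reason.NO_HOTSPOT:
            raise ConsistencyError("Benign(h) requires reason no_hotspot")
        if self.label == Label.PATHOGENIC and self.reason not in (
            Reason.STOP_GAIN,
            Reason.WPC_HIGH,
        ):
            raise ConsistencyError("Pathogenic requires stop_gain or wpc_high")
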