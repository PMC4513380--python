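"""The stepwise pathogenicity decision pipeline.

Ordered rules, applied to one missense (or stop-gain) query:

1. Stop-gain far enough upstream of the last exon-exon junction (the 50-nt
   nonsense-mediated-decay rule) -> ``Pathogenic`` (stop_gain).
2. No known disease-associated variant within the window -> ``Benign(h)``
   (literature says the region is not a functional hotspot).  Skipped when
   the hotspot feature is off (de novo variant mode); phenotype cannot be
   predicted in that mode.
3. PSIC delta below its cutoff (only when the PSIC feature is on, and never
   for stop-gains, which the profile does not score) -> ``Benign(a)``.
4. WPC at or above the active cutoff -> ``Pathogenic``, otherwise
   ``Benign(a)``.  The cutoff is 40 when PSIC is on and 49 in the default
   (WPC-only) mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from . import annotation, coordmap
from .conservation import (
    ConservationReport,
    PsicProfile,
    blosum62,
    percent_conservation,
    psic_delta,
    psic_profile,
    wpc_score,
)
from .io import GeneBundle, parse_variant_query
from .types import (
    STOP,
    ClassificationResult,
    KnownVariantRecord,
    Label,
    MispathError,
    MultipleAlignment,
    NO_PHENOTYPE_DATA,
    GeneRecord,
    PipelineConfig,
    Reason,
    UndefinedScoreError,
    VariantQuery,
)


def decide(
    *,
    stop_gain_auto: bool,
    hotspot: bool,
    wpc: float,
    psic: Optional[float],
    config: PipelineConfig,
) -> tuple[Label, Reason]:
    """Apply the ordered rules to already-computed evidence."""
    if config.use_stop_gain and stop_gain_auto:
        return Label.PATHOGENIC, Reason.STOP_GAIN
    if config.use_hotspot and not hotspot:
        return Label.BENIGN_H, Reason.NO_HOTSPOT
    if config.use_psic and psic is not None and psic < config.psic_cutoff:
        return Label.BENIGN_A, Reason.PSIC_LOW
    if wpc >= config.wpc_cutoff:
        return Label.PATHOGENIC, Reason.WPC_HIGH
    return Label.BENIGN_A, Reason.WPC_LOW


def classify(
    query: VariantQuery,
    gene: GeneRecord,
    combined_aln: MultipleAlignment,
    records: Sequence[KnownVariantRecord],
    config: PipelineConfig,
    profile: Optional[PsicProfile] = None,
) -> ClassificationResult:
    """Classify one variant against the combined ortholog+paralog alignment.

    ``profile`` may carry a precomputed PSIC profile of ``combined_aln`` to
    amortize profile construction over a batch.  An all-gap column (WPC
    undefined) raises :class:`UndefinedScoreError`; the caller decides how to
    surface it.
    """
    stop_auto = False
    if query.is_stop_gain and config.use_stop_gain:
        mapping = coordmap.map_protein_to_cds(
            gene, query.prot_pos, query.ref_aa, STOP
        )
        stop_auto = coordmap.stop_gain_auto_pathogenic(gene, mapping, config)

    hotspot = annotation.in_functional_hotspot(
        records, query.gene, query.prot_pos, config.range_aa
    )
    phenotype = (
        annotation.predict_phenotype(
            records, query.gene, query.prot_pos, config.range_aa
        )
        if config.use_hotspot
        else NO_PHENOTYPE_DATA
    )

    wpc = wpc_score(combined_aln, query.prot_pos, query.ref_aa)
    psic: Optional[float] = None
    if config.use_psic and not query.is_stop_gain:
        if profile is None:
            profile = psic_profile(combined_aln)
        psic = psic_delta(profile, query.prot_pos, query.ref_aa, query.alt_aa)

    label, reason = decide(
        stop_gain_auto=stop_auto, hotspot=hotspot, wpc=wpc, psic=psic,
        config=config,
    )
    return ClassificationResult(
        query=query,
        label=label,
        reason=reason,
        wpc=wpc,
        psic=psic,
        hotspot=hotspot,
        phenotype=phenotype,
    )


@dataclass(frozen=True)
class BatchRowError:
    """A non-fatal failure for one batch row."""

    row_index: int
    gene: str
    query_text: str
    message: str


def classify_batch(
    rows: Sequence[tuple[str, str]],
    bundles: dict[str, GeneBundle],
    records: Sequence[KnownVariantRecord],
    config: PipelineConfig,
) -> tuple[list[ClassificationResult], list[BatchRowError]]:
    """Classify ``(gene, query_text)`` rows; row failures are isolated.

    Results come back in input order.  Each row's result equals a standalone
    :func:`classify` call on the same inputs.
    """
    results: list[ClassificationResult] = []
    errors: list[BatchRowError] = []
    profiles: dict[str, PsicProfile] = {}
    for idx, (gene_sym, text) in enumerate(rows):
        try:
            bundle = bundles.get(gene_sym)
            if bundle is None:
                raise MispathError(f"unknown gene {gene_sym!r}")
            query = parse_variant_query(text, bundle.gene)
            prof = None
            if config.use_psic:
                prof = profiles.get(gene_sym)
                if prof is None:
                    prof = psic_profile(bundle.combined_protein)
                    profiles[gene_sym] = prof
            results.append(
                classify(
                    query, bundle.gene, bundle.combined_protein, records,
                    config, profile=prof,
                )
            )
        except MispathError as exc:
            errors.append(
                BatchRowError(
                    row_index=idx, gene=gene_sym, query_text=text,
                    message=str(exc),
                )
            )
    return results, errors


def conservation_report(
    query: VariantQuery,
    bundle: GeneBundle,
    records: Sequence[KnownVariantRecord],
    config: PipelineConfig,
    profile: Optional[PsicProfile] = None,
) -> ConservationReport:
    """Per-variant conservation summary across the four alignments.

    Nucleotide-level percentages require an unambiguous codon mapping (a
    definitive DNA location); otherwise they are left blank.  Missing
    alignments are likewise blank.
    """
    gene = bundle.gene
    wpc = wpc_score(bundle.combined_protein, query.prot_pos, query.ref_aa)
    psic: Optional[float] = None
    if not query.is_stop_gain:
        if profile is None:
            profile = psic_profile(bundle.combined_protein)
        psic = psic_delta(profile, query.prot_pos, query.ref_aa, query.alt_aa)
    blos = (
        None
        if query.is_stop_gain
        else blosum62(query.ref_aa, query.alt_aa)
    )

    def prot_pct(aln: Optional[MultipleAlignment]) -> Optional[float]:
        if aln is None:
            return None
        try:
            return percent_conservation(aln, query.prot_pos)
        except UndefinedScoreError:
            return None

    cds_pos: Optional[int] = query.cds_pos
    if cds_pos is None:
        try:
            mapping = coordmap.map_protein_to_cds(
                gene, query.prot_pos, query.ref_aa, query.alt_aa
            )
            cds_pos = mapping.cds_pos  # None when ambiguous
        except MispathError:
            cds_pos = None

    def nt_pct(aln: Optional[MultipleAlignment]) -> Optional[float]:
        if aln is None or cds_pos is None:
            return None
        try:
            return percent_conservation(aln, cds_pos)
        except UndefinedScoreError:
            return None

    n_window = sum(
        1
        for r in records
        if r.gene == query.gene
        and abs(r.prot_pos - query.prot_pos) <= config.range_aa
    )
    return ConservationReport(
        query=query,
        wpc=wpc,
        psic=psic,
        blosum=blos,
        protein_ortholog_pct=prot_pct(bundle.ortholog_protein),
        protein_paralog_pct=prot_pct(bundle.paralog_protein),
        nucleotide_ortholog_pct=nt_pct(bundle.ortholog_nucleotide),
        nucleotide_paralog_pct=nt_pct(bundle.paralog_nucleotide),
        known_in_window=n_window,
    )
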