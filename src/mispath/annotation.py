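"""Functional-hotspot detection and phenotype prediction.

Both operations scan the local curated-variant table within a window of
``range_aa`` amino acids (default 100, inclusive at both boundaries) on
either side of the query position.  Any disease-associated record in the
window makes the region a functional hotspot; the most frequent named
phenotype among in-window disease-associated records is the predicted
phenotype.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .types import (
    DISEASE_ASSOCIATED,
    Classification,
    KnownVariantRecord,
    PhenotypePrediction,
    PhenotypeStatus,
)


def _window_records(
    records: Iterable[KnownVariantRecord],
    gene: str,
    prot_pos: int,
    range_aa: int,
    exclude_self: bool = True,
) -> list[KnownVariantRecord]:
    out = []
    for r in records:
        if r.gene != gene:
            continue
        if r.classification not in DISEASE_ASSOCIATED:
            continue
        if exclude_self and r.prot_pos == prot_pos:
            continue
        if abs(r.prot_pos - prot_pos) <= range_aa:
            out.append(r)
    return out


def in_functional_hotspot(
    records: Iterable[KnownVariantRecord],
    gene: str,
    prot_pos: int,
    range_aa: int = 100,
) -> bool:
    """True iff any known disease-associated variant lies within the window.

    Hotspots are deliberately broad: a single disease-associated record
    suffices.  A record at the query position itself is excluded so a variant
    cannot be its own evidence.
    """
    return bool(_window_records(records, gene, prot_pos, range_aa))


def predict_phenotype(
    records: Iterable[KnownVariantRecord],
    gene: str,
    prot_pos: int,
    range_aa: int = 100,
) -> PhenotypePrediction:
    """Rank phenotypes of in-window disease-associated variants by frequency.

    Each record counts once (per-variant, not per-publication, counting).
    Records without a named phenotype (including unspecified-functional ones)
    count toward the window total but never contribute a name; if only such
    records are present the status is ``functional_only``.  An empty window
    yields ``no_data``.  Frequency ties break to the phenotype of the record
    nearest the query, then lexicographically.
    """
    window = _window_records(records, gene, prot_pos, range_aa)
    if not window:
        return PhenotypePrediction(status=PhenotypeStatus.NO_DATA)
    nearest_any = min(abs(r.prot_pos - prot_pos) for r in window)
    named = [
        r
        for r in window
        if r.phenotype and r.classification == Classification.PATHOGENIC
    ]
    if not named:
        return PhenotypePrediction(
            status=PhenotypeStatus.FUNCTIONAL_ONLY,
            total_in_window=len(window),
            nearest_distance=nearest_any,
        )
    counts = Counter(r.phenotype for r in named)
    top = max(counts.values())
    contenders = sorted(p for p, c in counts.items() if c == top)
    if len(contenders) > 1:
        nearest_of = {
            p: min(abs(r.prot_pos - prot_pos) for r in named if r.phenotype == p)
            for p in contenders
        }
        best_dist = min(nearest_of.values())
        contenders = sorted(p for p in contenders if nearest_of[p] == best_dist)
    phenotype = contenders[0]
    return PhenotypePrediction(
        status=PhenotypeStatus.PREDICTED,
        phenotype=phenotype,
        support=counts[phenotype],
        total_in_window=len(window),
        nearest_distance=nearest_any,
    )
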