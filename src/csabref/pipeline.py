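"""End-to-end annotation of a record: profile → γ-core → mapping →
classification → bonds → report row."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .mapping import (
    ArrayMapping,
    BondSet,
    FamilyLabel,
    MappingError,
    classify_family,
    describe_bonds,
    encode_notation,
    infer_bonds,
    map_to_reference,
    toxin_flag,
)
from .motifs import GammaCoreHit, cysteine_profile, find_gamma_core, n_loop_length
from .records import PeptideRecord, RecordAnnotation

logger = logging.getLogger(__name__)


@dataclass
class AnnotationResult:
    """Everything computed for one record (mapping is None on failure)."""

    record: PeptideRecord
    annotation: RecordAnnotation
    mapping: ArrayMapping | None = None
    family: FamilyLabel | None = None
    bonds: BondSet | None = None
    anchor_hit: GammaCoreHit | None = None
    toxin_heuristic: bool = False
    error: str | None = None


def _anchor_hit(mapping: ArrayMapping, hits: list[GammaCoreHit]) -> GammaCoreHit | None:
    if mapping.anchor_used is None:
        return None
    core = mapping.assignment[mapping.anchor_used]
    matching = [h for h in hits if h.core_cys == core]
    matching.sort(key=lambda h: h.orientation != "GXC")  # prefer GXC
    return matching[0] if matching else None


def annotate_record(
    record: PeptideRecord,
    *,
    long_extension_threshold: int = 10,
    short_nloop_threshold: int = 6,
    mytilin_exception: bool = True,
) -> AnnotationResult:
    """Run the full annotation pipeline on one record.

    Unmappable records (fewer than 2 or more than 12 cysteines) yield a
    report row with family ``none`` and the error recorded, never an
    exception.
    """
    profile = cysteine_profile(record)
    annotation = RecordAnnotation(record_id=record.id, n_cysteines=profile.count)
    result = AnnotationResult(record=record, annotation=annotation)
    hits = find_gamma_core(record, profile)
    try:
        mapping = map_to_reference(
            record, profile, hits, mytilin_exception=mytilin_exception
        )
    except MappingError as exc:
        result.error = str(exc)
        logger.warning("%s", exc)
        return result
    family = classify_family(
        mapping, long_extension_threshold=long_extension_threshold
    )
    bonds = infer_bonds(mapping, family)
    anchor = _anchor_hit(mapping, hits)
    n_loop = n_loop_length(mapping)
    annotation.slots = ",".join(str(s) for s in mapping.slots)
    annotation.notation = encode_notation(mapping)
    annotation.family = family.label
    annotation.bonds = describe_bonds(bonds)
    if anchor is not None:
        start, end = anchor.span
        annotation.gamma_core = f"{start + 1}-{end}"  # 1-based inclusive
        annotation.kcxn = anchor.kcxn
        result.toxin_heuristic = toxin_flag(
            mapping, anchor, family, short_nloop_threshold=short_nloop_threshold
        )
    annotation.n_loop = n_loop
    result.mapping = mapping
    result.family = family
    result.bonds = bonds
    result.anchor_hit = anchor
    return result


def annotate_collection(records, **kwargs) -> list[AnnotationResult]:
    """Annotate records in order; per-record failures are captured."""
    return [annotate_record(rec, **kwargs) for rec in records]
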