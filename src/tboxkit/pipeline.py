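"""End-to-end annotation: curation -> features -> terminator -> specifier -> tRNA.

This is the library core behind the ``tboxkit scan`` command: it takes parsed
inputs (leader records, structure-search hits, host tRNA sets) and produces
one annotated result per curated record, ready for the flat-file CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import annotate, specifier, terminator_thermo
from .annotate import SpecifierWindow, StructureAnnotation
from .errors import TboxKitError
from .models import STEM1_TRUNCATION_THRESHOLD
from .seqio import (
    StructureSearchHit,
    TboxRecord,
    TrnaRecord,
    format_interval,
)
from .specifier import FRAME_LABELS, SpecifierCall
from .terminator_thermo import EnergyModel, TerminatorCall

logger = logging.getLogger(__name__)


@dataclass
class ScanSettings:
    """Thresholds and tables for one pipeline run (all surfaced in the CLI)."""

    min_len: int = 100
    max_len: int = 500
    stem1_truncation: int = STEM1_TRUNCATION_THRESHOLD
    term_min_stem: int = 4
    term_min_loop: int = 3
    term_max_loop: int = 10
    term_max_gap: int = 3
    thermo_backend: str = "builtin"
    energy_model: Optional[EnergyModel] = None
    ontology_table: Optional[dict[str, str]] = None
    discriminator_table: Optional[dict[str, str]] = None

    def echo(self) -> list[str]:
        """key = value lines for output headers."""
        return [
            f"min_len = {self.min_len}",
            f"max_len = {self.max_len}",
            f"stem1_truncation = {self.stem1_truncation}",
            f"term_min_stem = {self.term_min_stem}",
            f"term_min_loop = {self.term_min_loop}",
            f"term_max_loop = {self.term_max_loop}",
            f"term_max_gap = {self.term_max_gap}",
            f"thermo_backend = {self.thermo_backend}",
        ]


@dataclass
class ScanResult:
    """Everything the pipeline produced for one record."""

    record: TboxRecord
    annotation: Optional[StructureAnnotation] = None
    tbox_class: str = ""
    window: Optional[SpecifierWindow] = None
    call: Optional[SpecifierCall] = None
    trna: Optional[TrnaRecord] = None
    terminator: Optional[TerminatorCall] = None
    mfe_antiterminator: Optional[float] = None
    mfe_terminator: Optional[float] = None
    failure: str = ""

    @property
    def annotated(self) -> bool:
        return self.annotation is not None

    def to_row(self) -> dict[str, str]:
        feats = self.annotation.features if self.annotation else {}
        top = self.call.top if self.call else None
        return {
            "id": self.record.record_id,
            "host": self.record.host_name,
            "class": self.tbox_class,
            "sequence": self.record.sequence,
            "specifier": top.triplet if top else "",
            "specifier_frame": FRAME_LABELS[top.frame] if top else "",
            "alt_specifiers": ";".join(
                f"{FRAME_LABELS[e.frame]}:{e.triplet}" for e in self.call.alternatives
            ) if self.call else "",
            "aa_family": top.aa_family if top else "",
            "tbox_uggn": (self.annotation.tbox_uggn or "") if self.annotation else "",
            "trna_anticodon": self.trna.anticodon if self.trna else "",
            "trna_matched": ("yes" if self.trna else "no") if self.call else "",
            "stem1_interval": format_interval(feats.get("stem1")),
            "antiterminator_interval": format_interval(feats.get("antiterminator")),
            "terminator_interval": format_interval(
                self.terminator.hairpin_interval if self.terminator else None
            ),
            "mfe_antiterminator": (
                f"{self.mfe_antiterminator:.2f}"
                if self.mfe_antiterminator is not None else ""
            ),
            "mfe_terminator": (
                f"{self.mfe_terminator:.2f}" if self.mfe_terminator is not None else ""
            ),
            "downstream_annotation": self.record.downstream_annotation or "",
        }


@dataclass
class ScanReport:
    results: list[ScanResult] = field(default_factory=list)
    dropped: list[tuple[TboxRecord, str]] = field(default_factory=list)

    @property
    def n_annotated(self) -> int:
        return sum(1 for r in self.results if r.annotated)

    @property
    def calls(self) -> list[Optional[SpecifierCall]]:
        return [r.call for r in self.results]

    @property
    def calls_with_trna(self) -> list[tuple[Optional[SpecifierCall], Optional[TrnaRecord]]]:
        return [(r.call, r.trna) for r in self.results]


def scan(
    records: list[TboxRecord],
    hits: list[StructureSearchHit],
    trnas: list[TrnaRecord],
    settings: Optional[ScanSettings] = None,
) -> ScanReport:
    """Annotate every curated record; failures degrade to empty fields."""
    settings = settings or ScanSettings()
    kept, dropped = terminator_thermo.curate(
        records, min_len=settings.min_len, max_len=settings.max_len
    )
    for rec, reason in dropped:
        logger.info("dropped %s: %s", rec.record_id, reason)

    hits_by_target: dict[str, StructureSearchHit] = {}
    for hit in hits:
        prev = hits_by_target.get(hit.target_id)
        if prev is None or hit.score > prev.score:
            hits_by_target[hit.target_id] = hit
    trnas_by_host: dict[str, list[TrnaRecord]] = {}
    for t in trnas:
        trnas_by_host.setdefault(t.host_name, []).append(t)

    report = ScanReport(dropped=dropped)
    for rec in kept:
        report.results.append(
            _scan_one(rec, hits_by_target.get(rec.record_id),
                      trnas_by_host.get(rec.host_name, []), settings)
        )
    return report


def _scan_one(
    record: TboxRecord,
    hit: Optional[StructureSearchHit],
    host_trnas: list[TrnaRecord],
    settings: ScanSettings,
) -> ScanResult:
    result = ScanResult(record=record)
    if hit is None:
        result.failure = "no structure-search hit"
        logger.warning("%s: no structure-search hit; row left unannotated",
                       record.record_id)
        return result

    trimmed, _ = terminator_thermo.trim_to_polyU(record.sequence)
    if len(trimmed) >= hit.target_end:
        record = TboxRecord(
            record_id=record.record_id,
            sequence=trimmed,
            host_name=record.host_name,
            tbox_class=record.tbox_class,
            source=record.source,
            locus=record.locus,
            downstream_annotation=record.downstream_annotation,
        )
        result.record = record

    try:
        annotation = annotate.extract_features(record, hit)
        result.annotation = annotation
        result.tbox_class = annotate.classify_tbox(
            annotation, truncation_threshold=settings.stem1_truncation
        )
    except TboxKitError as exc:
        result.failure = str(exc)
        logger.warning("%s: %s", record.record_id, exc)
        return result

    # terminator fold: transcriptional leaders only (sequestrators of the
    # translational class are not predicted)
    if result.tbox_class == "I":
        result.terminator = terminator_thermo.find_terminator(
            record.sequence, annotation, settings.energy_model,
            min_stem=settings.term_min_stem, min_loop=settings.term_min_loop,
            max_loop=settings.term_max_loop, max_gap=settings.term_max_gap,
        )
    try:
        result.mfe_antiterminator, result.mfe_terminator = terminator_thermo.mfe_pair(
            record, annotation, settings.energy_model,
            terminator=result.terminator, backend=settings.thermo_backend,
        )
    except TboxKitError as exc:
        logger.warning("%s: energy evaluation failed: %s", record.record_id, exc)

    try:
        window = annotate.specifier_window(
            annotation, record.sequence, record_id=record.record_id
        )
    except TboxKitError as exc:
        result.failure = str(exc)
        logger.warning("%s: %s", record.record_id, exc)
        return result
    result.window = window
    result.call = specifier.evaluate_frames(
        window.sequence,
        annotation.tbox_uggn,
        host_trnas,
        downstream_annotation=record.downstream_annotation,
        discriminator_fallback=settings.discriminator_table,
        ontology_table=settings.ontology_table,
    )
    result.trna = specifier.match_anticodon(result.call.top.triplet, host_trnas)
    return result
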