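"""Structural feature extraction from a sequence plus its model hit.

The aligned hit carries the model consensus structure; feature intervals are
defined on model columns (:mod:`tboxkit.models`) and mapped to sequence
positions through the alignment.  Model columns deleted in the target simply
drop out of the interval; a pair whose partner column is deleted becomes
unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .errors import StructureFormatError, WindowError
from .models import MODEL_MAPS, STEM1_TRUNCATION_THRESHOLD, ModelColumnMap
from .seqio import Interval, StructureSearchHit, TboxRecord


@dataclass
class StructureAnnotation:
    """Dot-bracket structure plus named feature intervals (0-based half-open).

    ``dotbracket`` spans the whole record sequence (dots outside the hit) and
    corresponds to the fold the search reports — the antiterminator /
    antisequestrator state.  ``tbox_uggn`` is the 4-mer at the T-box-bulge
    columns, absent when those columns are deleted in the hit; when present it
    canonically starts with UGG, otherwise it is flagged non-canonical (such
    riboswitches are annotated, never dropped).
    """

    dotbracket: str
    features: dict[str, Interval] = field(default_factory=dict)
    tbox_uggn: Optional[str] = None

    @property
    def uggn_canonical(self) -> Optional[bool]:
        if self.tbox_uggn is None:
            return None
        return self.tbox_uggn.startswith("UGG")


def pair_table(dotbracket: str) -> list[Optional[int]]:
    """Partner index per position (None when unpaired) for a ()-structure."""
    table: list[Optional[int]] = [None] * len(dotbracket)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureFormatError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise StructureFormatError(f"unclosed '(' at position {stack[-1]}")
    return table


def extract_features(record: TboxRecord, hit: StructureSearchHit) -> StructureAnnotation:
    """Map model-column features onto the record through the hit alignment."""
    model = _model_for(hit)
    cols = hit.consensus_structure
    aligned = hit.aligned_sequence
    if len(cols) != model.ncols:
        raise StructureFormatError(
            f"hit on {hit.target_id!r}: alignment has {len(cols)} columns, "
            f"model {model.name!r} defines {model.ncols}"
        )

    # model column -> target position (None for deleted columns)
    col_to_pos: list[Optional[int]] = []
    pos = hit.target_start
    for ch in aligned:
        if ch == "-":
            col_to_pos.append(None)
        else:
            col_to_pos.append(pos)
            pos += 1
    if pos != hit.target_end:
        raise StructureFormatError(
            f"hit on {hit.target_id!r}: aligned sequence covers "
            f"{pos - hit.target_start} nt but coordinates span "
            f"{hit.target_end - hit.target_start}"
        )
    ungapped = aligned.replace("-", "")
    if record.sequence[hit.target_start:hit.target_end] != ungapped:
        raise StructureFormatError(
            f"hit on {hit.target_id!r}: aligned sequence disagrees with the record "
            f"over [{hit.target_start}, {hit.target_end})"
        )

    features: dict[str, Interval] = {}
    for name, (c0, c1) in model.features.items():
        kept = [p for p in col_to_pos[c0:c1] if p is not None]
        if kept:
            features[name] = (kept[0], kept[-1] + 1)

    dot = ["."] * len(record.sequence)
    for i, j in _pairs(cols):
        pi, pj = col_to_pos[i], col_to_pos[j]
        if pi is not None and pj is not None:
            dot[pi], dot[pj] = "(", ")"

    tbox_uggn = None
    if "tbox_bulge" in model.features:
        c0, c1 = model.features["tbox_bulge"]
        bases = [col_to_pos[k] for k in range(c0, c1)]
        if all(p is not None for p in bases):
            tbox_uggn = "".join(record.sequence[p] for p in bases)  # type: ignore[index]

    return StructureAnnotation("".join(dot), features, tbox_uggn)


def _pairs(dotbracket: str) -> list[tuple[int, int]]:
    table = pair_table(dotbracket)
    return [(i, j) for i, j in enumerate(table) if j is not None and i < j]


def _model_for(hit: StructureSearchHit) -> ModelColumnMap:
    try:
        return MODEL_MAPS[hit.query_model]
    except KeyError:
        raise StructureFormatError(
            f"hit on {hit.target_id!r}: no bundled column map for model "
            f"{hit.query_model!r} (known: {sorted(MODEL_MAPS)})"
        ) from None


def classify_tbox(
    annotation: StructureAnnotation,
    truncation_threshold: int = STEM1_TRUNCATION_THRESHOLD,
) -> str:
    """Class II iff Stem I is truncated (span below the threshold), else I.

    A span exactly at the threshold classifies as I (ties go to the
    longer-stem, transcriptional class).
    """
    start, end = annotation.features["stem1"]
    return "II" if (end - start) < truncation_threshold else "I"


class SpecifierWindow(NamedTuple):
    """The 5-base window ending at the 3' end of the Stem I specifier bulge."""

    sequence: str
    start: int  # absolute position of the first window base

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(self.start, self.start + 5))


def specifier_window(
    annotation: StructureAnnotation, sequence: str, record_id: str = ""
) -> SpecifierWindow:
    """The bases at distances 5..1 upstream of (ending at) the bulge 3' end.

    The specifier region is the 1-5 bp (inclusive) 5' of the end of the
    specifier bulge; the "end" is the 3'-most unpaired base of the bulge loop.
    """
    try:
        _, bulge_end = annotation.features["specifier_bulge"]
    except KeyError:
        raise WindowError(f"record {record_id!r}: no specifier bulge annotated") from None
    if bulge_end < 5:
        raise WindowError(
            f"record {record_id!r}: specifier bulge ends at {bulge_end}, "
            "too close to the 5' end for a 5-base window"
        )
    return SpecifierWindow(sequence[bulge_end - 5:bulge_end], bulge_end - 5)
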