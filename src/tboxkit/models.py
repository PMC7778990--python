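"""Bundled consensus-model column maps.

A covariance-model search reports hits aligned to model columns; features are
located on the model, not on the raw sequence.  The upstream models never
publish their column numbers, so this package ships its own column maps — one
per riboswitch class — that define, in model-column coordinates, where each
conserved element sits.  The synthetic-fixture generator instantiates
sequences against these same maps, which is what makes feature extraction
testable end-to-end with exact ground truth.

Model architecture (class I, transcriptional): a long Stem I whose 3' side
carries the specifier bulge, Stem II and Stem III filler hairpins, and the
antiterminator hairpin with the four-base T-box bulge (5'-UGGN-3') on its 5'
side.  Class II (translational) differs by a truncated Stem I and no Stem III.
Terminator hairpin and poly-U tract lie 3' of the model and are found by
sequence search, not by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Interval = tuple[int, int]


@dataclass(frozen=True)
class ModelColumnMap:
    """Feature locations of one consensus model, in model-column coordinates."""

    name: str
    ss_cons: str
    features: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ncol = len(self.ss_cons)
        for fname, (c0, c1) in self.features.items():
            if not (0 <= c0 < c1 <= ncol):
                raise ValueError(f"{self.name}: feature {fname} outside model columns")

    @property
    def ncols(self) -> int:
        return len(self.ss_cons)


def _build(segments: list[tuple[str, int, str]], name: str,
           feature_spans: dict[str, tuple[str, str]]) -> ModelColumnMap:
    """Assemble a map from (segment-name, length, ss-char) triples.

    ``feature_spans`` maps a feature name to its first and last segment.
    """
    ss_parts: list[str] = []
    bounds: dict[str, Interval] = {}
    pos = 0
    for seg_name, length, ss_char in segments:
        bounds[seg_name] = (pos, pos + length)
        ss_parts.append(ss_char * length)
        pos += length
    features = {
        fname: (bounds[first][0], bounds[last][1])
        for fname, (first, last) in feature_spans.items()
    }
    return ModelColumnMap(name=name, ss_cons="".join(ss_parts), features=features)


# Class I: Stem I spans 50 columns with an 8-nt specifier bulge on its 3' side.
CLASS_I = _build(
    segments=[
        ("s1_arm5", 10, "("),
        ("s1_int", 3, "."),
        ("s1_inner5", 6, "("),
        ("s1_apex", 7, "."),
        ("s1_inner3", 6, ")"),
        ("spec_bulge", 8, "."),
        ("s1_arm3", 10, ")"),
        ("link1", 4, "."),
        ("s2_arm5", 7, "("),
        ("s2_loop", 5, "."),
        ("s2_arm3", 7, ")"),
        ("link2", 3, "."),
        ("s3_arm5", 7, "("),
        ("s3_loop", 5, "."),
        ("s3_arm3", 7, ")"),
        ("link3", 3, "."),
        ("at_arm5", 5, "("),
        ("tbox_bulge", 4, "."),
        ("at_inner5", 4, "("),
        ("at_loop", 6, "."),
        ("at_inner3", 4, ")"),
        ("at_arm3", 5, ")"),
    ],
    name="tbox_class_I",
    feature_spans={
        "stem1": ("s1_arm5", "s1_arm3"),
        "specifier_bulge": ("spec_bulge", "spec_bulge"),
        "stem2": ("s2_arm5", "s2_arm3"),
        "stem3": ("s3_arm5", "s3_arm3"),
        "antiterminator": ("at_arm5", "at_arm3"),
        "tbox_bulge": ("tbox_bulge", "tbox_bulge"),
    },
)

# Class II: truncated Stem I (20 columns), no Stem III.
CLASS_II = _build(
    segments=[
        ("s1_arm5", 6, "("),
        ("spec_bulge", 8, "."),
        ("s1_arm3", 6, ")"),
        ("link1", 4, "."),
        ("s2_arm5", 7, "("),
        ("s2_loop", 5, "."),
        ("s2_arm3", 7, ")"),
        ("link2", 3, "."),
        ("at_arm5", 5, "("),
        ("tbox_bulge", 4, "."),
        ("at_inner5", 4, "("),
        ("at_loop", 6, "."),
        ("at_inner3", 4, ")"),
        ("at_arm3", 5, ")"),
    ],
    name="tbox_class_II",
    feature_spans={
        "stem1": ("s1_arm5", "s1_arm3"),
        "specifier_bulge": ("spec_bulge", "spec_bulge"),
        "stem2": ("s2_arm5", "s2_arm3"),
        "antiterminator": ("at_arm5", "at_arm3"),
        "tbox_bulge": ("tbox_bulge", "tbox_bulge"),
    },
)

#: registry keyed by the model name reported in hit files
MODEL_MAPS: dict[str, ModelColumnMap] = {m.name: m for m in (CLASS_I, CLASS_II)}

#: default Stem I length separating truncated (class II) from full (class I)
#: stems; the bundled templates span 50 vs 20 columns, the cutoff is midway.
STEM1_TRUNCATION_THRESHOLD = 35
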