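"""Specifier-frame enumeration and the top-specifier assignment.

Within the 5-base window ending at the Stem I specifier bulge, three triplet
registers are examined: '+0' (the priority region, bases 2-4 from the bulge
end), '-1' (one base 5') and '+1' (one base 3').  Each frame is scored on two
equally weighted criteria:

* **discriminator pairing** — the variable base of the T-box bulge
  (5'-UGGN-3') must pair the discriminator base of the host's tRNA of the
  frame's family, Watson-Crick or G:U wobble.  Skipped (not-applicable) for
  His frames, because mature tRNA-His can carry an internally paired
  discriminator, and when the UGGN bulge is absent.  When the host has no
  tRNA of the family, the modal base from a discriminator-frequency table
  stands in.
* **downstream ontology** — the annotated downstream gene maps to the same
  amino-acid family via a keyword table.  Not-applicable when no annotation
  or no keyword matches.

The top frame is the highest score, ties resolved '+0' > '-1' > '+1'.
Cognate-tRNA matching is separate and stricter: the host tRNA anticodon must
equal the reverse complement of the specifier exactly — no wobble.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

from .genetics import RNA_BASES, aa_from_codon, can_pair, revcomp
from .seqio import TrnaRecord

#: frame preference order for tie-breaking
FRAME_ORDER = ("plus0", "minus1", "plus1")

#: display labels matching the field's usual notation
FRAME_LABELS = {"plus0": "+0", "minus1": "-1", "plus1": "+1"}


def aa_from_specifier(triplet: str) -> str:
    """One-letter amino-acid family of a specifier read as a codon
    ('*' for stops, 'X' when undetermined)."""
    return aa_from_codon(triplet)


def frames_of(window: str) -> dict[str, str]:
    """The three candidate triplets of a 5-base window.

    '+0' is the priority region window[1:4]; '-1' and '+1' shift one base 5'
    and 3' respectively.
    """
    if len(window) != 5:
        raise ValueError(f"specifier window must have length 5, got {len(window)}")
    return {"minus1": window[0:3], "plus0": window[1:4], "plus1": window[2:5]}


def pairs_discriminator(tbox_n: str, discriminator: str) -> Optional[bool]:
    """Can the variable T-box bulge base pair the tRNA discriminator?

    Watson-Crick or G:U wobble.  Returns None (not-applicable) when either
    base is unknown — distinct from False.
    """
    if tbox_n not in RNA_BASES or discriminator not in RNA_BASES:
        return None
    return can_pair(tbox_n, discriminator, wobble=True)


# ---------------------------------------------------------------------------
# bundled tables
# ---------------------------------------------------------------------------

def _read_table(path: Optional[str | Path], resource: str) -> list[tuple[str, str]]:
    if path is None:
        text = (importlib.resources.files("tboxkit.data") / resource).read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t") if "\t" in line else line.split(None, 1)
        rows.append((key.strip(), value.strip()))
    return rows


def load_ontology_table(path: Optional[str | Path] = None) -> dict[str, str]:
    """keyword (lower-cased) -> one-letter family."""
    return {k.lower(): v for k, v in _read_table(path, "ontology_keywords.tsv")}


def load_discriminator_table(path: Optional[str | Path] = None) -> dict[str, str]:
    """one-letter family -> modal discriminator base."""
    return dict(_read_table(path, "discriminator_freq.tsv"))


@lru_cache(maxsize=1)
def default_ontology_table() -> dict[str, str]:
    return load_ontology_table()


@lru_cache(maxsize=1)
def default_discriminator_table() -> dict[str, str]:
    return load_discriminator_table()


def families_from_text(text: str, table: Optional[dict[str, str]] = None) -> set[str]:
    """Families whose keywords occur in a gene/product description.

    Longer keywords mask the span they match, so overlapping shorter keywords
    (e.g. 'leucyl' inside 'isoleucyl') do not fire.
    """
    if table is None:
        table = default_ontology_table()
    low = text.lower()
    masked = [False] * len(low)
    found: set[str] = set()
    for keyword in sorted(table, key=len, reverse=True):
        start = 0
        while (idx := low.find(keyword, start)) != -1:
            span = range(idx, idx + len(keyword))
            if not any(masked[i] for i in span):
                found.add(table[keyword])
                for i in span:
                    masked[i] = True
            start = idx + 1
    return found


# ---------------------------------------------------------------------------
# frame evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameEvaluation:
    frame: str  # {"minus1", "plus0", "plus1"}
    triplet: str
    aa_family: str
    anticodon_expected: str
    discriminator_ok: Optional[bool]  # None = not-applicable
    ontology_ok: Optional[bool]
    score: int


@dataclass(frozen=True)
class SpecifierCall:
    """The top specifier assignment plus the alternative frames."""

    top: FrameEvaluation
    alternatives: tuple[FrameEvaluation, ...]
    n_frames_viable: int  # frames attaining the top score
    tbox_uggn: Optional[str] = None

    @property
    def evaluations(self) -> tuple[FrameEvaluation, ...]:
        return (self.top, *self.alternatives)


def host_discriminator(
    family: str,
    host_trnas: list[TrnaRecord],
    fallback: Optional[dict[str, str]] = None,
) -> Optional[str]:
    """Discriminator base the host uses for a tRNA family.

    Modal base over the host's tRNAs of that family (ties resolved toward the
    highest-scoring tRNA); when the host has none with a known discriminator,
    the modal base from the frequency table; None when neither is available.
    """
    known = [
        t for t in host_trnas
        if t.family == family and t.discriminator in RNA_BASES
    ]
    if known:
        counts = Counter(t.discriminator for t in known)
        top_count = max(counts.values())
        modal = {b for b, c in counts.items() if c == top_count}
        if len(modal) == 1:
            return modal.pop()
        for t in sorted(known, key=lambda t: (-t.score, t.record_id)):
            if t.discriminator in modal:
                return t.discriminator
    if fallback is None:
        fallback = default_discriminator_table()
    return fallback.get(family)


def evaluate_frames(
    window: str,
    tbox_uggn: Optional[str],
    host_trnas: list[TrnaRecord],
    downstream_annotation: Optional[str] = None,
    discriminator_fallback: Optional[dict[str, str]] = None,
    ontology_table: Optional[dict[str, str]] = None,
) -> SpecifierCall:
    """Score the three frames and assign the top specifier.

    Degenerate inputs never raise: unavailable evidence renders a criterion
    not-applicable (contributing 0), and an all-tie resolves by the '+0' >
    '-1' > '+1' preference.
    """
    ontology_families: Optional[set[str]] = None
    if downstream_annotation:
        ontology_families = families_from_text(downstream_annotation, ontology_table)
        if not ontology_families:
            ontology_families = None  # no signal: not-applicable, not a veto

    evaluations: list[FrameEvaluation] = []
    for frame in FRAME_ORDER:
        triplet = frames_of(window)[frame]
        aa = aa_from_specifier(triplet)

        disc_ok: Optional[bool] = None
        if tbox_uggn is not None and len(tbox_uggn) == 4 and aa not in ("H", "*", "X"):
            d = host_discriminator(aa, host_trnas, discriminator_fallback)
            if d is not None:
                disc_ok = pairs_discriminator(tbox_uggn[3], d)

        ont_ok: Optional[bool] = None
        if ontology_families is not None and aa not in ("*", "X"):
            ont_ok = aa in ontology_families

        evaluations.append(
            FrameEvaluation(
                frame=frame,
                triplet=triplet,
                aa_family=aa,
                anticodon_expected=revcomp(triplet),
                discriminator_ok=disc_ok,
                ontology_ok=ont_ok,
                score=sum(1 for c in (disc_ok, ont_ok) if c is True),
            )
        )

    top_score = max(e.score for e in evaluations)
    ranked = sorted(
        evaluations, key=lambda e: (-e.score, FRAME_ORDER.index(e.frame))
    )
    return SpecifierCall(
        top=ranked[0],
        alternatives=tuple(ranked[1:]),
        n_frames_viable=sum(1 for e in evaluations if e.score == top_score),
        tbox_uggn=tbox_uggn,
    )


def match_anticodon(
    triplet: str, host_trnas: list[TrnaRecord]
) -> Optional[TrnaRecord]:
    """Highest-scoring host tRNA whose anticodon is exactly the reverse
    complement of the specifier (no wobble); None when the host has none.

    Score ties break lexicographically on the record id, so the result is
    invariant under permutation of the input.
    """
    target = revcomp(triplet)
    candidates = [t for t in host_trnas if t.anticodon == target]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (-t.score, t.record_id))
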