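"""Curation trimming, intrinsic-terminator search, and free-energy evaluation.

The energy model is a simplified additive nearest-neighbor decomposition —
stack free energies over consecutive pairs, loop initiation penalties, and
terminal AU/GU penalties — loaded from a plain-text parameter file bundled
with the package.  It evaluates *given* structures (and a hairpin-restricted
local search); it does not fold arbitrary sequences.  A pluggable backend
(``backend="external"``) delegates evaluation to the ViennaRNA bindings when
they are installed; absolute kcal/mol values then follow that engine.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Optional

from .annotate import StructureAnnotation, pair_table
from .errors import StructureFormatError, UnsupportedStructureError
from .genetics import can_pair
from .seqio import Interval, TboxRecord

RT = 0.616  # kcal/mol at 37 C
_AU_GU_ENDS = frozenset({"AU", "UA", "GU", "UG"})
_PSEUDOKNOT_CHARS = set("[]{}<>AaBbCcDd")

POLYU_RUN = re.compile(r"U{5,}")


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

def _rev(pair: str) -> str:
    return pair[::-1]


@dataclass(frozen=True)
class EnergyModel:
    """Additive nearest-neighbor parameter set.

    ``stacks`` is keyed by (outer pair, inner pair) two-character strings; the
    loop tables extrapolate logarithmically beyond their largest tabulated
    size.  All penalties are >= 0; Watson-Crick stacks are <= 0.
    """

    stacks: dict[tuple[str, str], float]
    hairpin_table: dict[int, float]
    bulge_table: dict[int, float]
    internal_table: dict[int, float]
    au_end_penalty: float = 0.5
    multiloop_init: float = 3.4
    multiloop_branch: float = 0.4
    multiloop_unpaired: float = 0.0

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stacks[(outer, inner)]

    def hairpin_penalty(self, size: int) -> float:
        return _loop(self.hairpin_table, size)

    def bulge_penalty(self, size: int) -> float:
        return _loop(self.bulge_table, size)

    def internal_penalty(self, size: int) -> float:
        return _loop(self.internal_table, size)


def _loop(table: dict[int, float], size: int) -> float:
    if size in table:
        return table[size]
    nmax = max(table)
    if size < min(table):
        return table[min(table)]
    return table[nmax] + 1.75 * RT * math.log(size / nmax)


def load_energy_model(path=None) -> EnergyModel:
    """Load parameters from a key-value text file (bundled file by default)."""
    if path is None:
        source = importlib.resources.files("tboxkit.data") / "nn_params.txt"
        text = source.read_text()
    else:
        with open(path) as handle:
            text = handle.read()
    stacks: dict[tuple[str, str], float] = {}
    hairpin: dict[int, float] = {}
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    scalars: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        key = fields[0]
        if key == "stack":
            outer, inner, dg = fields[1], fields[2], float(fields[3])
            stacks[(outer, inner)] = dg
            stacks.setdefault((_rev(inner), _rev(outer)), dg)
        elif key in ("hairpin", "bulge", "internal"):
            {"hairpin": hairpin, "bulge": bulge, "internal": internal}[key][
                int(fields[1])
            ] = float(fields[2])
        else:
            scalars[key] = float(fields[1])
    return EnergyModel(
        stacks=stacks,
        hairpin_table=hairpin,
        bulge_table=bulge,
        internal_table=internal,
        au_end_penalty=scalars.get("au_end", 0.5),
        multiloop_init=scalars.get("multiloop_init", 3.4),
        multiloop_branch=scalars.get("multiloop_branch", 0.4),
        multiloop_unpaired=scalars.get("multiloop_unpaired", 0.0),
    )


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    return load_energy_model()


# ---------------------------------------------------------------------------
# structure evaluation
# ---------------------------------------------------------------------------

def energy_of(sequence: str, dotbracket: str, model: Optional[EnergyModel] = None) -> float:
    """Free energy of a given nested structure under the additive model.

    The all-unpaired structure scores 0.0.  Pseudoknot notation raises
    :class:`UnsupportedStructureError`; a bracket forcing a non-pairable base
    combination raises :class:`StructureFormatError` naming the position.
    """
    if model is None:
        model = default_model()
    if len(sequence) != len(dotbracket):
        raise StructureFormatError(
            f"sequence ({len(sequence)}) and structure ({len(dotbracket)}) lengths differ"
        )
    if _PSEUDOKNOT_CHARS & set(dotbracket):
        raise UnsupportedStructureError("pseudoknotted structures are not supported")
    bad = set(dotbracket) - set("().")
    if bad:
        raise StructureFormatError(f"invalid structure characters {sorted(bad)}")

    table = pair_table(dotbracket)
    for i, j in enumerate(table):
        if j is not None and i < j and not can_pair(sequence[i], sequence[j]):
            raise StructureFormatError(
                f"positions {i} and {j} force a non-pairable "
                f"{sequence[i]}:{sequence[j]} pair"
            )

    # build the nesting tree: parent/children per pair
    children: dict[Optional[tuple[int, int]], list[tuple[int, int]]] = {None: []}
    parent: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    stack: list[tuple[int, int]] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            node = (i, table[i])  # type: ignore[arg-type]
            parent[node] = stack[-1] if stack else None
            children.setdefault(node, [])
            children[parent[node]].append(node)
            stack.append(node)
        elif ch == ")":
            stack.pop()

    energy = 0.0
    for node, kids in children.items():
        if node is None:
            continue
        i, j = node
        outer = sequence[i] + sequence[j]
        if not kids:
            energy += model.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            inner = sequence[k] + sequence[l]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                energy += model.stack_energy(outer, inner)
            elif left == 0 or right == 0:
                size = left + right
                energy += model.bulge_penalty(size)
                if size == 1:  # single-base bulges keep the flanking stack
                    energy += model.stack_energy(outer, inner)
            else:
                energy += model.internal_penalty(left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += (
                model.multiloop_init
                + model.multiloop_branch * (len(kids) + 1)
                + model.multiloop_unpaired * unpaired
            )
        # terminal AU/GU penalties at helix ends
        if outer in _AU_GU_ENDS:
            if parent[node] != (i - 1, j + 1):
                energy += model.au_end_penalty
            if not (len(kids) == 1 and kids[0] == (i + 1, j - 1)):
                energy += model.au_end_penalty
    return round(energy, 10)


def eval_structure(
    sequence: str,
    dotbracket: str,
    model: Optional[EnergyModel] = None,
    backend: str = "builtin",
) -> float:
    """Evaluate a structure with the selected backend (``builtin``/``external``)."""
    if backend == "builtin":
        return energy_of(sequence, dotbracket, model)
    if backend == "external":
        try:
            import RNA  # type: ignore[import-not-found]
        except ImportError as exc:
            raise RuntimeError(
                "backend 'external' requires the ViennaRNA python bindings"
            ) from exc
        return float(RNA.energy_of_struct(sequence, dotbracket))
    raise ValueError(f"unknown thermo backend {backend!r}")


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def curate(
    records: list[TboxRecord], min_len: int = 100, max_len: int = 500
) -> tuple[list[TboxRecord], list[tuple[TboxRecord, str]]]:
    """Drop too-short (<min_len), too-long (>max_len) and duplicate sequences.

    The length inequalities are strict, so min_len and max_len themselves are
    kept.  The first occurrence of a duplicated sequence is kept.  Returns
    (kept, dropped-with-reasons).
    """
    kept: list[TboxRecord] = []
    dropped: list[tuple[TboxRecord, str]] = []
    seen: set[str] = set()
    for rec in records:
        n = len(rec.sequence)
        if n < min_len:
            dropped.append((rec, f"too short ({n} < {min_len} nt)"))
        elif n > max_len:
            dropped.append((rec, f"too long ({n} > {max_len} nt)"))
        elif rec.sequence in seen:
            dropped.append((rec, "redundant (duplicate sequence)"))
        else:
            seen.add(rec.sequence)
            kept.append(rec)
    return kept, dropped


class TrimResult(NamedTuple):
    sequence: str
    had_polyU: bool  # False = no >=5-U run found, sequence returned unchanged


def trim_to_polyU(sequence: str) -> TrimResult:
    """Trim to end at the last base of the 3'-most run of >=5 consecutive U.

    Without such a run the sequence is returned unchanged with the no-trim
    flag (``had_polyU=False``).
    """
    last = None
    for m in POLYU_RUN.finditer(sequence):
        last = m
    if last is None:
        return TrimResult(sequence, False)
    return TrimResult(sequence[: last.end()], True)


# ---------------------------------------------------------------------------
# terminator search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminatorCall:
    """A terminator hairpin followed by a poly-U tract."""

    hairpin_interval: Interval
    hairpin_dotbracket: str
    polyU_interval: Interval
    energy: float

    def __post_init__(self) -> None:
        if self.polyU_interval[0] < self.hairpin_interval[1]:
            raise StructureFormatError("poly-U tract must begin at or after the hairpin end")


def find_terminator(
    sequence: str,
    annotation: StructureAnnotation,
    model: Optional[EnergyModel] = None,
    min_stem: int = 4,
    min_loop: int = 3,
    max_loop: int = 10,
    max_gap: int = 3,
    max_stem: int = 30,
) -> Optional[TerminatorCall]:
    """Minimum-energy single stem-loop upstream of a poly-U tract, or None.

    The search region runs from the antiterminator start to the sequence end.
    A candidate hairpin is a perfect stem of ``min_stem``..``max_stem``
    WC-or-wobble pairs around a loop of ``min_loop``..``max_loop`` bases whose
    3' end lies at most ``max_gap`` nucleotides upstream of a run of >=5 U.
    Ties in energy resolve to the 5'-most, then longest-stem candidate.
    """
    if model is None:
        model = default_model()
    region_start = annotation.features["antiterminator"][0]
    best: Optional[tuple[float, int, int, TerminatorCall]] = None
    for run in POLYU_RUN.finditer(sequence, region_start):
        rs, re_ = run.start(), run.end()
        for end in range(max(region_start, rs - max_gap), rs + 1):
            for loop in range(min_loop, max_loop + 1):
                for stem in range(min_stem, max_stem + 1):
                    start = end - (2 * stem + loop)
                    if start < region_start:
                        break
                    if not all(
                        can_pair(sequence[start + k], sequence[end - 1 - k])
                        for k in range(stem)
                    ):
                        continue
                    db = "(" * stem + "." * loop + ")" * stem
                    e = energy_of(sequence[start:end], db, model)
                    key = (e, start, -stem)
                    if best is None or key < (best[0], best[1], best[2]):
                        best = (e, start, -stem, TerminatorCall(
                            hairpin_interval=(start, end),
                            hairpin_dotbracket=db,
                            polyU_interval=(rs, re_),
                            energy=e,
                        ))
    return best[3] if best else None


# ---------------------------------------------------------------------------
# MFE of both folds
# ---------------------------------------------------------------------------

def terminator_state_structure(
    annotation: StructureAnnotation, terminator: TerminatorCall
) -> str:
    """Dot-bracket of the terminator state: the antiterminator span unfolds,
    the terminator hairpin forms, everything else keeps the reported fold."""
    dot = list(annotation.dotbracket)
    table = pair_table(annotation.dotbracket)
    a0, a1 = annotation.features["antiterminator"]
    h0, h1 = terminator.hairpin_interval

    def _in_cleared(pos: int) -> bool:
        return a0 <= pos < a1 or h0 <= pos < h1

    for i, j in enumerate(table):
        if j is not None and (_in_cleared(i) or _in_cleared(j)):
            dot[i] = dot[j] = "."
    dot[h0:h1] = terminator.hairpin_dotbracket
    return "".join(dot)


def mfe_pair(
    record: TboxRecord,
    annotation: StructureAnnotation,
    model: Optional[EnergyModel] = None,
    terminator: Optional[TerminatorCall] = None,
    backend: str = "builtin",
) -> tuple[float, Optional[float]]:
    """Free energies of the antiterminator-state fold and, when a terminator
    call exists (searched here if not supplied), of the terminator-state fold."""
    if terminator is None:
        terminator = find_terminator(record.sequence, annotation, model)
    mfe_anti = eval_structure(record.sequence, annotation.dotbracket, model, backend)
    if terminator is None:
        return mfe_anti, None
    term_db = terminator_state_structure(annotation, terminator)
    return mfe_anti, eval_structure(record.sequence, term_db, model, backend)
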