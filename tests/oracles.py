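"""Independent brute-force oracles for the thermodynamic operations.

These re-derive the additive nearest-neighbor decomposition and the
terminator search directly from their definitions — recursive string
scanning and exhaustive candidate enumeration — sharing only the parameter
tables with the implementation, never its code paths.
"""

from __future__ import annotations

import random
import re
from typing import Optional

from tboxkit.terminator_thermo import EnergyModel

AU_GU = {"AU", "UA", "GU", "UG"}
PAIRABLE = {"AU", "UA", "GC", "CG", "GU", "UG"}


def _children(db: str, i: int, j: int) -> list[tuple[int, int]]:
    """Immediate pair spans within db[i:j]."""
    out = []
    k = i
    while k < j:
        if db[k] == "(":
            depth, m = 1, k
            while depth:
                m += 1
                depth += (db[m] == "(") - (db[m] == ")")
            out.append((k, m))
            k = m + 1
        else:
            k += 1
    return out


def oracle_energy(seq: str, db: str, model: EnergyModel) -> float:
    """Recursive evaluation of the additive decomposition."""

    def eval_pair(i: int, j: int, parent: Optional[tuple[int, int]]) -> float:
        kids = _children(db, i + 1, j)
        outer = seq[i] + seq[j]
        if not kids:
            e = model.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            left, right = k - i - 1, j - l - 1
            inner = seq[k] + seq[l]
            if left == 0 and right == 0:
                e = model.stack_energy(outer, inner)
            elif min(left, right) == 0:
                e = model.bulge_penalty(left + right)
                if left + right == 1:
                    e += model.stack_energy(outer, inner)
            else:
                e = model.internal_penalty(left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for (k, l) in kids)
            e = (model.multiloop_init + model.multiloop_branch * (len(kids) + 1)
                 + model.multiloop_unpaired * unpaired)
        if outer in AU_GU:
            if parent != (i - 1, j + 1):
                e += model.au_end_penalty
            if not (len(kids) == 1 and kids[0] == (i + 1, j - 1)):
                e += model.au_end_penalty
        return e + sum(eval_pair(k, l, (i, j)) for (k, l) in kids)

    return round(sum(eval_pair(i, j, None) for (i, j) in _children(db, 0, len(db))), 10)


def oracle_find_terminator(seq: str, region_start: int, model: EnergyModel,
                           min_stem: int = 4, min_loop: int = 3,
                           max_loop: int = 10, max_gap: int = 3):
    """Exhaustive enumeration of qualifying tail-anchored hairpins.

    Returns (interval, dotbracket, polyU interval, energy) or None, with the
    same (energy, start, -stem) tie-break the contract specifies.
    """
    best = None
    for run in re.compile("U{5,}").finditer(seq, region_start):
        rs, re_ = run.start(), run.end()
        for end in range(region_start, len(seq) + 1):
            if not (0 <= rs - end <= max_gap):
                continue
            for start in range(region_start, end):
                span = end - start
                for stem in range(min_stem, span // 2 + 1):
                    loop = span - 2 * stem
                    if not (min_loop <= loop <= max_loop):
                        continue
                    if any(seq[start + k] + seq[end - 1 - k] not in PAIRABLE
                           for k in range(stem)):
                        continue
                    db = "(" * stem + "." * loop + ")" * stem
                    e = oracle_energy(seq[start:end], db, model)
                    key = (e, start, -stem)
                    if best is None or key < best[0]:
                        best = (key, ((start, end), db, (rs, re_), e))
    return best[1] if best else None


# ---------------------------------------------------------------------------
# structure / sequence generators for oracle comparisons
# ---------------------------------------------------------------------------

def all_nested_structures(n: int, min_loop: int = 3) -> list[str]:
    """Every dot-bracket string of length n whose hairpin loops are >= min_loop."""
    memo: dict[int, list[str]] = {0: [""]}

    def gen(m: int) -> list[str]:
        if m in memo:
            return memo[m]
        out = ["." + s for s in gen(m - 1)]
        for k in range(2, m + 1):  # pair (0, k-1)
            for inner in gen(k - 2):
                if "(" not in inner and len(inner) < min_loop:
                    continue
                for rest in gen(m - k):
                    out.append("(" + inner + ")" + rest)
        memo[m] = out
        return out

    return [s for s in gen(n) if _loops_ok(s, min_loop)]


def _loops_ok(db: str, min_loop: int) -> bool:
    for i, j in _all_pairs(db):
        if not _children(db, i + 1, j) and j - i - 1 < min_loop:
            return False
    return True


def _all_pairs(db: str) -> list[tuple[int, int]]:
    stack, pairs = [], []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return pairs


def compatible_sequence(db: str, rng: random.Random) -> str:
    """A random sequence whose bases can form every pair db demands."""
    seq = [rng.choice("ACGU") for _ in db]
    for i, j in _all_pairs(db):
        seq[i], seq[j] = rng.choice(sorted(PAIRABLE))
    return "".join(seq)


def random_nested_structure(n: int, rng: random.Random, min_loop: int = 3) -> str:
    """One random dot-bracket string of length n with hairpin loops >= min_loop."""

    def gen(m: int) -> str:
        if m < 2 + min_loop or rng.random() < 0.3:
            return "." * m
        k = rng.randint(2 + min_loop, m)  # span of the leading pair
        inner = gen(k - 2)
        if "(" not in inner and len(inner) < min_loop:
            inner = "." * (k - 2)
            if len(inner) < min_loop:
                return "." * m
        return "(" + inner + ")" + gen(m - k)

    return gen(n)
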