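"""Deterministic generator of synthetic riboswitch leaders with ground truth.

Fixtures are grammar-composed against the bundled consensus column maps
(:mod:`tboxkit.models`), not sampled from real genomes: every conserved
element is planted at known positions, so the generator can emit — for the
same sequence — the FASTA record, the aligned search hit, the host tRNA set,
and a machine-readable ground-truth annotation.  Random filler is drawn so
the evidence stays unambiguous: no stray >=5-U runs outside the planted
poly-U tail, no competing terminator-strength hairpin near the tail, and
window edges chosen so the shifted specifier frames fall outside the planted
family whenever the genetic code allows it.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import StructureAnnotation
from .errors import FixtureSpecError
from .genetics import (
    CODONS_BY_FAMILY,
    RNA_BASES,
    SYNTHETASE_NAMES,
    aa_from_codon,
    can_pair,
    complement,
    revcomp,
)
from .models import CLASS_I, CLASS_II, ModelColumnMap
from .seqio import (
    StructureSearchHit,
    TboxRecord,
    TrnaRecord,
    write_aligned_hits,
    write_fasta,
    write_trna_fasta,
)

SENSE_CODONS = tuple(
    c for fam, codons in CODONS_BY_FAMILY.items() if fam not in ("*", "X")
    for c in codons
)

_PAD5 = 5          # unaligned 5' padding before the model region
_SPACER = "GAC"    # between antiterminator and terminator; ends avoid A/G-U pairing
_TAIL3 = 30        # 3' filler when no terminator/poly-U is planted
_TERM_STEM = 8
_TERM_LOOP = 4
_POLYU = "UUUUU"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic riboswitch leader."""

    seed: int
    tbox_class: str = "I"
    specifier: str = "UGG"
    uggn_n: str = "A"
    with_terminator: bool = True
    with_polyU: bool = True
    ontology_text: Optional[str] = ""  # "" = derive from the specifier family
    host_discriminator: Optional[str] = None  # None = WC complement of uggn_n
    decoys: int = 4
    host_name: str = ""
    record_id: str = ""
    delete_tbox_bulge: bool = False

    def __post_init__(self) -> None:
        if self.tbox_class not in ("I", "II"):
            raise FixtureSpecError(f"unknown class {self.tbox_class!r}")
        if len(self.specifier) != 3 or not set(self.specifier) <= RNA_BASES:
            raise FixtureSpecError(f"specifier {self.specifier!r} is not a valid codon")
        if self.uggn_n not in RNA_BASES:
            raise FixtureSpecError(f"uggn_n {self.uggn_n!r} is not a base")
        if self.with_terminator and not self.with_polyU:
            raise FixtureSpecError("a terminator requires a poly-U tail (with_polyU)")
        if self.host_discriminator is not None and self.host_discriminator not in RNA_BASES:
            raise FixtureSpecError(f"bad discriminator {self.host_discriminator!r}")
        if self.decoys < 0:
            raise FixtureSpecError("decoys must be >= 0")

    @property
    def family(self) -> str:
        return aa_from_codon(self.specifier)

    @property
    def effective_discriminator(self) -> str:
        if self.host_discriminator is not None:
            return self.host_discriminator
        return complement(self.uggn_n)

    @property
    def effective_ontology(self) -> Optional[str]:
        if self.ontology_text == "":
            return SYNTHETASE_NAMES.get(self.family)
        return self.ontology_text or None

    @property
    def model(self) -> ModelColumnMap:
        return CLASS_I if self.tbox_class == "I" else CLASS_II


# ---------------------------------------------------------------------------
# sequence composition
# ---------------------------------------------------------------------------

def _random_run_free(rng: random.Random, n: int, alphabet: str = "ACGU") -> str:
    """n random bases with no more than 3 consecutive U."""
    out: list[str] = []
    for _ in range(n):
        choices = alphabet.replace("U", "") if "".join(out[-3:]) == "UUU" else alphabet
        out.append(rng.choice(choices))
    return "".join(out)


def _instantiate_model(rng: random.Random, spec: FixtureSpec) -> list[str]:
    """Assign one base per model column, honouring pairing and planted motifs."""
    model = spec.model
    ss = model.ss_cons
    inst = [""] * model.ncols

    # pair model columns (the consensus is nested by construction)
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(ss):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            pairs.append((stack.pop(), k))

    for i, j in pairs:
        left = rng.choice("ACGU")
        inst[i], inst[j] = left, complement(left)

    for k, ch in enumerate(ss):
        if ch == "." and not inst[k]:
            inst[k] = rng.choice("ACGU")

    # plant the specifier window at the 3' end of the specifier bulge:
    # bulge columns [..., w0, s0, s1, s2, w4]; the priority (+0) frame is the
    # planted specifier, the window edges avoid U and, when possible, keep the
    # shifted frames outside the planted family.
    b0, b1 = model.features["specifier_bulge"]
    s = spec.specifier
    inst[b1 - 4], inst[b1 - 3], inst[b1 - 2] = s[0], s[1], s[2]
    fam = spec.family
    w0_opts = [b for b in "ACG" if aa_from_codon(b + s[0] + s[1]) != fam] or list("ACG")
    w4_opts = [b for b in "ACG" if aa_from_codon(s[1] + s[2] + b) != fam] or list("ACG")
    inst[b1 - 5] = rng.choice(w0_opts)
    inst[b1 - 1] = rng.choice(w4_opts)

    # plant the T-box bulge
    t0, _ = model.features["tbox_bulge"]
    for off, base in enumerate("UGG" + spec.uggn_n):
        inst[t0 + off] = base
    return inst


def _terminator_block(rng: random.Random) -> str:
    """GC-only stem around an A/C loop; arm starts with G so the upstream
    spacer cannot extend the stem."""
    arm = "G" + "".join(rng.choice("GC") for _ in range(_TERM_STEM - 1))
    loop = "".join(rng.choice("AC") for _ in range(_TERM_LOOP))
    return arm + loop + revcomp(arm)


def _competing_stem(sequence: str, planted: tuple[int, int], run_start: int,
                    region_start: int) -> bool:
    """Does any other tail-anchored hairpin tie or beat the planted one?

    The planted terminator must be the unique minimum-energy qualifying
    hairpin under the bundled energy model, else the ground truth would be
    ambiguous.  Candidates sharing the planted boundaries are sub-stems with
    larger loops and strictly fewer stacks; they always lose.
    """
    from .terminator_thermo import default_model, energy_of

    model = default_model()
    p0, p1 = planted
    stem_p = _TERM_STEM
    planted_db = "(" * stem_p + "." * _TERM_LOOP + ")" * stem_p
    planted_e = energy_of(sequence[p0:p1], planted_db, model)
    for end in range(max(region_start, run_start - 3), run_start + 1):
        for loop in range(3, 11):
            for stem in range(4, 31):
                start = end - (2 * stem + loop)
                if start < region_start:
                    break
                if (start, end) == planted:
                    continue
                if all(
                    can_pair(sequence[start + k], sequence[end - 1 - k])
                    for k in range(stem)
                ):
                    db = "(" * stem + "." * loop + ")" * stem
                    if energy_of(sequence[start:end], db, model) <= planted_e:
                        return True
    return False


def make_tbox(spec: FixtureSpec) -> tuple[TboxRecord, StructureSearchHit, StructureAnnotation]:
    """Compose one leader; returns (record, aligned hit, ground truth)."""
    model = spec.model
    for attempt in range(64):
        rng = random.Random((spec.seed * 1000003 + attempt) % 2**31)
        inst = _instantiate_model(rng, spec)

        deleted = set()
        if spec.delete_tbox_bulge:
            t0, t1 = model.features["tbox_bulge"]
            deleted = set(range(t0, t1))

        pad5 = _random_run_free(rng, _PAD5)
        region = "".join(inst[k] for k in range(model.ncols) if k not in deleted)
        downstream = ""
        term_rel: Optional[tuple[int, int]] = None
        polyU_rel: Optional[tuple[int, int]] = None
        if spec.with_terminator:
            block = _terminator_block(rng)
            term_rel = (len(_SPACER), len(_SPACER) + len(block))
            polyU_rel = (term_rel[1], term_rel[1] + len(_POLYU))
            downstream = _SPACER + block + _POLYU
        elif spec.with_polyU:
            polyU_rel = (len(_SPACER), len(_SPACER) + len(_POLYU))
            downstream = _SPACER + _POLYU
        else:
            downstream = _SPACER + _random_run_free(rng, _TAIL3)

        sequence = pad5 + region + downstream
        core_end = len(pad5 + region)

        # reject compositions whose randomness blurs the ground truth
        polyU_abs = (
            (core_end + polyU_rel[0], core_end + polyU_rel[1]) if polyU_rel else None
        )
        check_to = polyU_abs[0] if polyU_abs else len(sequence)
        if "UUUUU" in sequence[:check_to]:
            continue
        if spec.with_terminator:
            term_abs = (core_end + term_rel[0], core_end + term_rel[1])
            anti_start = _PAD5 + _map_cols(model, deleted)[
                model.features["antiterminator"][0]
            ]
            if _competing_stem(sequence, term_abs, polyU_abs[0], anti_start):
                continue
        break
    else:  # pragma: no cover - 64 rejections would mean a generator defect
        raise FixtureSpecError(f"could not compose an unambiguous fixture for {spec}")

    col_to_pos = _map_cols(model, deleted)
    features: dict[str, tuple[int, int]] = {}
    for name, (c0, c1) in model.features.items():
        kept = [col_to_pos[k] for k in range(c0, c1) if k not in deleted]
        if kept:
            features[name] = (_PAD5 + kept[0], _PAD5 + kept[-1] + 1)
    if spec.with_terminator:
        features["terminator"] = term_abs
    if polyU_abs:
        features["polyU"] = polyU_abs

    dot = ["."] * len(sequence)
    stack: list[int] = []
    for k, ch in enumerate(model.ss_cons):
        if k in deleted:
            continue
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            i = stack.pop()
            dot[_PAD5 + col_to_pos[i]] = "("
            dot[_PAD5 + col_to_pos[k]] = ")"

    tbox_uggn = None if spec.delete_tbox_bulge else "UGG" + spec.uggn_n
    ground_truth = StructureAnnotation("".join(dot), features, tbox_uggn)

    record_id = spec.record_id or f"TBX{spec.seed:06d}"
    host = spec.host_name or f"synthhost{spec.seed:06d}"
    record = TboxRecord(
        record_id=record_id,
        sequence=sequence,
        host_name=host,
        source="synthetic",
        downstream_annotation=spec.effective_ontology,
    )
    aligned = "".join("-" if k in deleted else inst[k] for k in range(model.ncols))
    hit = StructureSearchHit(
        query_model=model.name,
        target_id=record_id,
        target_start=_PAD5,
        target_end=_PAD5 + len(region),
        strand="+",
        score=round(rng.uniform(40.0, 120.0), 1),
        consensus_structure=model.ss_cons,
        aligned_sequence=aligned,
    )
    return record, hit, ground_truth


def _map_cols(model: ModelColumnMap, deleted: set[int]) -> dict[int, int]:
    """model column -> position within the (pad-less) hit region."""
    mapping: dict[int, int] = {}
    pos = 0
    for k in range(model.ncols):
        if k not in deleted:
            mapping[k] = pos
            pos += 1
    return mapping


# ---------------------------------------------------------------------------
# host tRNA sets
# ---------------------------------------------------------------------------

def make_host_trnas(spec: FixtureSpec) -> list[TrnaRecord]:
    """Cognate tRNA (anticodon = revcomp of the specifier, planted
    discriminator) plus ``spec.decoys`` tRNAs of other families."""
    rng = random.Random((spec.seed * 7130429 + 11) % 2**31)
    host = spec.host_name or f"synthhost{spec.seed:06d}"
    cognate_ac = revcomp(spec.specifier)
    records = [
        TrnaRecord(
            host_name=host,
            anticodon=cognate_ac,
            sequence=_random_run_free(rng, 60) + spec.effective_discriminator + "CCA",
            score=round(rng.uniform(60.0, 100.0), 1),
            record_id=f"{host}.trna1",
        )
    ]
    n = 1
    while n <= spec.decoys:
        ac = "".join(rng.choice("ACGU") for _ in range(3))
        if ac == cognate_ac or aa_from_codon(revcomp(ac)) in (spec.family, "*"):
            continue
        n += 1
        records.append(
            TrnaRecord(
                host_name=host,
                anticodon=ac,
                sequence=_random_run_free(rng, 60) + rng.choice("ACGU") + "CCA",
                score=round(rng.uniform(20.0, 95.0), 1),
                record_id=f"{host}.trna{n}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# whole corpora
# ---------------------------------------------------------------------------

#: families guaranteed early in every corpus (Met and Trp first)
_SPECIFIER_CYCLE = (
    "AUG", "UGG", "CAC", "AUC", "CUC", "GGC",
    "GAC", "UAC", "GCU", "ACC", "AAA", "UUC",
)

GROUND_TRUTH_COLUMNS = (
    "record_id", "host", "tbox_class", "specifier", "frame", "uggn",
    "stem1", "specifier_bulge", "antiterminator", "tbox_bulge",
    "terminator", "polyU", "anticodon", "discriminator", "consistent",
)


@dataclass
class Corpus:
    """An in-memory synthetic dataset plus, when written, its file paths."""

    records: list[TboxRecord]
    hits: list[StructureSearchHit]
    trnas: list[TrnaRecord]
    ground_truth: list[dict]
    annotations: list[StructureAnnotation]
    paths: dict[str, Path] = field(default_factory=dict)


def make_corpus(n: int, seed: int, outdir: Optional[str | Path] = None) -> Corpus:
    """Generate ``n`` fixtures spanning families and classes.

    The first twelve records walk a fixed family cycle (Met and Trp first),
    the rest draw random sense codons.  Every fifth record is class II
    (translational: no terminator, no poly-U); one record in eleven has its
    T-box bulge deleted from the hit, emulating searches that cannot place
    the canonical UGGN.  When ``outdir`` is given, the FASTA, aligned-hit,
    tRNA and ground-truth files are written there.
    """
    if n < 1:
        raise FixtureSpecError("corpus size must be >= 1")
    rng = random.Random(seed % 2**31)
    corpus = Corpus([], [], [], [], [])
    for i in range(n):
        specifier = (
            _SPECIFIER_CYCLE[i]
            if i < len(_SPECIFIER_CYCLE)
            else rng.choice(SENSE_CODONS)
        )
        tbox_class = "II" if i % 5 == 4 else "I"
        deleted = i % 11 == 10
        spec = FixtureSpec(
            seed=(seed * 100003 + i * 17 + 1) % 2**31,
            tbox_class=tbox_class,
            specifier=specifier,
            uggn_n=rng.choice("ACGU"),
            with_terminator=tbox_class == "I",
            with_polyU=tbox_class == "I",
            decoys=rng.randint(2, 6),
            host_name=f"synthhost{i:03d}",
            record_id=f"TBX{i:03d}",
            delete_tbox_bulge=deleted,
        )
        record, hit, truth = make_tbox(spec)
        trnas = make_host_trnas(spec)
        corpus.records.append(record)
        corpus.hits.append(hit)
        corpus.trnas.extend(trnas)
        corpus.annotations.append(truth)
        fmt = lambda name: (
            f"{truth.features[name][0]}..{truth.features[name][1]}"
            if name in truth.features else ""
        )
        corpus.ground_truth.append(
            {
                "record_id": record.record_id,
                "host": record.host_name,
                "tbox_class": spec.tbox_class,
                "specifier": spec.specifier,
                "frame": "+0",
                "uggn": truth.tbox_uggn or "",
                "stem1": fmt("stem1"),
                "specifier_bulge": fmt("specifier_bulge"),
                "antiterminator": fmt("antiterminator"),
                "tbox_bulge": fmt("tbox_bulge"),
                "terminator": fmt("terminator"),
                "polyU": fmt("polyU"),
                "anticodon": revcomp(spec.specifier),
                "discriminator": spec.effective_discriminator,
                "consistent": "no" if deleted else "yes",
            }
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        corpus.paths = {
            "fasta": outdir / "leaders.fasta",
            "hits": outdir / "hits.sto",
            "trnas": outdir / "trnas.fasta",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        write_fasta(corpus.records, corpus.paths["fasta"])
        write_aligned_hits(corpus.hits, corpus.paths["hits"])
        write_trna_fasta(corpus.trnas, corpus.paths["trnas"])
        with open(corpus.paths["ground_truth"], "w") as handle:
            handle.write("\t".join(GROUND_TRUTH_COLUMNS) + "\n")
            for row in corpus.ground_truth:
                handle.write("\t".join(row[c] for c in GROUND_TRUTH_COLUMNS) + "\n")
    return corpus
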