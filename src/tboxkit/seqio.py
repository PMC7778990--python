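"""Readers and writers for every external format the pipeline touches.

Formats
-------
* FASTA leader sequences (via Biopython).
* Covariance-search hits in two dialects:

  - ``tabular``: whitespace-delimited lines with ``#`` comments and fields
    ``target query start end strand score`` (coordinates 1-based inclusive,
    minus-strand hits have start > end);
  - ``aligned``: Stockholm-style blocks, one hit per block, the aligned target
    on a ``name/start-end`` line and the model consensus structure on a
    ``#=GC SS_cons`` line.  ``#=GF CM`` names the model, ``#=GF SC`` carries
    the bit score.  Every alignment column is a model column; ``-`` or ``.``
    in the aligned sequence marks a model column deleted in the target
    (insertion columns are not part of this dialect).

* Host tRNA sets in two dialects: ``scanner_tabular`` (tRNA-scanner style
  columns, no sequence, discriminator unknown) and ``fasta_meta`` (FASTA with
  ``key=value`` metadata in the header; discriminator derived from the
  sequence).
* The flat-file annotation CSV (schema fixed by this package, see
  :data:`TBDB_COLUMNS`).

All coordinates are converted to 0-based half-open intervals at the boundary;
1-based inclusive coordinates exist only inside the files.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ParseError, StructureFormatError
from .genetics import (
    RNA_ALPHABET,
    UNDETERMINED,
    aa_from_codon,
    family_from_3letter,
    normalize_rna,
    revcomp,
)

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TboxRecord:
    """One riboswitch leader sequence with identity and provenance."""

    record_id: str
    sequence: str
    host_name: str = ""
    tbox_class: str = "unknown"  # {"I", "II", "unknown"}
    source: str = ""
    locus: Optional[tuple[str, int, int, str]] = None  # (contig, start, end, strand)
    downstream_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if not self.sequence:
            raise ParseError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.record_id!r}: invalid characters {sorted(bad)} in sequence"
            )
        if self.locus is not None and self.locus[2] <= self.locus[1]:
            raise ParseError(f"record {self.record_id!r}: locus end must exceed start")


@dataclass
class StructureSearchHit:
    """One covariance-model hit on a target sequence.

    ``target_start``/``target_end`` are 0-based half-open on the plus strand of
    the stored sequence; minus-strand source coordinates are flipped on read.
    """

    query_model: str
    target_id: str
    target_start: int
    target_end: int
    strand: str = "+"
    score: float = 0.0
    consensus_structure: str = ""
    aligned_sequence: str = ""

    def __post_init__(self) -> None:
        if len(self.consensus_structure) != len(self.aligned_sequence):
            raise StructureFormatError(
                f"hit {self.target_id!r}: consensus structure and aligned sequence "
                f"lengths differ ({len(self.consensus_structure)} vs "
                f"{len(self.aligned_sequence)})"
            )
        if self.consensus_structure:
            _check_balanced(self.consensus_structure, self.target_id)


@dataclass
class TrnaRecord:
    """A host tRNA with anticodon, family and (when known) discriminator base.

    The discriminator is the base immediately 5' of a 3'-terminal CCA when the
    sequence ends in CCA, else the 3'-terminal base; ``None`` when the source
    dialect carries no sequence.
    """

    host_name: str
    anticodon: str
    family: str = ""
    sequence: str = ""
    discriminator: Optional[str] = None
    score: float = 0.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.anticodon = normalize_rna(self.anticodon)
        if len(self.anticodon) != 3:
            raise ParseError(
                f"tRNA {self.record_id or self.host_name!r}: anticodon "
                f"{self.anticodon!r} is not length 3"
            )
        self.sequence = normalize_rna(self.sequence)
        if not self.family:
            self.family = aa_from_codon(revcomp(self.anticodon))
        if self.discriminator is None and self.sequence:
            self.discriminator = discriminator_of(self.sequence)


def discriminator_of(sequence: str) -> Optional[str]:
    """Discriminator base of a tRNA sequence (position 73).

    Scanner outputs vary in whether the 3'-terminal CCA is included, so: the
    base 5' of a terminal CCA when present, else the last base.
    """
    seq = normalize_rna(sequence)
    if not seq:
        return None
    if seq.endswith("CCA") and len(seq) >= 4:
        return seq[-4]
    return seq[-1]


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def from_source_coords(start1: int, end1: int) -> tuple[int, int, str]:
    """1-based inclusive (possibly reversed for minus strand) -> 0-based
    half-open plus strand order.  Returns (start, end, strand)."""
    if start1 <= end1:
        return start1 - 1, end1, "+"
    return end1 - 1, start1, "-"


def to_source_coords(start: int, end: int, strand: str) -> tuple[int, int]:
    """Inverse of :func:`from_source_coords`."""
    if strand == "+":
        return start + 1, end
    return end, start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TboxRecord]:
    """Read leader sequences from FASTA.

    The header token before the first whitespace becomes the record id; a
    ``host=...`` token in the description sets the host organism, and the
    remainder, when present, is kept as the downstream annotation.  T is
    silently normalized to U.  An empty file yields an empty list.
    """
    records: list[TboxRecord] = []
    with open(path) as handle:
        for i, (title, seq) in enumerate(SimpleFastaParser(handle), start=1):
            parts = title.split()
            rec_id = parts[0] if parts else f"record{i}"
            host = ""
            rest: list[str] = []
            for token in parts[1:]:
                if token.startswith("host="):
                    host = token[len("host="):]
                else:
                    rest.append(token)
            annotation = " ".join(rest) or None
            try:
                records.append(
                    TboxRecord(
                        record_id=rec_id,
                        sequence=seq,
                        host_name=host,
                        downstream_annotation=annotation,
                        source=str(path),
                    )
                )
            except ParseError as exc:
                raise ParseError(f"{path}, entry {i}: {exc}") from exc
    return records


def write_fasta(records: Iterable[TboxRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            desc = f" host={rec.host_name}" if rec.host_name else ""
            if rec.downstream_annotation:
                desc += f" {rec.downstream_annotation}"
            handle.write(f">{rec.record_id}{desc}\n{rec.sequence}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# structure-search hits
# ---------------------------------------------------------------------------

def _check_balanced(consensus: str, name: str) -> None:
    depth = 0
    for ch in consensus:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise StructureFormatError(
                    f"hit {name!r}: unbalanced ')' in consensus structure"
                )
    if depth != 0:
        raise StructureFormatError(
            f"hit {name!r}: {depth} unclosed '(' in consensus structure"
        )


def read_structure_hits(path: str | Path, dialect: str = "aligned") -> list[StructureSearchHit]:
    """Read covariance-search hits; see the module docstring for dialects."""
    if dialect == "tabular":
        return _read_tabular_hits(path)
    if dialect == "aligned":
        return _read_aligned_hits(path)
    raise ValueError(f"unknown structure-hit dialect {dialect!r}")


def _read_tabular_hits(path: str | Path) -> list[StructureSearchHit]:
    hits = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            target, query, s, e, strand, score = fields[:6]
            try:
                start, end, derived = from_source_coords(int(s), int(e))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates {s!r}/{e!r}") from exc
            hits.append(
                StructureSearchHit(
                    query_model=query,
                    target_id=target,
                    target_start=start,
                    target_end=end,
                    strand=strand if strand in "+-" else derived,
                    score=float(score),
                )
            )
    return hits


_SEQCOORD = re.compile(r"^(?P<name>.+)/(?P<start>\d+)-(?P<end>\d+)$")


def _read_aligned_hits(path: str | Path) -> list[StructureSearchHit]:
    text = Path(path).read_text()
    hits: list[StructureSearchHit] = []
    for block in text.split("//"):
        block = block.strip("\n")
        if "STOCKHOLM" not in block:
            continue
        model = "unknown"
        score = 0.0
        for line in block.splitlines():
            if line.startswith("#=GF CM"):
                model = line.split(None, 2)[2].strip()
            elif line.startswith("#=GF SC"):
                score = float(line.split(None, 2)[2])
        aln = AlignIO.read(io.StringIO(block + "\n//\n"), "stockholm")
        ss_cons = aln.column_annotations.get("secondary_structure")
        if ss_cons is None:
            raise StructureFormatError(f"{path}: block lacks an SS_cons line")
        for row in aln:
            m = _SEQCOORD.match(row.id)
            if m:
                target_id = m.group("name")
                start, end, strand = from_source_coords(
                    int(m.group("start")), int(m.group("end"))
                )
            else:
                target_id, strand = row.id, "+"
                start, end = 0, sum(1 for c in str(row.seq) if c not in "-.")
            hits.append(
                StructureSearchHit(
                    query_model=model,
                    target_id=target_id,
                    target_start=start,
                    target_end=end,
                    strand=strand,
                    score=score,
                    consensus_structure=ss_cons,
                    aligned_sequence=normalize_rna(str(row.seq)).replace(".", "-"),
                )
            )
    return hits


def write_aligned_hits(hits: Iterable[StructureSearchHit], path: str | Path) -> int:
    """Write hits as Stockholm-style blocks (the ``aligned`` dialect)."""
    n = 0
    with open(path, "w") as handle:
        for hit in hits:
            s1, e1 = to_source_coords(hit.target_start, hit.target_end, hit.strand)
            name = f"{hit.target_id}/{s1}-{e1}"
            width = max(len(name), len("#=GC SS_cons")) + 2
            handle.write("# STOCKHOLM 1.0\n")
            handle.write(f"#=GF CM {hit.query_model}\n")
            handle.write(f"#=GF SC {hit.score:.1f}\n")
            handle.write(f"{name:<{width}}{hit.aligned_sequence}\n")
            handle.write(f"{'#=GC SS_cons':<{width}}{hit.consensus_structure}\n")
            handle.write("//\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# tRNA sets
# ---------------------------------------------------------------------------

def read_trnas(path: str | Path, dialect: str = "fasta_meta") -> list[TrnaRecord]:
    """Read a host tRNA set.

    Records with malformed anticodons (wrong length, ambiguity codes) are
    skipped with a logged warning rather than aborting the batch.
    """
    if dialect == "scanner_tabular":
        raw = _read_scanner_tabular(path)
    elif dialect == "fasta_meta":
        raw = _read_trna_fasta_meta(path)
    else:
        raise ValueError(f"unknown tRNA dialect {dialect!r}")

    records: list[TrnaRecord] = []
    skipped = 0
    for kwargs in raw:
        anticodon = normalize_rna(kwargs.get("anticodon", ""))
        if len(anticodon) != 3 or not set(anticodon) <= set("ACGU"):
            skipped += 1
            logger.warning(
                "skipping tRNA %s: unusable anticodon %r",
                kwargs.get("record_id", "?"), anticodon,
            )
            continue
        records.append(TrnaRecord(**kwargs))
    if skipped:
        logger.warning("skipped %d tRNA record(s) with unusable anticodons", skipped)
    return records


def _read_scanner_tabular(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("Sequence", "Name", "----", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 9:
                raise ParseError(f"{path}: expected >=9 columns, got {len(fields)}")
            host, num, _begin, _end, family3, anticodon = fields[:6]
            score = float(fields[8])
            fam = family_from_3letter(family3.strip())
            rows.append(
                dict(
                    host_name=host.strip(),
                    anticodon=anticodon.strip(),
                    family=fam if fam != UNDETERMINED else "",
                    score=score,
                    record_id=f"{host.strip()}.trna{num.strip()}",
                )
            )
    return rows


def _read_trna_fasta_meta(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split()
            meta = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
            rows.append(
                dict(
                    host_name=meta.get("host", ""),
                    anticodon=meta.get("anticodon", ""),
                    family=meta.get("family", ""),
                    sequence=seq,
                    score=float(meta.get("score", 0.0)),
                    record_id=parts[0],
                )
            )
    return rows


def write_trna_fasta(trnas: Iterable[TrnaRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for t in trnas:
            handle.write(
                f">{t.record_id or f'trna{n}'} host={t.host_name} family={t.family} "
                f"anticodon={t.anticodon} score={t.score:.1f}\n{t.sequence}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# flat-file annotation CSV
# ---------------------------------------------------------------------------

TBDB_COLUMNS = (
    "id", "host", "class", "sequence",
    "specifier", "specifier_frame", "alt_specifiers", "aa_family",
    "tbox_uggn", "trna_anticodon", "trna_matched",
    "stem1_interval", "antiterminator_interval", "terminator_interval",
    "mfe_antiterminator", "mfe_terminator",
    "downstream_annotation",
)


def write_tbdb_csv(
    rows: Iterable[dict],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> int:
    """Write annotated records to the flat-file CSV; returns the row count.

    Every row must provide values for :data:`TBDB_COLUMNS` (missing keys become
    empty strings — failed predictions are empty fields, not missing rows).
    ``header_comments`` are echoed as ``#``-prefixed lines above the header.
    """
    n = 0
    with open(path, "w", newline="") as handle:
        for comment in header_comments:
            handle.write(f"# {comment}\n")
        writer = csv.DictWriter(handle, fieldnames=TBDB_COLUMNS, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow({col: row.get(col, "") for col in TBDB_COLUMNS})
            n += 1
    return n


def read_tbdb_csv(path: str | Path) -> list[dict]:
    """Read the flat-file CSV back into a list of string-valued row dicts.

    Inverse of :func:`write_tbdb_csv` field-for-field (comments skipped).
    """
    with open(path, newline="") as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is not None and tuple(reader.fieldnames) != TBDB_COLUMNS:
        raise ParseError(f"{path}: unexpected column set {reader.fieldnames}")
    return [dict(row) for row in reader]


def format_interval(interval: Optional[Interval]) -> str:
    """0-based half-open interval -> 'start..end' (empty string for absent)."""
    if interval is None:
        return ""
    return f"{interval[0]}..{interval[1]}"


def parse_interval(text: str) -> Optional[Interval]:
    if not text:
        return None
    start, end = text.split("..")
    return int(start), int(end)
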