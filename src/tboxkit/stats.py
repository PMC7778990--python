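"""Dataset-level summaries: specifier usage, frame ambiguity, tRNA-match rates.

The specifier usage table is the codon-usage-table analogue for riboswitch
specifiers: counts of top-frame specifier triplets, normalized within each
amino-acid family so a family's frequencies sum to 1.  Rounding to two
decimals is presentation-only; raw frequencies are retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .genetics import CODONS_BY_FAMILY
from .seqio import TrnaRecord
from .specifier import SpecifierCall, aa_from_specifier


@dataclass
class UsageTable:
    """Specifier counts and per-family frequencies.

    Frequencies cover every codon of each observed family (unseen codons of an
    observed family have frequency 0.0); families with zero records are
    omitted entirely.  Stop-codon 'families' ('*') are tabulated but flagged.
    """

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({aa_from_specifier(t) for t in self.counts}))

    @property
    def freqs(self) -> dict[str, float]:
        totals = Counter()
        for triplet, n in self.counts.items():
            totals[aa_from_specifier(triplet)] += n
        out: dict[str, float] = {}
        for fam in self.families:
            for codon in CODONS_BY_FAMILY.get(fam, ()):
                out[codon] = self.counts.get(codon, 0) / totals[fam]
        return out

    def freq(self, triplet: str) -> float:
        """Raw within-family frequency of a specifier triplet."""
        return self.freqs[triplet]

    def rounded(self, triplet: str) -> float:
        """Presentation frequency, rounded to two decimal places."""
        return round(self.freq(triplet), 2)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "specifier": t,
                "aa_family": aa_from_specifier(t),
                "count": self.counts.get(t, 0),
                "freq": f,
                "freq_rounded": round(f, 2),
                "stop_family": aa_from_specifier(t) == "*",
            }
            for t, f in sorted(self.freqs.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["specifier", "aa_family", "count", "freq", "freq_rounded",
                     "stop_family"],
        )

    def to_tsv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        """Export SPEC/AA/FREQ triplets (full precision plus rounded column)."""
        with open(path, "w") as handle:
            for comment in header_comments:
                handle.write(f"# {comment}\n")
            self.to_dataframe().to_csv(handle, sep="\t", index=False)


def usage_table(calls: Sequence[Optional[SpecifierCall]]) -> UsageTable:
    """Tabulate top-frame specifiers only (records without a call are skipped)."""
    counts = Counter(c.top.triplet for c in calls if c is not None)
    return UsageTable(counts=dict(counts))


class FrameCounts(NamedTuple):
    n_single: int
    n_two: int
    n_three: int
    n_no_uggn: int  # specifier predicted but canonical UGGN bulge absent


def frame_counts(calls: Sequence[Optional[SpecifierCall]]) -> FrameCounts:
    """Bucket records by how many frames tie for the top score; records whose
    T-box bulge was absent are counted separately."""
    buckets = Counter()
    no_uggn = 0
    for call in calls:
        if call is None:
            continue
        if call.tbox_uggn is None:
            no_uggn += 1
        else:
            buckets[call.n_frames_viable] += 1
    return FrameCounts(buckets[1], buckets[2], buckets[3], no_uggn)


def match_rate(
    calls_with_trna: Sequence[tuple[Optional[SpecifierCall], Optional[TrnaRecord]]],
    group_by: str = "overall",
):
    """Fraction of specifier-bearing records with a matched host tRNA.

    ``group_by='overall'`` returns a float; ``'specifier'`` and ``'family'``
    return dicts keyed by triplet / one-letter family.  Groups with zero
    members are omitted.
    """
    if group_by not in ("overall", "specifier", "family"):
        raise ValueError(f"unknown grouping {group_by!r}")
    totals: Counter = Counter()
    matched: Counter = Counter()
    for call, trna in calls_with_trna:
        if call is None:
            continue
        if group_by == "overall":
            key = "overall"
        elif group_by == "specifier":
            key = call.top.triplet
        else:
            key = call.top.aa_family
        totals[key] += 1
        if trna is not None:
            matched[key] += 1
    rates = {k: matched[k] / totals[k] for k in totals}
    return rates.get("overall", 0.0) if group_by == "overall" else rates
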