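# Methods

## Scope and data flow

`tboxkit` annotates T-box riboswitch leader sequences given three inputs: the
sequences (FASTA), covariance-model search hits against a class I or class II
consensus model (tabular or Stockholm-style aligned blocks), and the host
organism's tRNA set. It does not run the homology search, fold arbitrary
sequences *ab initio*, fetch anything from the network, or predict the
sequestrator fold of translational (class II) leaders.

All internal coordinates are 0-based half-open; 1-based inclusive coordinates
exist only inside external files and are converted at the boundary
(minus-strand source intervals are flipped on read). DNA input is accepted
and normalized to upper-case RNA.

## Feature extraction

Conserved elements are located on *model columns*, not on the raw sequence.
The upstream consensus models do not publish column numbers, so the package
ships its own column maps (`tboxkit.models`): class I spans 126 columns with
a 50-column Stem I carrying an 8-column specifier bulge, Stems II and III,
and a 28-column antiterminator whose 5' side holds the 4-column T-box bulge;
class II spans 74 columns with a truncated 20-column Stem I and no Stem III.
The aligned-hit dialect is deliberately simple: every alignment column is a
model column and `-` marks a deletion in the target (no insertion columns).
Features map through the alignment; a feature whose columns are all deleted
is absent — in particular, a hit with the T-box bulge deleted yields an
annotation without a UGGN, which is a reported outcome, not an error.
Non-canonical bulges (not starting UGG) are annotated and flagged, never
dropped.

Class assignment uses the Stem I span: below the truncation threshold
(default 35 nt, midway between the two template stems at 50 and 20 nt) the
leader is class II; a span exactly at the threshold classifies as class I.
The threshold is configurable (`--stem1-threshold`).

The specifier window is the 5 bases ending at the 3' end of the specifier
bulge, where "end" is interpreted as the 3'-most *unpaired* base of the
bulge loop (the closing pair is the other defensible reading; this choice is
a package convention, surfaced in the docs rather than asserted as ground
truth). The '+0' frame is the priority region — bases 2–4 from the bulge
end, i.e. `window[1:4]` — with '−1' shifted one base 5' and '+1' one base
3'; the direction naming is likewise a package convention.

## Curation and terminator thermodynamics

Curation drops sequences shorter than 100 nt or longer than 500 nt (strict
inequalities: 100 and 500 are kept) and exact duplicates (first occurrence
kept), recording a reason per drop. Sequences are trimmed to end at the last
base of the 3'-most run of ≥5 U; without such a run the sequence passes
through unchanged with a no-trim flag. Genomic 3' extension before trimming
is out of scope (it requires genome access); trimming operates on whatever
sequence is supplied.

The terminator search enumerates perfect single stem-loops (no multiloop)
from the antiterminator start to the sequence end: stem of 4–30 Watson–Crick
or G:U pairs, loop of 3–10 nt, hairpin 3' end at most 3 nt upstream of a
≥5-U run. All four gates are configuration values — "suitable hairpin" has
no canonical numeric definition — and are echoed into every output header.
The minimum-energy candidate wins; ties resolve to the 5'-most, then
longest-stem candidate, making the search order-independent.

Free energies use an additive nearest-neighbor decomposition: stack energies
over consecutive pairs, hairpin/bulge/internal loop initiation penalties
(logarithmic extrapolation beyond the tables), a 0.5 kcal/mol terminal AU/GU
penalty per helix end, a single-base bulge keeping its flanking stack, and
an affine multibranch term (3.4 + 0.4/branch). Parameters live in a
plain-text file (`tboxkit/data/nn_params.txt`); Watson–Crick stacks follow
the standard Turner-style values while G:U stacks and the loop curves are
simplified defaults. Absolute kcal/mol values are therefore *not* comparable
to a full folding engine — the contracts are orderings and the additive
decomposition itself, which the test suite pins to independent brute-force
oracles (exhaustively for all nested structures up to 12 nt, on seeded
random structures to 30 nt, and against exhaustive hairpin enumeration on
toy regions to 40 nt). For engine-grade numbers, `thermo backend = external`
delegates evaluation to the ViennaRNA bindings when installed.

The two reported energies are the antiterminator-state fold (as aligned by
the search) and, when a terminator is found, the terminator-state fold: the
antiterminator span unfolded, the terminator hairpin formed, everything else
unchanged. Pseudoknots are rejected as unsupported.

## Specifier assignment and tRNA pairing

Each frame is scored on two equally weighted binary criteria; evidence that
is unavailable renders a criterion not-applicable (contributing 0, distinct
from a failed check):

* **Discriminator pairing.** The variable base of the UGGN bulge must pair
  the discriminator the host uses for the frame's tRNA family —
  Watson–Crick or G:U wobble, the only wobble the biology documents at this
  contact. The host discriminator is the modal base over the host's tRNAs
  of the family (score-ranked on ties); when the host has none, the modal
  base from a bundled, editable frequency table stands in. The criterion is
  skipped for His frames (mature tRNA-His can carry an internally paired
  discriminator) and when the bulge is absent. A tRNA's discriminator is
  read as the base 5' of a 3'-terminal CCA when present, else the terminal
  base, since scanner outputs vary in CCA inclusion.
* **Downstream ontology.** A keyword table (synthetase names, gene symbols,
  amino-acid and pathway terms; longest match masks its span so 'isoleucyl'
  never also fires 'leucyl') maps the downstream gene annotation to
  families. A match scores 1; a mismatch scores 0 but does not veto; no
  annotation or no keyword hit is not-applicable. With only two criteria,
  1-vs-1 ties across frames are resolved purely by the preference order.

The top frame is the highest score with ties broken '+0' > '−1' > '+1';
`n_frames_viable` counts the frames attaining the top score and feeds the
ambiguity statistics. Cognate-tRNA matching is stricter than frame scoring:
the anticodon must equal the reverse complement of the specifier exactly (no
wobble), with the highest-scoring tRNA chosen and score ties broken by
record id, so results are invariant under input permutation.

Usage tables count top-frame specifiers only and normalize within each
amino-acid family; rounding to two decimals is presentation-only and the
exports carry both raw and rounded columns. Stop-codon triplets are
tabulated but flagged, since their biological status as "families" is
unclear.

## The synthetic corpus

The fixture generator composes leaders against the same column maps the
extractor uses, which is what makes end-to-end recovery exact: stems are
sampled complementary, the specifier is planted in the '+0' register, the
UGGN bulge and (for class I) a GC-rich 8-pair terminator hairpin with an
A/C loop and 5-U tail are planted at known offsets, and each record gets a
host tRNA set containing the cognate (with a discriminator that pairs the
planted N) plus decoys from other families. Filler is drawn to keep the
evidence unambiguous: no ≥5-U run outside the planted tail, no tail-anchored
hairpin that ties or beats the planted terminator under the bundled energy
model, and window edges chosen to keep shifted frames outside the planted
family where the genetic code allows. Class II fixtures carry neither
terminator nor poly-U, mirroring the decision not to predict sequestrators.
Corpora walk a fixed family cycle (Met and Trp first) before sampling sense
codons at random; every fifth record is class II and one in eleven has its
T-box bulge deleted, providing the inconsistent-evidence stratum. Everything
derives from the corpus seed.

What passing on fixtures does **not** show: the fixtures are grammar
composites, not biological sequences — filler has no phylogenetic structure,
stems are perfect, the alignment dialect has no insertions, and the planted
evidence is cleaner than real downstream annotations or tRNA scans. Recovery
on fixtures validates the bookkeeping (coordinates, alignment mapping, rule
implementations), not predictive accuracy on genomes.

## Reported numbers

`scripts/acceptance.py` generates a 20-record corpus from the given seed,
round-trips it through the on-disk formats, runs the pipeline and reports
the usage-table frequencies of AUG within Met and UGG within Trp. Both are
forced to 1.00 by the genetic code whenever any Met or Trp specifier is
assigned (single-codon families), making them seed-independent checks that
the whole chain — generation, parsing, extraction, scoring, tabulation —
composes correctly. Corpus sizes throughout (20 for the reference corpus,
50 for the recovery suite) keep the full test run in seconds while covering
both classes, all evidence strata, and a dozen families.

## Known limitations

* The flat-file CSV schema is this package's own; column sets of public
  riboswitch databases differ.
* Stem IIA/B pseudoknots, K-turns, and sequestrator folds are not annotated.
* The builtin energy model is for ordering and contracts, not for
  publication-grade ΔG values.
* Multi-tRNA (multi-specificity) regulation and anticodon-side wobble are
  out of scope.
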