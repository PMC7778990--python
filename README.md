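# tboxkit

Annotation toolkit for **T-box riboswitches** — the tRNA-sensing 5'-UTR
leader sequences that regulate amino-acid metabolism genes across
gram-positive bacteria.

A T-box leader reads the charging state of one tRNA family. Two base-pairing
contacts define its specificity: the **specifier sequence**, a codon-like
triplet in the Stem I bulge that pairs the tRNA anticodon, and the four-base
**T-box bulge** (5'-UGGN-3') in the antiterminator, whose variable fourth
base pairs the tRNA discriminator (5'-NCCA-3' acceptor end). When uncharged
tRNA binds, the antiterminator (or antisequestrator) fold is stabilized and
the downstream gene is expressed; otherwise an intrinsic terminator hairpin
followed by a poly-U tract stops transcription.

`tboxkit` takes pre-computed covariance-model search hits (it does not run
the homology search itself) and performs, for each leader:

* **feature extraction** — Stem I, specifier bulge, Stems II/III,
  antiterminator and T-box bulge intervals, mapped from model columns
  through the alignment; class I (transcriptional, long Stem I) vs class II
  (translational, truncated Stem I) assignment;
* **terminator prediction** — minimum-energy single stem-loop upstream of a
  ≥5-U run, plus free energies of both regulatory folds under a bundled
  nearest-neighbor model (a ViennaRNA-backed evaluation is available via
  `thermo backend = external`);
* **specifier assignment** — the three triplet registers ('−1', '+0', '+1')
  of the 5-base window at the 3' end of the specifier bulge are scored on
  two equally weighted criteria (discriminator pairing, Watson–Crick or G:U
  wobble, skipped for His; downstream-gene ontology match), ties resolved
  '+0' > '−1' > '+1';
* **cognate-tRNA matching** — host tRNA whose anticodon is the exact reverse
  complement of the specifier (no wobble), highest score first;
* **collection statistics** — a specifier usage table (within-family
  frequencies), frame-ambiguity counts, and tRNA match rates.

A seeded synthetic-fixture generator (`tboxkit.fixtures`) composes leaders
with known ground truth — planted specifier, class, UGGN, terminator — and
writes every input dialect the readers consume, so the whole pipeline is
testable offline.

## Worked example

```sh
tboxkit fixtures -n 20 --seed 7 --outdir corpus
tboxkit scan --fasta corpus/leaders.fasta --hits corpus/hits.sto \
             --trnas corpus/trnas.fasta --out tbox_annotations.csv
# INFO tboxkit: annotated 20/20 record(s); frames single/two/three: 18/1/0;
#               no canonical UGGN: 1; tRNA match rate 1.000
```

One row of `tbox_annotations.csv` (a Trp leader):

```
id                         TBX001
class                      I
specifier                  UGG          # Stem I triplet, '+0' frame
alt_specifiers             -1:GUG;+1:GGG
aa_family                  W
tbox_uggn                  UGGU         # N=U pairs the tRNA discriminator
trna_anticodon             CCA          # exact reverse complement, no wobble
trna_matched               yes
stem1_interval             5..55        # 0-based half-open
terminator_interval        134..154
mfe_antiterminator         -48.46       # kcal/mol, bundled NN model
mfe_terminator             -58.99
downstream_annotation      tryptophanyl-tRNA synthetase
```

The leader reads tRNA-Trp: its specifier UGG pairs the CCA anticodon, and
the terminator fold (−58.99 kcal/mol) out-stabilizes the antiterminator
(−48.46) unless bound uncharged tRNA tips the balance. The companion
`tbox_annotations_usage.tsv` reports specifier usage per family — e.g. the
single-codon families Met and Trp are always at frequency 1.00, while a
four-codon family splits (here Thr: ACC/ACG/ACU at 0.33 each).

Each subcommand is a thin wrapper over the library (`tboxkit.scan`,
`tboxkit.make_corpus`, `tboxkit.usage_table`), which is the better entry
point for programmatic use.

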