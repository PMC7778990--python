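import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tboxkit.annotate import StructureAnnotation, extract_features
from tboxkit.errors import StructureFormatError, UnsupportedStructureError
from tboxkit.fixtures import FixtureSpec, make_tbox
from tboxkit.seqio import TboxRecord
from tboxkit.terminator_thermo import (
    curate,
    default_model,
    energy_of,
    eval_structure,
    find_terminator,
    load_energy_model,
    mfe_pair,
    trim_to_polyU,
)

from .oracles import (
    all_nested_structures,
    compatible_sequence,
    oracle_energy,
    oracle_find_terminator,
    random_nested_structure,
)


def _rec(i, seq):
    return TboxRecord(record_id=f"r{i}", sequence=seq)


class TestCurate:
    def test_length_boundaries_are_strict(self):
        recs = [
            _rec(0, "A" * 99), _rec(1, "C" * 100), _rec(2, "G" * 500),
            _rec(3, "U" * 501),
        ]
        kept, dropped = curate(recs)
        assert [len(r.sequence) for r in kept] == [100, 500]
        assert [reason.split(" (")[0] for _, reason in dropped] == [
            "too short", "too long"]

    def test_duplicates_dropped_keeping_first(self):
        recs = [_rec(0, "AC" * 60), _rec(1, "AC" * 60)]
        kept, dropped = curate(recs)
        assert [r.record_id for r in kept] == ["r0"]
        assert dropped[0][0].record_id == "r1"
        assert "redundant" in dropped[0][1]

    def test_empty_input(self):
        assert curate([]) == ([], [])


class TestTrimToPolyU:
    @pytest.mark.parametrize(
        "seq, expected, flag",
        [
            ("ACGUUUUUAAG", "ACGUUUUU", True),
            ("ACGUUUU", "ACGUUUU", False),          # only 4 U: unchanged
            ("UUUUUACGUUUUUG", "UUUUUACGUUUUU", True),  # 3'-most run wins
            ("ACGUUUUUUUA", "ACGUUUUUUU", True),    # run longer than 5
        ],
    )
    def test_rule(self, seq, expected, flag):
        assert trim_to_polyU(seq) == (expected, flag)

    @given(st.text(alphabet="ACGU", max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_output_ends_in_pentau_or_flags(self, seq):
        trimmed, had = trim_to_polyU(seq)
        if had:
            assert trimmed.endswith("UUUUU")
            assert seq.startswith(trimmed)
        else:
            assert trimmed == seq and "UUUUU" not in seq


class TestEnergyOf:
    def test_all_unpaired_scores_zero(self):
        assert energy_of("ACGUACGUACGU", "." * 12) == 0.0

    def test_pseudoknot_notation_unsupported(self):
        with pytest.raises(UnsupportedStructureError):
            energy_of("GGGAAACCCAAA", "(((.[[)))..]")

    def test_forced_non_pair_names_position(self):
        with pytest.raises(StructureFormatError, match="0 and 8"):
            energy_of("ACGAAAACC", "((.....))")

    def test_removing_a_wc_stack_destabilizes(self):
        seq = "GGGGCAAAAGCCCC"
        full = "(((((....)))))"
        outer_removed = ".((((....))))."
        assert energy_of(seq, full) < energy_of(seq, outer_removed)

    def test_adding_outer_gc_stack_never_raises_energy(self):
        rng = random.Random(2)
        for _ in range(25):
            stem = "".join(rng.choice("GC") for _ in range(4))
            loop = "".join(rng.choice("ACGU") for _ in range(4))
            from tboxkit.genetics import revcomp
            core = stem + loop + revcomp(stem)
            grown = "G" + core + "C"
            assert (
                energy_of(grown, "(((((....)))))")
                <= energy_of(grown, ".((((....))))." )
            )

    def test_matches_oracle_exhaustively_up_to_len_12(self):
        model = default_model()
        rng = random.Random(12)
        n_checked = 0
        for n in range(1, 13):
            for db in all_nested_structures(n):
                seq = compatible_sequence(db, rng)
                assert energy_of(seq, db, model) == oracle_energy(seq, db, model), (
                    seq, db)
                n_checked += 1
        assert n_checked > 500

    def test_matches_oracle_on_random_cases_up_to_len_30(self):
        model = default_model()
        rng = random.Random(30)
        for _ in range(200):
            n = rng.randint(5, 30)
            db = random_nested_structure(n, rng)
            seq = compatible_sequence(db, rng)
            assert energy_of(seq, db, model) == oracle_energy(seq, db, model), (
                seq, db)

    def test_custom_parameter_file(self, tmp_path):
        p = tmp_path / "params.txt"
        p.write_text("stack GC CG -9.0\nhairpin 3 1.0\nau_end 0.0\n")
        model = load_energy_model(p)
        assert energy_of("GCAAAGC", "((...))", model) == pytest.approx(-8.0)

    def test_external_backend_delegates_to_folding_engine(self):
        e = eval_structure("GGGAAACCC", "(((...)))", backend="external")
        assert e == pytest.approx(-1.2, abs=0.3)


class TestFindTerminator:
    def test_recovers_planted_hairpin(self, trp_fixture):
        _, rec, hit, truth = trp_fixture
        ann = extract_features(rec, hit)
        call = find_terminator(rec.sequence, ann)
        assert call is not None
        assert call.hairpin_interval == truth.features["terminator"]
        assert call.polyU_interval == truth.features["polyU"]
        assert call.energy < 0

    def test_absent_without_polyu(self):
        rec, hit, _ = make_tbox(FixtureSpec(
            seed=8, with_terminator=False, with_polyU=False))
        ann = extract_features(rec, hit)
        assert find_terminator(rec.sequence, ann) is None

    def test_deeper_stem_register_wins_on_energy(self):
        seq = "GGCGCAAAGCGCC" + "UUUUU"
        ann = StructureAnnotation("." * len(seq), {"antiterminator": (0, 1)})
        call = find_terminator(seq, ann)
        assert call is not None
        assert call.hairpin_dotbracket == "(((((...)))))"
        assert call.hairpin_interval == (0, 13)

    def test_matches_exhaustive_enumeration_on_toys(self):
        model = default_model()
        rng = random.Random(40)
        n_with_call = 0
        for _ in range(60):
            n = rng.randint(15, 40)
            seq = list("".join(rng.choice("ACGU") for _ in range(n)))
            k = rng.randint(10, n - 5)
            seq[k:k + 5] = "UUUUU"
            seq = "".join(seq)
            ann = StructureAnnotation("." * n, {"antiterminator": (0, 1)})
            got = find_terminator(seq, ann, model)
            expected = oracle_find_terminator(seq, 0, model)
            if expected is None:
                assert got is None, seq
            else:
                n_with_call += 1
                interval, db, polyu, e = expected
                assert got is not None, seq
                assert (got.hairpin_interval, got.hairpin_dotbracket,
                        got.polyU_interval, got.energy) == (
                    interval, db, polyu, e), seq
        assert n_with_call >= 5  # the toys must actually exercise the search


class TestMfePair:
    def test_both_folds_on_full_fixture(self, trp_fixture):
        _, rec, hit, _ = trp_fixture
        ann = extract_features(rec, hit)
        mfe_anti, mfe_term = mfe_pair(rec, ann)
        assert mfe_anti < 0 and mfe_term is not None and mfe_term < 0

    def test_terminator_absent_yields_none(self, class2_fixture):
        _, rec, hit, _ = class2_fixture
        ann = extract_features(rec, hit)
        mfe_anti, mfe_term = mfe_pair(rec, ann)
        assert isinstance(mfe_anti, float) and mfe_term is None

    def test_deterministic(self, trp_fixture):
        _, rec, hit, _ = trp_fixture
        ann = extract_features(rec, hit)
        assert mfe_pair(rec, ann) == mfe_pair(rec, ann)
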