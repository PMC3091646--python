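import numpy as np
import pytest

from conftest import random_dna
from pseudis.io_formats import GenomeRecord, revcomp
from pseudis.is_elements import (
    ISParams,
    build_consensus,
    classify_transposase,
    detect_tir,
    detect_tsd,
    family_summary,
    find_repeat_families,
    find_transposase_orf,
    p_distance_matrix,
    scan_copies,
)
from pseudis.is_elements import _pairwise_rows
from pseudis.synthetic_genome import ISFamilySpec, _build_element


def make_element(rng, spec=None):
    spec = spec or ISFamilySpec()
    return _build_element(spec, rng), spec


class TestRepeatFamilies:
    def test_three_identical_copies_one_family(self, rng):
        el = random_dna(rng, 600)
        seq = random_dna(rng, 900) + el + random_dna(rng, 900) + el + random_dna(rng, 900) + el + random_dna(rng, 500)
        fams = find_repeat_families(GenomeRecord("chr", seq))
        assert len(fams) == 1
        assert len(fams[0].copies) == 3

    def test_two_unrelated_elements_two_families(self, rng):
        a, b = random_dna(rng, 600), random_dna(rng, 700)
        seq = random_dna(rng, 600) + a + random_dna(rng, 600) + b + random_dna(rng, 600) \
            + a + random_dna(rng, 600) + b + random_dna(rng, 400)
        fams = find_repeat_families(GenomeRecord("chr", seq))
        assert len(fams) == 2
        assert sorted(len(f.copies) for f in fams) == [2, 2]

    def test_95pct_identity_still_clusters(self, rng):
        el = random_dna(rng, 600)
        mut = list(el)
        for i in rng.choice(np.arange(600), size=30, replace=False):
            mut[i] = str(rng.choice([b for b in "ACGT" if b != el[i]]))
        seq = random_dna(rng, 700) + el + random_dna(rng, 700) + "".join(mut) + random_dna(rng, 700)
        fams = find_repeat_families(GenomeRecord("chr", seq))
        assert len(fams) == 1
        assert len(fams[0].copies) == 2

    def test_minus_strand_copy_normalized(self, rng):
        el = random_dna(rng, 600)
        seq = random_dna(rng, 700) + el + random_dna(rng, 700) + revcomp(el) + random_dna(rng, 700)
        fams = find_repeat_families(GenomeRecord("chr", seq))
        assert len(fams) == 1
        assert sorted(c.strand for c in fams[0].copies) == ["+", "-"]


class TestConsensus:
    def test_identical_copies_give_the_copy(self, rng):
        s = random_dna(rng, 200)
        for k in (1, 2, 3, 5):
            cons, rows = build_consensus([s] * k)
            assert cons == s
            assert len(rows) == k

    def test_majority_wins_single_substitution(self, rng):
        s = random_dna(rng, 200)
        mutated = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        cons, _ = build_consensus([s, s, mutated])
        assert cons == s

    def test_two_way_tie_gives_n(self, rng):
        s = random_dna(rng, 100)
        other = "A" if s[40] != "A" else "C"
        mutated = s[:40] + other + s[41:]
        cons, _ = build_consensus([s, mutated])
        assert cons[40] == "N"
        assert cons[:40] == s[:40] and cons[41:] == s[41:]


class TestTIR:
    def test_planted_17bp_terminal_tir_detected_exactly(self, rng):
        for _ in range(5):
            el, spec = make_element(rng)
            res = detect_tir(el)
            assert res is not None and not res["internal"]
            assert res["length"] == 17
            assert res["left_seq"] == el[:17]
            assert res["right_seq"] == el[-17:]

    def test_random_termini_not_detected_in_99pct(self, rng):
        hits = 0
        for _ in range(100):
            s = random_dna(rng, 400)
            res = detect_tir(s)
            if res is not None and not res["internal"]:
                hits += 1
        assert hits <= 1

    def test_palindromic_8bp_boundary_accepted(self):
        arm = "GGGATCAT"
        mid = "CCTTAAGGCCTTAAGGAATT"
        el = arm + mid + revcomp(arm)
        res = detect_tir(el, ISParams(tir_min_len=8))
        assert res is not None and res["length"] == 8

    def test_internal_ir_reported_with_offsets(self, rng):
        arm = "GATCCGGTACGT"
        core = random_dna(rng, 300)
        el = random_dna(rng, 20) + arm + core + revcomp(arm) + random_dna(rng, 30)
        res = detect_tir(el)
        if res is not None:
            assert res["internal"]
            assert res["length"] >= len(arm)


class TestTSD:
    def test_planted_9mers_detected(self):
        flanks = [("AAAAAGATCGATCG", "GATCGATCGTTTTT")] * 4
        assert detect_tsd(flanks) == 9

    def test_no_duplication_not_detected(self, rng):
        flanks = []
        for _ in range(6):
            up, down = random_dna(rng, 15), random_dna(rng, 15)
            if up[-1] == down[0]:
                up = up[:-1] + ("A" if down[0] != "A" else "C")
            flanks.append((up, down))
        assert detect_tsd(flanks) is None

    def test_modal_rule_with_spurious_minority(self):
        good = ("AAAAAGATCGATCG", "GATCGATCGTTTTT")  # 9
        spur = ("CCCCCCCCCCCTAG", "TAGCCAAAAAAAAA")  # 3
        assert detect_tsd([good, good, good, spur]) == 9


class TestScanCopies:
    def test_complete_partial_and_minus_strand_copies(self, rng):
        el = random_dna(rng, 800)
        seq = (
            random_dna(rng, 400) + el + random_dna(rng, 400)
            + el[:450] + random_dna(rng, 400)
            + revcomp(el) + random_dna(rng, 400)
        )
        copies = scan_copies(GenomeRecord("chr", seq), el)
        assert len(copies) == 3
        kinds = sorted((c.completeness, c.strand) for c in copies)
        assert kinds == [("complete", "+"), ("complete", "-"), ("partial", "+")]
        for c in copies:
            if c.completeness == "complete":
                assert c.p_to_consensus == 0.0


class TestPDistance:
    def test_quarter_distance(self):
        mat, summary = p_distance_matrix(["AAAA", "AAAT"])
        assert mat[0, 1] == 0.25
        assert summary == {"min": 0.25, "max": 0.25, "mean": 0.25}

    def test_pairwise_deletion_excludes_gap_sites(self):
        mat, _ = p_distance_matrix(["AA-A", "AAAA"])
        assert mat[0, 1] == 0.0

    def test_matrix_matches_per_pair_recount(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            width = int(rng.integers(10, 40))
            rows = []
            for _ in range(n):
                rows.append("".join(rng.choice(list("ACGT-"), size=width,
                                               p=[0.22, 0.22, 0.22, 0.22, 0.12])))
            mat, _ = p_distance_matrix(rows)
            assert np.allclose(mat, mat.T, equal_nan=True)
            for i in range(n):
                assert mat[i, i] == 0.0
                for j in range(i + 1, n):
                    comp = [(a, b) for a, b in zip(rows[i], rows[j]) if a != "-" and b != "-"]
                    if not comp:
                        assert np.isnan(mat[i, j])
                    else:
                        expected = sum(a != b for a, b in comp) / len(comp)
                        assert mat[i, j] == pytest.approx(expected)


class TestClassifyTransposase:
    @pytest.fixture
    def element(self, rng):
        el, spec = make_element(rng)
        return el, spec

    def rows(self, copy, consensus):
        return _pairwise_rows(copy, consensus)

    def test_identical_copy_functional(self, element):
        el, spec = element
        q, c = self.rows(el, el)
        assert classify_transposase(el, [q], cons_row=c) == ["functional"]

    def test_internal_stop_defective(self, element):
        el, spec = element
        s, t = spec.transposase_span
        mid = s + 3 * (((t - s) // 3) // 2)
        damaged = el[:mid] + "TAG" + el[mid + 3 :]
        q, c = self.rows(damaged, el)
        assert classify_transposase(el, [q], cons_row=c) == ["defective"]

    def test_inframe_3bp_deletion_functional(self, element):
        el, spec = element
        s, t = spec.transposase_span
        mid = s + 3 * (((t - s) // 3) // 2)
        damaged = el[:mid] + el[mid + 3 :]
        q, c = self.rows(damaged, el)
        assert classify_transposase(el, [q], cons_row=c) == ["functional"]

    def test_1bp_deletion_defective(self, element):
        el, spec = element
        s, t = spec.transposase_span
        mid = s + (t - s) // 2
        damaged = el[:mid] + el[mid + 1 :]
        q, c = self.rows(damaged, el)
        assert classify_transposase(el, [q], cons_row=c) == ["defective"]

    def test_truncated_copy_absent(self, element):
        el, spec = element
        trunc = el[: spec.transposase_span[0] + 100]
        q, c = self.rows(trunc, el)
        assert classify_transposase(el, [q], cons_row=c) == ["absent"]

    def test_orf_finder_locates_planted_transposase(self, element):
        el, spec = element
        orf = find_transposase_orf(el)
        assert orf is not None
        (s, t), strand = orf
        assert strand == "+"
        assert (s, t) == spec.transposase_span


class TestFamilySummary:
    def test_empty_family_list(self):
        s = family_summary([], genome_len=1_000_000)
        assert s["genome_fraction_pct"] == 0.00
        assert s["load_per_kb"] == 0.000

    def test_fraction_recomputed_from_copies_matches(self, small_bench):
        from pseudis.is_elements import find_is_families

        _, sim, _ = small_bench
        fams = find_is_families(sim.genome)
        s = family_summary(fams, len(sim.genome))
        total = sum(c.length for f in fams for c in f.copies)
        assert total <= len(sim.genome)
        assert s["genome_fraction_pct"] == pytest.approx(100 * total / len(sim.genome), abs=0.005)
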