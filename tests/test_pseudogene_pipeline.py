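import numpy as np
import pytest

from conftest import random_dna, random_protein, small_config
from pseudis.benchmark import run_benchmark
from pseudis.io_formats import AnnotationSet, Feature, GenomeRecord
from pseudis.pseudogene_pipeline import (
    PipelineParams,
    PseudogeneCall,
    detect_pass,
    extract_intergenic,
    merge_and_reconcile,
    reconstruct_model,
    run_two_pass,
    transfer_annotation,
)
from pseudis.synthetic_genome import reverse_translate
from pseudis.translated_search import HSP


def ann(features, gid="chr"):
    return AnnotationSet(gid, features)


class TestExtractIntergenic:
    def g(self, n=300):
        return GenomeRecord("chr", "A" * n)

    def test_gaps_and_chromosome_end(self):
        a = ann([Feature("g1", "gene", "+", [(0, 100)]), Feature("g2", "gene", "+", [(150, 250)])])
        regions = extract_intergenic(a, self.g())
        assert [r.interval for r in regions] == [(100, 150), (250, 300)]
        assert regions[0].left_flank_id == "g1" and regions[0].right_flank_id == "g2"
        assert regions[1].right_flank_id == "chromosome_end"

    def test_gap_below_threshold_dropped(self):
        a = ann([Feature("g1", "gene", "+", [(0, 100)]), Feature("g2", "gene", "+", [(149, 250)])])
        regions = extract_intergenic(a, self.g())
        assert [r.interval for r in regions] == [(250, 300)]

    def test_overlapping_genes_leave_no_region(self):
        a = ann([Feature("g1", "gene", "+", [(0, 100)]), Feature("g2", "gene", "+", [(90, 250)])])
        regions = extract_intergenic(a, self.g())
        assert [r.interval for r in regions] == [(250, 300)]

    def test_feature_beyond_genome_rejected(self):
        a = ann([Feature("g1", "gene", "+", [(0, 400)])])
        with pytest.raises(Exception, match="g1"):
            extract_intergenic(a, self.g())


class TestDetectPass:
    def test_coverage_threshold(self, rng):
        """A region carrying 60% of a subject is called; 20% is not."""
        prot = random_protein(rng, 200)
        proteome = {"P": prot}
        for frac, expect in ((0.6, 1), (0.2, 0)):
            n = int(frac * 200)
            cds = reverse_translate(prot[:n])[:-3]
            region_seq = random_dna(rng, 80) + cds + random_dna(rng, 80)
            genome = GenomeRecord("chr", region_seq)
            regions = extract_intergenic(ann([]), genome)
            calls = detect_pass(regions, genome, proteome)
            assert len(calls) == expect, frac
            if expect:
                assert calls[0].subject_coverage == pytest.approx(frac, abs=0.02)

    def test_monotone_in_coverage_threshold(self, small_bench):
        """Lowering min_subject_coverage never decreases the call count."""
        _, sim, _ = small_bench
        regions = extract_intergenic(sim.annotation, sim.genome)[:10]
        n_calls = []
        for cov in (0.6, 0.25, 0.05):
            p = PipelineParams(min_subject_coverage=cov)
            n_calls.append(len(detect_pass(regions, sim.genome, sim.proteome, p)))
        assert n_calls[0] <= n_calls[1] <= n_calls[2]


class TestReconstructModel:
    def test_planted_frameshift_yields_two_segments_one_shift(self, rng):
        prot = random_protein(rng, 200)
        cds = reverse_translate(prot)[:-3]
        mutated = cds[:300] + cds[301:]  # 1-bp deletion at codon 100
        region_seq = random_dna(rng, 60) + mutated + random_dna(rng, 60)
        genome = GenomeRecord("chr", region_seq)
        regions = extract_intergenic(ann([]), genome)
        calls = detect_pass(regions, genome, {"P": prot})
        assert len(calls) == 1
        call = reconstruct_model(calls[0], genome, {"P": prot})
        assert call.disruptions["frameshifts"] == 1
        assert call.disruptions["premature_stops"] == 0
        assert call.subject_coverage > 0.95

    def test_frame_change_count_over_three_frames(self, rng):
        prot = random_protein(rng, 300)
        cds = reverse_translate(prot)[:-3]
        # two deletions -> frames visit three phases
        mutated = cds[:250] + cds[251:550] + cds[552:]
        genome = GenomeRecord("chr", random_dna(rng, 60) + mutated + random_dna(rng, 60))
        calls = detect_pass(extract_intergenic(ann([]), genome), genome, {"P": prot})
        call = reconstruct_model(calls[0], genome, {"P": prot})
        assert call.disruptions["frameshifts"] == 2
        assert len(call.segments) == 3

    def test_premature_stop_counted_inside_segment(self, rng):
        prot = random_protein(rng, 150)
        cds = reverse_translate(prot)[:-3]
        mutated = cds[:210] + "TAA" + cds[213:]  # codon 70 -> stop
        genome = GenomeRecord("chr", random_dna(rng, 60) + mutated + random_dna(rng, 60))
        calls = detect_pass(extract_intergenic(ann([]), genome), genome, {"P": prot})
        call = reconstruct_model(calls[0], genome, {"P": prot})
        assert call.disruptions["premature_stops"] == 1
        assert call.disruptions["frameshifts"] == 0


class TestMergeAndReconcile:
    def _call(self, subject, strand, hsps, region):
        evidence = [
            HSP(query_interval=q, frame=f, subject_id=subject, subject_interval=s,
                score=sc, identity=1.0, evalue=1e-20)
            for q, f, s, sc in hsps
        ]
        return PseudogeneCall(
            subject_id=subject,
            strand=strand,
            segments=[h.query_interval for h in evidence],
            frames=[h.frame for h in evidence],
            subject_coverage=sum(s[1] - s[0] for _, _, s, _ in hsps) / 200,
            evidence=evidence,
            region=region,
            score=sum(sc for *_, sc in hsps),
            evalue=1e-20,
        )

    def test_adjacent_same_subject_calls_merge_with_union_coverage(self):
        genome = GenomeRecord("chr", "A" * 2000)
        proteome = {"P": "M" + "K" * 199}
        c1 = self._call("P", "+", [((100, 400), 1, (0, 100), 500)], (0, 500))
        c2 = self._call("P", "+", [((600, 870), 1, (110, 200), 450)], (500, 1000))
        rec = merge_and_reconcile([c1, c2], ann([]), genome, proteome)
        assert len(rec.calls) == 1
        assert rec.calls[0].subject_coverage == pytest.approx(0.95)
        assert len(rec.calls[0].segments) == 2

    def test_distant_calls_stay_separate(self):
        genome = GenomeRecord("chr", "A" * 10000)
        proteome = {"P": "M" + "K" * 199}
        c1 = self._call("P", "+", [((100, 400), 1, (0, 100), 500)], (0, 500))
        c2 = self._call("P", "+", [((8000, 8270), 1, (110, 200), 450)], (7000, 9000))
        rec = merge_and_reconcile([c1, c2], ann([]), genome, proteome)
        assert len(rec.calls) == 2

    def test_output_renumbered_in_genomic_order(self):
        genome = GenomeRecord("chr", "A" * 10000)
        proteome = {"P": "M" + "K" * 199, "Q": "M" + "R" * 199}
        c1 = self._call("Q", "+", [((5000, 5600), 1, (0, 200), 900)], (4500, 6000))
        c2 = self._call("P", "+", [((100, 700), 1, (0, 200), 900)], (0, 1000))
        rec = merge_and_reconcile([c1, c2], ann([]), genome, proteome)
        tags = [c.locus_tag for c in rec.calls]
        assert tags == ["ps_0001", "ps_0002"]
        assert rec.calls[0].subject_id == "P"


class TestTwoPass:
    def test_pass2_finds_homolog_only_in_extended_proteome(self, rng):
        protA, protB = random_protein(rng, 150), random_protein(rng, 150)
        cdsA = reverse_translate(protA)[:-3]
        cdsB = reverse_translate(protB)[:-3]
        seq = random_dna(rng, 200) + cdsA + random_dna(rng, 200) + cdsB + random_dna(rng, 200)
        genome = GenomeRecord("chr", seq)
        rec = run_two_pass(genome, ann([]), {"A": protA}, {"A": protA, "B": protB})
        found = {c.subject_id: c.pass_found for c in rec.calls}
        assert found == {"A": 1, "B": 2}

    def test_extended_equal_primary_is_idempotent(self, rng):
        prot = random_protein(rng, 150)
        cds = reverse_translate(prot)[:-3]
        genome = GenomeRecord("chr", random_dna(rng, 150) + cds + random_dna(rng, 150))
        rec1 = run_two_pass(genome, ann([]), {"A": prot})
        rec2 = run_two_pass(genome, ann([]), {"A": prot}, {"A": prot})
        assert [(c.subject_id, c.segments) for c in rec1.calls] == [
            (c.subject_id, c.segments) for c in rec2.calls
        ]
        assert all(c.pass_found == 1 for c in rec2.calls)


class TestSyntheticRecovery:
    def test_small_genome_full_recovery(self, small_bench):
        res, sim, rec = small_bench
        assert res.sensitivity >= 0.9
        assert res.precision >= 0.9
        assert res.splits_detected == res.splits_planted
        assert res.is_insertion_calls == res.is_split_planted

    def test_split_records_report_annotated_fraction(self, small_bench):
        res, sim, rec = small_bench
        truth = {t.feature_id: t for t in sim.truth if t.category == "missplit_pair"}
        assert len(rec.splits) == len(truth)
        by_gene = {sp.gene_id: sp for sp in rec.splits}
        for tid, t in truth.items():
            sp = by_gene[tid]
            assert sp.relative_position == t.extras["gene_relative_position"]
            assert sp.gene_fraction == pytest.approx(t.extras["annotated_fraction"], abs=0.06)
            assert 0 < sp.gene_fraction < 1 and 0 < sp.pseudogene_fraction < 1
            assert sp.gene_fraction + sp.pseudogene_fraction <= 1.05

    def test_disruption_counts_mostly_exact_across_seeds(self):
        exact = tot = 0
        for seed in (1, 2, 4):
            res, _, _ = run_benchmark(small_config(seed))
            exact += res.disruption_exact_fraction * res.n_calls * res.precision
            tot += res.n_calls * res.precision
        assert exact / tot >= 0.8

    def test_calls_do_not_overlap_original_genes(self, small_bench):
        res, sim, rec = small_bench
        genes = [f for f in sim.annotation.features if f.kind == "gene"]
        for c in rec.calls:
            for g in genes:
                ov = min(c.end, g.end) - max(c.start, g.start)
                assert ov <= 45, (c.locus_tag, g.locus_tag)
            assert c.subject_coverage >= 0.25


class TestTransferAnnotation:
    def test_identical_sequences_pair_with_qualifiers(self, rng):
        p = random_protein(rng, 120)
        quals = {"R1": {"product": "enzyme X", "gene": "abcX", "note": "ignored"}}
        orth, transferred = transfer_annotation({"Q1": p}, {"R1": p}, quals)
        assert orth == {"Q1": "R1"}
        assert transferred["Q1"] == {"product": "enzyme X", "gene": "abcX"}

    def test_low_identity_pair_rejected(self, rng):
        p = random_protein(rng, 150)
        # ~25% identity full-length analogue: keep every 4th residue
        aas = list("ACDEFGHIKLNPQRSTVWY")
        q = "M" + "".join(
            p[i] if i % 4 == 0 else str(rng.choice([a for a in aas if a != p[i]]))
            for i in range(1, len(p))
        )
        orth, _ = transfer_annotation({"Q1": q}, {"R1": p})
        assert orth == {}

    def test_non_reciprocal_best_hit_rejected(self, rng):
        p = random_protein(rng, 120)
        mutated = list(p)
        for i in rng.choice(np.arange(1, 120), size=12, replace=False):
            mutated[i] = "W" if p[i] != "W" else "Y"
        a = "".join(mutated)  # A: decayed copy of p
        orth, _ = transfer_annotation({"A": a, "C": p}, {"B": p})
        # B's best hit is C (exact), so A gains no ortholog
        assert "A" not in orth
        assert orth.get("C") == "B"
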