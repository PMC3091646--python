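import random

import pytest

from pseudis.pathway_status import (
    GeneStatusTable,
    PathwayDef,
    PathwayError,
    Reaction,
    complementation_report,
    load_bundled_pathway,
    load_bundled_status,
    pathway_report,
    producible_metabolites,
)


@pytest.fixture(scope="module")
def sg():
    return load_bundled_status("sodalis")


@pytest.fixture(scope="module")
def wg():
    return load_bundled_status("wigglesworthia")


class TestCore:
    def linear(self, statuses):
        pw = PathwayDef(
            name="toy",
            reactions=[
                Reaction("r1", ["a"], ["b"], "g1"),
                Reaction("r2", ["b"], ["c"], ["OR", "g2", "g3"]),
                Reaction("r3", ["c", "a"], ["d"], ["AND", "g4", "g5"]),
            ],
            external_inputs=["a"],
            targets=["d"],
        )
        return pw, GeneStatusTable("org", statuses)

    def test_all_functional_reaches_target(self):
        pw, st = self.linear({g: "functional" for g in ("g1", "g2", "g3", "g4", "g5")})
        assert "d" in producible_metabolites(pw, st)

    def test_or_tolerates_one_pseudogene(self):
        pw, st = self.linear(
            {"g1": "functional", "g2": "pseudogene", "g3": "functional",
             "g4": "functional", "g5": "functional"}
        )
        assert "d" in producible_metabolites(pw, st)

    def test_and_blocks_on_absent_gene(self):
        pw, st = self.linear(
            {"g1": "functional", "g2": "functional", "g3": "functional",
             "g4": "absent", "g5": "functional"}
        )
        rep = pathway_report(pw, st)
        assert rep.target_verdicts["d"] == "blocked"
        assert rep.missing_steps == ["r3"]
        assert rep.inactivated_steps == []

    def test_unlisted_gene_is_absent(self):
        pw, st = self.linear({"g1": "functional"})
        assert producible_metabolites(pw, st) == {"a", "b"}

    def test_malformed_expression_names_reaction(self):
        with pytest.raises(PathwayError, match="rx"):
            Reaction("rx", ["a"], ["b"], ["NOT", "g1"])

    def test_target_must_be_reachable_in_principle(self):
        with pytest.raises(PathwayError, match="ghost"):
            PathwayDef("t", [Reaction("r", ["a"], ["b"], "g")], ["a"], ["ghost"])

    def test_cycles_converge(self):
        pw = PathwayDef(
            "cyc",
            [
                Reaction("r1", ["a"], ["b"], "g1"),
                Reaction("r2", ["b"], ["a", "c"], "g1"),
            ],
            ["a"],
            ["c"],
        )
        st = GeneStatusTable("org", {"g1": "functional"})
        assert producible_metabolites(pw, st) == {"a", "b", "c"}


class TestRandomizedProperties:
    def random_pathway(self, rnd):
        mets = [f"m{i}" for i in range(10)]
        genes = [f"g{i}" for i in range(6)]
        reactions = []
        for i in range(1, 10):
            subs = rnd.sample(mets[:i], k=min(len(mets[:i]), rnd.randint(1, 2)))
            expr = rnd.choice(
                [
                    rnd.choice(genes),
                    ["AND", rnd.choice(genes), rnd.choice(genes)],
                    ["OR", rnd.choice(genes), rnd.choice(genes)],
                ]
            )
            reactions.append(Reaction(f"r{i}", subs, [mets[i]], expr))
        pw = PathwayDef("rand", reactions, ["m0"], [mets[-1]])
        st = {g: rnd.choice(["functional", "pseudogene", "absent"]) for g in genes}
        return pw, st

    def test_order_independence(self):
        rnd = random.Random(11)
        for _ in range(30):
            pw, st = self.random_pathway(rnd)
            table = GeneStatusTable("org", st)
            base = producible_metabolites(pw, table)
            shuffled = PathwayDef(
                pw.name, rnd.sample(pw.reactions, k=len(pw.reactions)),
                pw.external_inputs, pw.targets,
            )
            assert producible_metabolites(shuffled, table) == base

    def test_monotone_under_status_upgrade(self):
        order = {"absent": 0, "pseudogene": 1, "functional": 2}
        upgrade = {"absent": "pseudogene", "pseudogene": "functional", "functional": "functional"}
        rnd = random.Random(13)
        for _ in range(30):
            pw, st = self.random_pathway(rnd)
            base = producible_metabolites(pw, GeneStatusTable("org", st))
            g = rnd.choice(sorted(st))
            st2 = {**st, g: upgrade[st[g]]}
            assert order[st2[g]] >= order[st[g]]
            up = producible_metabolites(pw, GeneStatusTable("org", st2))
            assert up >= base

    def test_consortium_superset_of_standalone(self):
        rnd = random.Random(17)
        for _ in range(15):
            pw, st_a = self.random_pathway(rnd)
            _, st_b = self.random_pathway(rnd)
            a = GeneStatusTable("A", st_a)
            b = GeneStatusTable("B", st_b)
            exch = set(rnd.sample([f"m{i}" for i in range(10)], k=4))
            comp = complementation_report(pw, a, b, exch)
            assert comp.producible_a_exchange >= comp.producible_a
            assert comp.producible_b_exchange >= comp.producible_b

    def test_no_exchange_equals_standalone(self, sg, wg):
        pw = load_bundled_pathway("thiamine")
        comp = complementation_report(pw, sg, wg, set())
        assert comp.producible_a_exchange == comp.producible_a
        assert comp.producible_b_exchange == comp.producible_b


class TestBundledFixtures:
    def test_arginine_blocked_with_exact_inactivated_steps(self, sg):
        rep = pathway_report(load_bundled_pathway("arginine"), sg)
        assert rep.target_verdicts["L-arginine"] == "blocked"
        assert sorted(rep.inactivated_steps) == ["argA", "argC", "argD", "argG"]
        assert rep.missing_steps == [] and rep.both_steps == []

    def test_putrescine_from_arginine_not_ornithine(self, sg):
        pw = load_bundled_pathway("putrescine")
        assert "putrescine" in producible_metabolites(pw, sg, ["L-arginine"])
        assert "putrescine" not in producible_metabolites(pw, sg, ["L-ornithine"])

    def test_lysine_rescued_by_alternative_aminotransferase(self, sg):
        rep = pathway_report(load_bundled_pathway("lysine"), sg)
        assert rep.target_verdicts["L-lysine"] == "producible"
        assert rep.target_verdicts["meso-diaminopimelate"] == "producible"

    def test_thiamine_sodalis_thz_branch_only(self, sg):
        rep = pathway_report(load_bundled_pathway("thiamine"), sg)
        assert rep.target_verdicts == {
            "thiamine-diphosphate": "blocked",
            "THZ-P": "producible",
            "HMP-PP": "blocked",
        }
        assert "thiD" in rep.missing_steps or "hmp_salvage" in rep.missing_steps
        assert "thiazole_synthase" in rep.inactivated_steps

    def test_thiamine_sodalis_salvage_from_exogenous_thiamine(self, sg):
        pw = load_bundled_pathway("thiamine")
        prod = producible_metabolites(pw, sg, list(pw.external_inputs) + ["thiamine_ext"])
        assert "THZ-P" in prod  # via transport, tenA2 and thiM
        assert "thiamine-diphosphate" in prod  # via thiK and thiL

    def test_thiamine_wigglesworthia_hmp_branch_only(self, wg):
        rep = pathway_report(load_bundled_pathway("thiamine"), wg)
        assert rep.target_verdicts == {
            "thiamine-diphosphate": "blocked",
            "THZ-P": "blocked",
            "HMP-PP": "producible",
        }
        # the sulfur relay fails through a pseudogene (thiF) and absent genes
        # (thiI, iscS) simultaneously
        assert rep.both_steps == ["sulfur_relay"]

    def test_thiamine_complementation_via_moiety_exchange(self, sg, wg):
        pw = load_bundled_pathway("thiamine")
        comp = complementation_report(pw, sg, wg, {"THZ-P", "HMP-PP"})
        v = comp.verdicts["thiamine-diphosphate"]
        assert v["S_glossinidius"] == "blocked"
        assert v["W_glossinidia"] == "blocked"
        assert v["consortium"] == {
            "S_glossinidius": "producible",
            "W_glossinidia": "producible",
        }

    def test_all_genes_absent_only_inputs_producible(self):
        pw = load_bundled_pathway("arginine")
        st = GeneStatusTable("empty", {})
        rep = pathway_report(pw, st)
        assert rep.producible == set(pw.external_inputs)
        assert len(rep.missing_steps) >= 1
        assert rep.inactivated_steps == []
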