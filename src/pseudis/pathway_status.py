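"""Boolean pathway completeness and two-organism metabolic complementation.

A pathway is a set of reactions, each consuming substrate metabolites and
producing product metabolites when its gene requirement — an AND/OR
expression over gene symbols — is satisfied.  Gene status is three-valued
(functional / pseudogene / absent); a pseudogene contributes no activity, so
pseudogene and absent both evaluate false, but non-firing reactions are
reported separately as *inactivated* (pseudogene-caused) versus *missing*
(absence-caused), mirroring how re-annotation studies distinguish recent
gene decay from ancestral gene loss.

Producibility is the least fixed point: starting from the external inputs, a
reaction fires iff all its substrates are producible and its requirement is
true; products join the set; iterate to convergence.  The result is
deterministic and independent of evaluation order, and gene-status upgrades
can only grow the producible set (requirements are monotone).

Complementation couples two organisms through an exchangeable metabolite
set: each organism's inputs are augmented with the exchangeable metabolites
its partner can produce, iterating the joint system to convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

VALID_STATUS = ("functional", "pseudogene", "absent")


class PathwayError(ValueError):
    pass


@dataclass
class Reaction:
    id: str
    substrates: list[str]
    products: list[str]
    gene_requirement: object  # nested ["AND"/"OR", ...] expression or gene symbol
    kind: str = "enzymatic"   # enzymatic | transport

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise PathwayError(f"reaction {self.id}: substrates and products must be non-empty")
        if self.kind not in ("enzymatic", "transport"):
            raise PathwayError(f"reaction {self.id}: bad kind {self.kind!r}")
        _validate_expr(self.gene_requirement, self.id)

    def genes(self) -> set[str]:
        return _expr_genes(self.gene_requirement)


def _validate_expr(expr, rid):
    if isinstance(expr, str):
        if not expr:
            raise PathwayError(f"reaction {rid}: empty gene symbol")
        return
    if isinstance(expr, (list, tuple)):
        if len(expr) < 2 or expr[0] not in ("AND", "OR"):
            raise PathwayError(f"reaction {rid}: malformed expression {expr!r}")
        for sub in expr[1:]:
            _validate_expr(sub, rid)
        return
    raise PathwayError(f"reaction {rid}: malformed expression {expr!r}")


def _expr_genes(expr) -> set[str]:
    if isinstance(expr, str):
        return {expr}
    out: set[str] = set()
    for sub in expr[1:]:
        out |= _expr_genes(sub)
    return out


def _eval_expr(expr, truth: dict[str, bool]) -> bool:
    if isinstance(expr, str):
        return truth[expr]
    op = expr[0]
    vals = (_eval_expr(sub, truth) for sub in expr[1:])
    return all(vals) if op == "AND" else any(vals)


@dataclass
class GeneStatusTable:
    organism: str
    status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for g, s in self.status.items():
            if s not in VALID_STATUS:
                raise PathwayError(f"{self.organism}: bad status {s!r} for gene {g}")

    def lookup(self, gene: str) -> str:
        # unlisted genes are treated as absent (and reported as such)
        return self.status.get(gene, "absent")

    def truth(self, genes) -> dict[str, bool]:
        return {g: self.lookup(g) == "functional" for g in genes}


@dataclass
class PathwayDef:
    name: str
    reactions: list[Reaction]
    external_inputs: list[str]
    targets: list[str]

    def __post_init__(self):
        producible = set(self.external_inputs) | {
            p for r in self.reactions for p in r.products
        }
        for t in self.targets:
            if t not in producible:
                raise PathwayError(f"target {t!r} is produced by no reaction and not an input")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return out


@dataclass
class CompletenessReport:
    organism: str
    producible: set[str]
    inactivated_steps: list[str]   # requirement fails because of pseudogenes
    missing_steps: list[str]       # requirement fails because of absent genes
    both_steps: list[str]          # fails for both reasons
    target_verdicts: dict[str, str]  # target -> producible | blocked


# ---------------------------------------------------------------------------


def producible_metabolites(
    pathway: PathwayDef,
    statuses: GeneStatusTable,
    inputs_override: list[str] | None = None,
) -> set[str]:
    """Least fixed point of the firing relation from the external inputs."""
    truth = statuses.truth(pathway.genes())
    producible = set(pathway.external_inputs if inputs_override is None else inputs_override)
    fired_req = {r.id: _eval_expr(r.gene_requirement, truth) for r in pathway.reactions}
    changed = True
    while changed:
        changed = False
        for r in pathway.reactions:
            if not fired_req[r.id]:
                continue
            if all(s in producible for s in r.substrates):
                new = set(r.products) - producible
                if new:
                    producible |= new
                    changed = True
    return producible


def pathway_report(
    pathway: PathwayDef,
    statuses: GeneStatusTable,
    inputs_override: list[str] | None = None,
) -> CompletenessReport:
    """Completeness report: producible set, target verdicts, and non-firing
    reactions classified by the cause of the requirement failure."""
    truth = statuses.truth(pathway.genes())
    producible = producible_metabolites(pathway, statuses, inputs_override)
    inactivated, missing, both = [], [], []
    for r in pathway.reactions:
        if _eval_expr(r.gene_requirement, truth):
            continue
        genes = r.genes()
        as_if_pseudo_ok = {
            g: truth[g] or statuses.lookup(g) == "pseudogene" for g in genes
        }
        as_if_absent_ok = {
            g: truth[g] or statuses.lookup(g) == "absent" for g in genes
        }
        pseudo_caused = _eval_expr(r.gene_requirement, as_if_pseudo_ok)
        absent_caused = _eval_expr(r.gene_requirement, as_if_absent_ok)
        if pseudo_caused and absent_caused:
            # fails only through a mix: restoring either class alone fixes it
            both.append(r.id)
        elif pseudo_caused:
            inactivated.append(r.id)
        elif absent_caused:
            missing.append(r.id)
        else:
            both.append(r.id)  # needs both classes restored
    verdicts = {
        t: "producible" if t in producible else "blocked" for t in pathway.targets
    }
    return CompletenessReport(
        organism=statuses.organism,
        producible=producible,
        inactivated_steps=inactivated,
        missing_steps=missing,
        both_steps=both,
        target_verdicts=verdicts,
    )


@dataclass
class ComplementationReport:
    producible_a: set[str]
    producible_b: set[str]
    producible_a_exchange: set[str]
    producible_b_exchange: set[str]
    verdicts: dict[str, dict[str, str]]  # target -> {A, B, consortium}


def complementation_report(
    pathway: PathwayDef,
    statuses_a: GeneStatusTable,
    statuses_b: GeneStatusTable,
    exchangeable: set[str],
    inputs_a: list[str] | None = None,
    inputs_b: list[str] | None = None,
) -> ComplementationReport:
    """Joint fixed point of two organisms exchanging a metabolite set."""
    base_a = list(pathway.external_inputs if inputs_a is None else inputs_a)
    base_b = list(pathway.external_inputs if inputs_b is None else inputs_b)
    alone_a = producible_metabolites(pathway, statuses_a, base_a)
    alone_b = producible_metabolites(pathway, statuses_b, base_b)
    prod_a, prod_b = set(alone_a), set(alone_b)
    while True:
        in_a = set(base_a) | (exchangeable & prod_b)
        in_b = set(base_b) | (exchangeable & prod_a)
        new_a = producible_metabolites(pathway, statuses_a, sorted(in_a))
        new_b = producible_metabolites(pathway, statuses_b, sorted(in_b))
        if new_a == prod_a and new_b == prod_b:
            break
        prod_a, prod_b = new_a, new_b
    verdicts = {}
    for t in pathway.targets:
        verdicts[t] = {
            statuses_a.organism: "producible" if t in alone_a else "blocked",
            statuses_b.organism: "producible" if t in alone_b else "blocked",
            "consortium": {
                statuses_a.organism: "producible" if t in prod_a else "blocked",
                statuses_b.organism: "producible" if t in prod_b else "blocked",
            },
        }
    return ComplementationReport(
        producible_a=alone_a,
        producible_b=alone_b,
        producible_a_exchange=prod_a,
        producible_b_exchange=prod_b,
        verdicts=verdicts,
    )


# ---------------------------------------------------------------------------
# JSON schema + bundled fixtures


def pathway_from_dict(d: dict) -> PathwayDef:
    return PathwayDef(
        name=d["name"],
        reactions=[
            Reaction(
                id=r["id"],
                substrates=list(r["substrates"]),
                products=list(r["products"]),
                gene_requirement=r["gene_requirement"],
                kind=r.get("kind", "enzymatic"),
            )
            for r in d["reactions"]
        ],
        external_inputs=list(d["external_inputs"]),
        targets=list(d["targets"]),
    )


def load_pathway_file(path) -> PathwayDef:
    with open(path) as fh:
        return pathway_from_dict(json.load(fh))


def load_status_file(path) -> GeneStatusTable:
    with open(path) as fh:
        d = json.load(fh)
    return GeneStatusTable(organism=d["organism"], status=dict(d["status"]))


def _data_text(name: str) -> str:
    return resources.files("pseudis").joinpath(f"data/pathways/{name}").read_text()


def load_bundled_pathway(name: str) -> PathwayDef:
    """Bundled pathway fixtures: arginine, putrescine, lysine, thiamine."""
    return pathway_from_dict(json.loads(_data_text(f"{name}.json")))


def load_bundled_status(organism: str) -> GeneStatusTable:
    """Bundled status tables: ``sodalis`` and ``wigglesworthia``."""
    d = json.loads(_data_text(f"status_{organism}.json"))
    return GeneStatusTable(organism=d["organism"], status=dict(d["status"]))
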