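"""Scoring of full pipeline runs against a synthetic truth manifest.

Runs the production path end to end — IS discovery first, then two-pass
pseudogene detection with the located IS copies — and compares the output
with the generator's ground truth: planted-pseudogene recovery, disruption
count agreement, split records, IS-split rejoining, and IS family structure
(TIR/TSD lengths, consensus identity against the designed element).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .io_formats import revcomp
from .is_elements import ISParams, find_is_families
from .pseudogene_pipeline import PipelineParams, run_two_pass
from .synthetic_genome import SimConfig, plant_genome


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class BenchmarkResult:
    sensitivity: float
    precision: float
    n_planted: int
    n_calls: int
    disruption_exact_fraction: float
    splits_detected: int
    splits_planted: int
    is_insertion_calls: int
    is_split_planted: int
    n_families_detected: int
    family_metrics: list[dict] = field(default_factory=list)

    @property
    def tir_exact(self) -> bool:
        return all(m["tir_detected"] == m["tir_planted"] for m in self.family_metrics)

    @property
    def tsd_exact(self) -> bool:
        return all(m["tsd_detected"] == m["tsd_planted"] for m in self.family_metrics)

    @property
    def min_consensus_identity(self) -> float:
        return min((m["consensus_identity"] for m in self.family_metrics), default=0.0)


def run_benchmark(
    config: SimConfig,
    pipeline_params: PipelineParams | None = None,
    is_params: ISParams | None = None,
):
    """Returns ``(BenchmarkResult, SimResult, ReconciledAnnotation)``."""
    sim = plant_genome(config)
    families = find_is_families(sim.genome, is_params)
    is_copies = [c.interval for f in families for c in f.copies]
    rec = run_two_pass(
        sim.genome, sim.annotation, sim.proteome,
        params=pipeline_params, is_copies=is_copies,
    )

    truth_ps = {t.feature_id: t for t in sim.truth if t.category == "pseudogene"}
    matched: set[str] = set()
    n_exact = 0
    n_matched_calls = 0
    false_calls = 0
    for c in rec.calls:
        span = (c.start, c.end)
        hit = None
        for tid, t in truth_ps.items():
            ts = (
                min(s for s, _ in t.planted_segments),
                max(e for _, e in t.planted_segments),
            )
            if _overlap(span, ts) > 0.5 * (ts[1] - ts[0]) and t.origin_protein_id == c.subject_id:
                hit = tid
                break
        if hit is None:
            false_calls += 1
            continue
        matched.add(hit)
        n_matched_calls += 1
        t = truth_ps[hit]
        if (
            c.disruptions["frameshifts"] == t.disruptions["frameshifts"]
            and c.disruptions["premature_stops"] == t.disruptions["premature_stops"]
            and c.disruptions["is_insertion"] == t.disruptions["is_insertion"]
        ):
            n_exact += 1

    fam_metrics = []
    for fam in families:
        best = None
        for fid, element in sim.is_elements.items():
            for seq in (element, revcomp(element)):
                d = edlib.align(fam.consensus, seq, mode="NW")["editDistance"]
                ident = 1.0 - d / max(len(seq), len(fam.consensus))
                if best is None or ident > best[1]:
                    best = (fid, ident)
        fid, ident = best
        spec = config.is_families[int(fid[3:]) - 1]
        fam_metrics.append(
            {
                "detected_family": fam.family_id,
                "planted_family": fid,
                "consensus_identity": ident,
                "tir_detected": fam.stats["tir_len"],
                "tir_planted": spec.tir_len or None,
                "tsd_detected": fam.stats["tsd_len"],
                "tsd_planted": spec.tsd_len,
                "n_complete_detected": fam.stats["n_complete"],
                "n_complete_planted": spec.n_complete + spec.n_defective,
                "n_partial_detected": fam.stats["n_partial"],
                "n_partial_planted": spec.n_partial,
            }
        )

    n_planted = len(truth_ps)
    result = BenchmarkResult(
        sensitivity=len(matched) / n_planted if n_planted else 1.0,
        precision=(len(rec.calls) - false_calls) / len(rec.calls) if rec.calls else 1.0,
        n_planted=n_planted,
        n_calls=len(rec.calls),
        disruption_exact_fraction=n_exact / n_matched_calls if n_matched_calls else 0.0,
        splits_detected=len(rec.splits),
        splits_planted=config.n_missplit_genes,
        is_insertion_calls=sum(1 for c in rec.calls if c.disruptions["is_insertion"]),
        is_split_planted=config.n_is_split_genes,
        n_families_detected=len(families),
        family_metrics=fam_metrics,
    )
    return result, sim, rec
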