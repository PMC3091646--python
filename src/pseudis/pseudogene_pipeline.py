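"""Two-pass intergenic pseudogene discovery and reconciliation.

The procedure mirrors classic endosymbiont re-annotation practice:

1. extract intergenic regions (>= 50 bp between non-overlapping features),
2. search them against a reference proteome with a translated (BLASTX-like)
   search, chain colinear HSPs per subject across reading frames, and keep
   chains covering >= 25% of the subject protein,
3. reconstruct a gene model per chain (one segment per HSP, frameshifts =
   frame changes between consecutive segments, premature stops = in-frame
   stops inside segments), rescuing short sub-significant fragments the way
   Genewise rebuilds ORFs around the best hit,
4. re-extract intergenic space counting the new pseudogenes and run a second
   pass against an extended proteome,
5. merge adjacent same-subject calls, rejoin genes split by an IS insertion,
   and convert "short annotated gene + flanking pseudogene" situations into
   split records.

Significance gating: individual HSPs are collected at a relaxed reporting
floor and the BLAST-style cutoff (default E <= 1e-5) is applied to the
chained total score, the chain being the analogue of a linked HSP set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .io_formats import AnnotationSet, Feature, GenomeRecord, revcomp
from .translated_search import (
    HSP,
    ProteomeIndex,
    SearchParams,
    evalue_of,
    local_align,
    search_region,
    six_frame_translate,
)


@dataclass(frozen=True)
class PipelineParams:
    min_intergenic_len: int = 50
    min_subject_coverage: float = 0.25
    chain_max_genomic_gap: int = 3000
    chain_max_subject_overlap: int = 10   # aa
    chain_max_genomic_overlap: int = 45   # nt; tolerates TSD duplications
    merge_max_distance: int = 3000
    hsp_report_evalue: float = 10.0       # per-HSP reporting floor inside the pipeline
    rescue_min_score: int = 15            # Genewise-like fragment rescue floor
    search: SearchParams = SearchParams()

    def __post_init__(self):
        if not (0 < self.min_subject_coverage <= 1):
            raise ValueError("min_subject_coverage must be in (0,1]")
        if min(self.min_intergenic_len, self.chain_max_genomic_gap,
               self.merge_max_distance) < 0:
            raise ValueError("lengths must be >= 0")


@dataclass
class IntergenicRegion:
    interval: tuple[int, int]
    left_flank_id: str   # locus_tag or "chromosome_start"
    right_flank_id: str  # locus_tag or "chromosome_end"

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class PseudogeneCall:
    subject_id: str
    strand: str
    segments: list[tuple[int, int]] = field(default_factory=list)  # genomic, ascending
    frames: list[int] = field(default_factory=list)                # frame per segment
    subject_coverage: float = 0.0
    disruptions: dict = field(default_factory=lambda: {
        "frameshifts": 0, "premature_stops": 0, "is_insertion": False})
    pass_found: int = 1
    evidence: list[HSP] = field(default_factory=list)
    region: tuple[int, int] = (0, 0)
    score: int = 0
    evalue: float = 0.0
    locus_tag: str = ""

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)

    def subject_union(self) -> list[tuple[int, int]]:
        ivs = sorted(h.subject_interval for h in self.evidence)
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out


@dataclass
class SplitRecord:
    """An annotated short gene plus an adjacent pseudogene that together
    represent one ancestral CDS."""

    combined_interval: tuple[int, int]
    gene_id: str
    pseudogene_id: str
    subject_id: str
    gene_fraction: float
    pseudogene_fraction: float
    relative_position: str  # gene at "5P" or "3P" of the combined CDS


@dataclass
class ReconciledAnnotation:
    annotation: AnnotationSet       # original features + reconciled pseudogenes
    calls: list[PseudogeneCall]
    splits: list[SplitRecord]


# ---------------------------------------------------------------------------


def extract_intergenic(
    annotation: AnnotationSet, genome: GenomeRecord, params: PipelineParams | None = None
) -> list[IntergenicRegion]:
    """Complement of the union of annotated features, kept when >= threshold.

    Overlapping neighbours produce no region between them; chromosome ends
    count as regions flanked by a sentinel.
    """
    params = params or PipelineParams()
    annotation.validate_against(genome)
    L = len(genome)
    ivs = []
    for f in annotation.sorted_features():
        for s, e in f.segments:
            ivs.append((s, e, f.locus_tag))
    ivs.sort()
    regions = []
    cursor = 0
    left_id = "chromosome_start"
    for s, e, tag in ivs:
        if s > cursor:
            regions.append(IntergenicRegion((cursor, s), left_id, tag))
        if e > cursor:
            cursor = e
            left_id = tag
    if cursor < L:
        regions.append(IntergenicRegion((cursor, L), left_id, "chromosome_end"))
    return [r for r in regions if r.length >= params.min_intergenic_len]


# ---------------------------------------------------------------------------
# chaining


def _chain_hsps(hsps: list[HSP], subject_len: int, region_len: int,
                db_len_aa: int, params: PipelineParams,
                spans_is=None) -> list[dict]:
    """Best-scoring colinear chain per (subject, strand) via DP.

    Colinear: ascending subject positions along the transcription direction,
    genomic gap <= chain_max_genomic_gap, subject overlap <= 10 aa, small
    genomic overlap tolerated (target-site duplications).  A junction whose
    genomic gap spans a located IS copy tolerates up to 30 aa of subject
    overlap (target-site duplication plus alignment slop into the element).
    """
    if not hsps:
        return []
    strand = hsps[0].strand
    # order along transcription direction
    hs = sorted(hsps, key=lambda h: (h.query_interval[0] if strand == "+" else -h.query_interval[1],
                                     h.subject_interval))
    n = len(hs)
    best = [h.score for h in hs]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = hs[i], hs[j]
            if strand == "+":
                gap = b.query_interval[0] - a.query_interval[1]
                gap_iv = (a.query_interval[1], b.query_interval[0])
            else:
                gap = a.query_interval[0] - b.query_interval[1]
                gap_iv = (b.query_interval[1], a.query_interval[0])
            if gap > params.chain_max_genomic_gap or gap < -params.chain_max_genomic_overlap:
                continue
            allowed_ov = params.chain_max_subject_overlap
            if spans_is is not None and gap > 0 and spans_is(gap_iv):
                allowed_ov = 30
            if b.subject_interval[0] < a.subject_interval[1] - allowed_ov:
                continue
            if b.subject_interval[1] <= a.subject_interval[1]:
                continue
            cand = best[i] + b.score
            if cand > best[j]:
                best[j] = cand
                prev[j] = i
    out = []
    j = max(range(n), key=lambda k: best[k])
    chain = []
    while j >= 0:
        chain.append(hs[j])
        j = prev[j]
    chain.reverse()
    total = sum(h.score for h in chain)
    cov_iv = []
    for h in chain:
        cov_iv.append(h.subject_interval)
    cov_iv.sort()
    merged = []
    for s, e in cov_iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    covered = sum(e - s for s, e in merged)
    out.append({
        "hsps": chain,
        "score": total,
        "coverage": covered / subject_len,
        "evalue": evalue_of(total, region_len, db_len_aa),
    })
    return out


def detect_pass(
    regions: list[IntergenicRegion],
    genome: GenomeRecord,
    proteome: dict[str, str],
    params: PipelineParams | None = None,
    pass_no: int = 1,
    index: ProteomeIndex | None = None,
    is_copies: list[tuple[int, int]] | None = None,
) -> list[PseudogeneCall]:
    """One search pass over intergenic regions.

    Per region, HSPs are grouped by (subject, strand) and chained; the chain
    total score must pass the configured E-value cutoff and the chain must
    cover >= min_subject_coverage of the subject.  Overlapping chains on the
    same genomic span are resolved by total score (ties: E-value, then
    subject id).
    """
    params = params or PipelineParams()
    if not proteome:
        raise ValueError("empty proteome")
    db_len_aa = sum(len(s) for s in proteome.values())
    index = index or ProteomeIndex(proteome, params.search.seed_word_len)
    relaxed = replace(params.search, evalue_cutoff=params.hsp_report_evalue)
    sorted_is = sorted(is_copies or [])

    def spans_is(gap: tuple[int, int]) -> bool:
        for cs, ce in sorted_is:
            if gap[0] - 50 <= cs and ce <= gap[1] + 50 and \
                    min(gap[1], ce) - max(gap[0], cs) > 0.5 * (ce - cs):
                return True
        return False

    calls: list[PseudogeneCall] = []
    for region in regions:
        s0, e0 = region.interval
        dna = genome.sequence[s0:e0]
        hsps = search_region(dna, s0, proteome, relaxed, index=index, db_len_aa=db_len_aa)
        groups: dict[tuple[str, str], list[HSP]] = {}
        for h in hsps:
            if h.evalue > params.search.evalue_cutoff:
                # sub-significant HSPs may only join a chain when they look
                # like genuine conserved fragments, not diffuse chance matches
                aa = max(1, h.subject_interval[1] - h.subject_interval[0])
                if h.score < 2.5 * aa:
                    continue
            groups.setdefault((h.subject_id, h.strand), []).append(h)
        chains = []
        for (sid, strand), hs in groups.items():
            for c in _chain_hsps(hs, len(proteome[sid]), len(dna), db_len_aa, params,
                                 spans_is=spans_is):
                c["subject"] = sid
                c["strand"] = strand
                chains.append(c)
        chains = [
            c for c in chains
            if c["evalue"] <= params.search.evalue_cutoff
            and c["coverage"] >= params.min_subject_coverage
        ]
        # overlap resolution on the same genomic span
        chains.sort(key=lambda c: (-c["score"], c["evalue"], c["subject"]))
        kept = []
        for c in chains:
            cs = min(h.query_interval[0] for h in c["hsps"])
            ce = max(h.query_interval[1] for h in c["hsps"])
            clash = False
            for k in kept:
                ov = min(ce, k["_end"]) - max(cs, k["_start"])
                if ov > 0.5 * min(ce - cs, k["_end"] - k["_start"]):
                    clash = True
                    break
            if not clash:
                c["_start"], c["_end"] = cs, ce
                kept.append(c)
        for c in sorted(kept, key=lambda c: c["_start"]):
            calls.append(
                PseudogeneCall(
                    subject_id=c["subject"],
                    strand=c["strand"],
                    segments=[h.query_interval for h in sorted(c["hsps"], key=lambda h: h.query_interval)],
                    frames=[h.frame for h in sorted(c["hsps"], key=lambda h: h.query_interval)],
                    subject_coverage=c["coverage"],
                    pass_found=pass_no,
                    evidence=c["hsps"],
                    region=region.interval,
                    score=c["score"],
                    evalue=c["evalue"],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# model reconstruction


def _translate_frame_segment(genome_seq: str, seg: tuple[int, int], frame: int) -> str:
    s, e = seg
    dna = genome_seq[s:e]
    if frame < 0:
        dna = revcomp(dna)
    n = 3 * (len(dna) // 3)
    return six_frame_translate(dna[:n])[1] if n else ""


def _genome_frame(seg: tuple[int, int], strand: str, genome_len: int) -> int:
    """Canonical frame label from the genome phase of a codon-aligned segment."""
    if strand == "+":
        return seg[0] % 3 + 1
    return -((genome_len - seg[1]) % 3 + 1)


def reconstruct_model(call: PseudogeneCall, genome: GenomeRecord,
                      proteome: dict[str, str],
                      params: PipelineParams | None = None) -> PseudogeneCall:
    """Fill in segments and disruption counts for a chained call.

    One segment per chained HSP (already codon-aligned in its frame).
    Unexplained subject stretches (>= 3 aa) between consecutive segments or
    at the termini are re-aligned against the local genomic window at a low
    score floor, recovering fragments too short to be significant on their
    own — the package's analogue of Genewise ORF joining.  Frameshifts are
    frame changes between consecutive segments; premature stops are stops
    translated inside segments.
    """
    params = params or PipelineParams()
    if not call.evidence:
        raise ValueError("call has no evidence HSPs")
    signs = {h.frame > 0 for h in call.evidence}
    if len(signs) > 1:
        raise RuntimeError("mixed-sign frames in one chain (chaining bug)")
    subject = proteome[call.subject_id]
    strand = call.strand
    hsps = sorted(call.evidence, key=lambda h: h.subject_interval)
    rlo, rhi = call.region
    L = len(genome.sequence)
    rlo, rhi = max(0, rlo), min(L, rhi)

    def genomic_window(prev_h, next_h, aa_gap):
        """Window (gs, ge) on the forward strand between two HSPs (either may
        be None at the termini) in which a missing fragment may sit."""
        slack = 3 * aa_gap + 36
        if strand == "+":
            gs = prev_h.query_interval[1] if prev_h else max(rlo, next_h.query_interval[0] - slack)
            ge = next_h.query_interval[0] if next_h else min(rhi, prev_h.query_interval[1] + slack)
        else:
            gs = next_h.query_interval[1] if next_h else max(rlo, prev_h.query_interval[0] - slack)
            ge = prev_h.query_interval[0] if prev_h else min(rhi, next_h.query_interval[1] + slack)
        return (gs, ge) if ge - gs >= 9 else None

    def rescue(prev_h, next_h):
        lo = prev_h.subject_interval[1] if prev_h else 0
        hi = next_h.subject_interval[0] if next_h else len(subject)
        if hi - lo < 3:
            # no clear subject gap, but an unexplained genomic stretch can
            # still hide a short out-of-frame fragment (sloppy junctions)
            if prev_h is None or next_h is None:
                return None
            if strand == "+":
                g_gap = next_h.query_interval[0] - prev_h.query_interval[1]
            else:
                g_gap = prev_h.query_interval[0] - next_h.query_interval[1]
            if g_gap < 9:
                return None
            lo, hi = max(0, lo - 3), min(len(subject), hi + 3)
            if hi - lo < 3:
                return None
        aa_gap = hi - lo
        win = genomic_window(prev_h, next_h, aa_gap)
        if win is None:
            return None
        gs, ge = win
        dna = genome.sequence[gs:ge]
        if strand == "-":
            dna = revcomp(dna)
        frag = subject[lo:hi]
        # a genuine missing fragment aligns near-perfectly (~5 bits/aa); a
        # floor growing with the gap keeps junk matches out of wide windows
        floor = max(params.rescue_min_score, int(1.5 * aa_gap))
        best = None
        for off in range(3):
            sub = dna[off : off + 3 * ((len(dna) - off) // 3)]
            if len(sub) < 9:
                continue
            pep = six_frame_translate(sub)[1]
            score, p_iv, f_iv, ident = local_align(frag, pep, params.search)
            if score >= floor and ident >= 0.4 and (best is None or score > best[0]):
                best = (score, off, p_iv, f_iv, ident)
        if best is None:
            return None
        score, off, p_iv, f_iv, ident = best
        if strand == "+":
            q = (gs + off + 3 * f_iv[0], gs + off + 3 * f_iv[1])
        else:
            q = (ge - (off + 3 * f_iv[1]), ge - (off + 3 * f_iv[0]))
        frame = _genome_frame(q, strand, L)
        return HSP(
            query_interval=q, frame=frame, subject_id=call.subject_id,
            subject_interval=(lo + p_iv[0], lo + p_iv[1]),
            score=score, identity=ident, evalue=math.inf, frame_interval=f_iv,
        )

    rescued = []
    pairs = [(None, hsps[0])] + list(zip(hsps, hsps[1:])) + [(hsps[-1], None)]
    for prev_h, next_h in pairs:
        r = rescue(prev_h, next_h)
        if r is not None:
            rescued.append(r)
    # drop fragments that mostly duplicate genomic or subject space already
    # explained by a stronger HSP; small overlaps (a few nt at frameshift
    # junctions, TSDs) are legitimate
    pruned: list[HSP] = []
    for h in sorted(hsps + rescued, key=lambda h: -h.score):
        dup = False
        for p in pruned:
            gov = _overlap(h.query_interval, p.query_interval)
            sov = _overlap(h.subject_interval, p.subject_interval)
            g_short = min(h.query_interval[1] - h.query_interval[0],
                          p.query_interval[1] - p.query_interval[0])
            s_short = min(h.subject_interval[1] - h.subject_interval[0],
                          p.subject_interval[1] - p.subject_interval[0]) or 1
            if gov > 0.5 * g_short or sov > 0.5 * s_short:
                dup = True
                break
        if not dup:
            pruned.append(h)
    all_hsps = sorted(pruned, key=lambda h: h.query_interval)

    segments = [h.query_interval for h in all_hsps]
    frames = [_genome_frame(h.query_interval, strand, L) for h in all_hsps]
    # along transcription direction for frame-change counting
    tx = list(zip(segments, frames)) if strand == "+" else list(zip(segments, frames))[::-1]
    frameshifts = sum(1 for (s1, f1), (s2, f2) in zip(tx, tx[1:]) if f1 != f2)

    stops = 0
    for seg, fr, h in zip(segments, frames, all_hsps):
        pep = _translate_frame_segment(genome.sequence, seg, fr)
        n_star = pep.count("*")
        if n_star and pep.endswith("*") and h.subject_interval[1] >= len(subject) - 1:
            n_star -= 1  # terminal stop aligned at/after the subject C-terminus
        stops += n_star

    merged_s = []
    for iv in sorted(h.subject_interval for h in all_hsps):
        if merged_s and iv[0] <= merged_s[-1][1]:
            merged_s[-1] = (merged_s[-1][0], max(merged_s[-1][1], iv[1]))
        else:
            merged_s.append(iv)
    coverage = sum(e - s for s, e in merged_s) / len(subject)

    return replace(
        call,
        segments=segments,
        frames=frames,
        evidence=all_hsps,
        subject_coverage=coverage,
        disruptions={"frameshifts": frameshifts, "premature_stops": stops,
                     "is_insertion": call.disruptions.get("is_insertion", False)},
    )


# ---------------------------------------------------------------------------
# merging / reconciliation


def _gap_intervals(segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    segs = sorted(segments)
    return [(a[1], b[0]) for a, b in zip(segs, segs[1:]) if b[0] > a[1]]


def _disjoint_segments(segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Clip small overlaps (frameshift junctions, TSDs) so segments can be
    written as a standards-compliant join()."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(segments):
        if out and s < out[-1][1]:
            s = out[-1][1]
        if e > s:
            out.append((s, e))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def merge_and_reconcile(
    calls: list[PseudogeneCall],
    original_annotation: AnnotationSet,
    genome: GenomeRecord,
    proteome: dict[str, str],
    is_copies: list[tuple[int, int]] | None = None,
    params: PipelineParams | None = None,
) -> ReconciledAnnotation:
    """Merging and elimination rules applied to reconstructed calls.

    (a) adjacent same-subject calls with compatible subject intervals and
        genomic distance <= merge_max_distance become one multi-segment
        pseudogene (coverage = union);
    (b) calls whose internal gap or merge junction spans a located IS copy
        are flagged ``is_insertion`` and the IS-spanning junction does not
        count as a frameshift;
    (c) an annotated gene covering < 90% of a subject whose remainder is
        covered by an adjacent call becomes a :class:`SplitRecord`; the call
        is removed from the pseudogene set (the paper's elimination of
        gene+pseudogene splits);
    (d) remaining calls are renumbered ps_0001... in genomic order.
    """
    params = params or PipelineParams()
    is_copies = sorted(is_copies or [])

    def spans_is(gap: tuple[int, int]) -> bool:
        for cs, ce in is_copies:
            if gap[0] - 50 <= cs and ce <= gap[1] + 50 and _overlap(gap, (cs, ce)) > 0.5 * (ce - cs):
                return True
        return False

    # --- (a) merge adjacent same-subject calls
    calls = sorted(calls, key=lambda c: (c.subject_id, c.start))
    merged: list[PseudogeneCall] = []
    for c in calls:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.subject_id == c.subject_id
            and prev.strand == c.strand
            and 0 <= c.start - prev.end <= params.merge_max_distance
        ):
            prev_u = prev.subject_union()
            c_u = c.subject_union()
            ov = sum(max(0, _overlap(a, b)) for a in prev_u for b in c_u)
            junction_is = spans_is((prev.end, c.start))
            # rule (b): rejoining across an IS insertion tolerates the larger
            # overlap produced by target-site duplication plus alignment slop
            allowed_ov = 30 if junction_is else params.chain_max_subject_overlap
            if ov <= allowed_ov:
                ev = prev.evidence + c.evidence
                segs = sorted(prev.segments + c.segments)
                frames_map = dict(zip(prev.segments, prev.frames))
                frames_map.update(zip(c.segments, c.frames))
                u = sorted(h.subject_interval for h in ev)
                mu = []
                for s, e in u:
                    if mu and s <= mu[-1][1]:
                        mu[-1] = (mu[-1][0], max(mu[-1][1], e))
                    else:
                        mu.append((s, e))
                cov = sum(e - s for s, e in mu) / len(proteome[prev.subject_id])
                fs = prev.disruptions["frameshifts"] + c.disruptions["frameshifts"]
                junction = (prev.end, c.start)
                if not spans_is(junction):
                    # junction between the two merged parts counts as a frame
                    # change when the flanking frames differ
                    f1 = frames_map[prev.segments[-1] if prev.strand == "+" else prev.segments[0]]
                    f2 = frames_map[c.segments[0] if c.strand == "+" else c.segments[-1]]
                    fs += 1 if f1 != f2 else 0
                merged[-1] = replace(
                    prev,
                    segments=segs,
                    frames=[frames_map[s] for s in segs],
                    evidence=ev,
                    subject_coverage=cov,
                    score=prev.score + c.score,
                    evalue=min(prev.evalue, c.evalue),
                    pass_found=min(prev.pass_found, c.pass_found),
                    disruptions={
                        "frameshifts": fs,
                        "premature_stops": prev.disruptions["premature_stops"]
                        + c.disruptions["premature_stops"],
                        "is_insertion": prev.disruptions["is_insertion"]
                        or c.disruptions["is_insertion"]
                        or spans_is(junction),
                    },
                )
                continue
        merged.append(replace(c, disruptions=dict(c.disruptions)))

    # --- (b) IS-insertion flag + frameshift correction on internal gaps
    for c in merged:
        if any(spans_is(gap) for gap in _gap_intervals(c.segments)):
            c.disruptions["is_insertion"] = True
        if not c.disruptions["is_insertion"]:
            # a short gene fragment beyond an adjacent IS copy is too small to
            # stand as its own call; rescue it across the element (the flank
            # search around located IS copies, as a per-call refinement)
            _rescue_across_is(c, genome, proteome, is_copies, params)
        if c.disruptions["is_insertion"]:
            # a frame change across the IS is an artefact of the insertion
            # length, not a frameshift mutation
            segs = sorted(zip(c.segments, c.frames))
            fs = 0
            for (s1, f1), (s2, f2) in zip(segs, segs[1:]):
                if f1 != f2 and not spans_is((s1[1], s2[0])):
                    fs += 1
            c.disruptions["frameshifts"] = fs

    # --- (c) split records against flanking annotated genes
    genes = [f for f in original_annotation.sorted_features() if f.kind == "gene"]
    splits: list[SplitRecord] = []
    final_calls: list[PseudogeneCall] = []
    for c in merged:
        subject = proteome[c.subject_id]
        split = None
        for g in genes:
            if g.strand != c.strand:
                continue
            if c.start - g.end > params.merge_max_distance and g.start - c.end > params.merge_max_distance:
                continue
            gap_ok = (0 <= c.start - g.end <= params.merge_max_distance) or (
                0 <= g.start - c.end <= params.merge_max_distance
            )
            if not gap_ok:
                continue
            gene_pep = _gene_peptide(g, genome)
            if not gene_pep:
                continue
            score, g_iv, s_iv, ident = local_align(gene_pep, subject, params.search)
            gene_cov = (s_iv[1] - s_iv[0]) / len(subject)
            if score < 40 or ident < 0.5 or gene_cov < 0.05 or gene_cov > 0.9:
                continue
            call_u = c.subject_union()
            ov = sum(max(0, _overlap((s_iv[0], s_iv[1]), u)) for u in call_u)
            if ov > 0.2 * len(subject):
                continue
            combined = gene_cov + c.subject_coverage
            if not (0.6 <= combined <= 1.05):
                continue
            gene_at_nterm = s_iv[0] <= min(u[0] for u in call_u)
            rel = "5P" if gene_at_nterm else "3P"
            combined_iv = (min(g.start, c.start), max(g.end, c.end))
            split = SplitRecord(
                combined_interval=combined_iv,
                gene_id=g.locus_tag,
                pseudogene_id="",
                subject_id=c.subject_id,
                gene_fraction=gene_cov,
                pseudogene_fraction=c.subject_coverage,
                relative_position=rel,
            )
            break
        if split is not None:
            splits.append(split)
        else:
            final_calls.append(c)

    # --- (d) renumber in genomic order and build the output annotation
    final_calls.sort(key=lambda c: (c.start, c.end))
    features = list(original_annotation.features)
    out_calls = []
    for i, c in enumerate(final_calls, 1):
        tag = f"ps_{i:04d}"
        d = c.disruptions
        disj = _disjoint_segments(c.segments)
        feat = Feature(
            locus_tag=tag,
            kind="pseudogene",
            strand=c.strand,
            segments=disj if c.strand == "+" else disj[::-1],
            qualifiers={
                "subject": c.subject_id,
                "coverage": f"{c.subject_coverage:.3f}",
                "frameshifts": str(d["frameshifts"]),
                "premature_stops": str(d["premature_stops"]),
                "is_insertion": "yes" if d["is_insertion"] else "no",
                "pass": str(c.pass_found),
            },
        )
        features.append(feat)
        out_calls.append(replace(c, locus_tag=tag))
    for i, sp in enumerate(splits, 1):
        sp.pseudogene_id = f"split_ps_{i:04d}"
    ann = AnnotationSet(
        original_annotation.genome_id, features,
        provenance=original_annotation.provenance + " + reconciled pseudogenes",
    )
    return ReconciledAnnotation(annotation=ann, calls=out_calls, splits=splits)


def _rescue_across_is(
    call: PseudogeneCall,
    genome: GenomeRecord,
    proteome: dict[str, str],
    is_copies: list[tuple[int, int]],
    params: PipelineParams,
) -> None:
    """Extend a call over an adjacent IS copy when the missing subject tail
    aligns immediately beyond the element; sets ``is_insertion`` in place."""
    subject = proteome[call.subject_id]
    union = call.subject_union()
    if not union:
        return
    missing_n = union[0][0]                 # uncovered N-terminal residues
    missing_c = len(subject) - union[-1][1]  # uncovered C-terminal residues
    L = len(genome.sequence)

    def try_side(terminal: str, aa_gap: int):
        if aa_gap < 3:
            return None
        # genomic side of the call where the missing terminus continues
        right_side = (call.strand == "+") == (terminal == "C")
        anchor = call.end if right_side else call.start
        for cs, ce in is_copies:
            # the call may stop short of the element or creep into it by a
            # trimmed junk tail; both count as adjacency
            near = (cs - 150 <= anchor <= cs + 150) if right_side else (ce - 150 <= anchor <= ce + 150)
            if not near:
                continue
            win_len = 3 * aa_gap + 120
            if right_side:
                gs, ge = ce, min(L, ce + win_len)
            else:
                gs, ge = max(0, cs - win_len), cs
            dna = genome.sequence[gs:ge]
            if call.strand == "-":
                dna = revcomp(dna)
            frag = (
                subject[: union[0][0]] if terminal == "N" else subject[union[-1][1] :]
            )
            best = None
            for off in range(3):
                sub = dna[off : off + 3 * ((len(dna) - off) // 3)]
                if len(sub) < 9:
                    continue
                pep = six_frame_translate(sub)[1]
                score, p_iv, f_iv, ident = local_align(frag, pep, params.search)
                if score >= max(params.rescue_min_score, int(1.2 * aa_gap)) and ident >= 0.5:
                    if best is None or score > best[0]:
                        best = (score, off, p_iv, f_iv)
            if best is None:
                continue
            score, off, p_iv, f_iv = best
            if (call.strand == "+") == right_side:
                q = (gs + off + 3 * f_iv[0], gs + off + 3 * f_iv[1])
            else:
                q = (ge - (off + 3 * f_iv[1]), ge - (off + 3 * f_iv[0]))
            base = union[-1][1] if terminal == "C" else 0
            s_iv = (base + p_iv[0], base + p_iv[1]) if terminal == "C" else (p_iv[0], p_iv[1])
            return HSP(
                query_interval=q,
                frame=_genome_frame(q, call.strand, L),
                subject_id=call.subject_id,
                subject_interval=s_iv,
                score=score,
                identity=1.0,
                evalue=math.inf,
            )
        return None

    added = False
    for terminal, gap in (("C", missing_c), ("N", missing_n)):
        h = try_side(terminal, gap)
        if h is None:
            continue
        call.evidence.append(h)
        call.segments = sorted(call.segments + [h.query_interval])
        call.frames = [
            _genome_frame(seg, call.strand, L) for seg in call.segments
        ]
        added = True
    if added:
        call.disruptions["is_insertion"] = True
        merged_u = call.subject_union()
        call.subject_coverage = sum(e - s for s, e in merged_u) / len(subject)


def _gene_peptide(g: Feature, genome: GenomeRecord) -> str:
    dna = g.extract(genome.sequence)
    n = 3 * (len(dna) // 3)
    if n < 30:
        return ""
    pep = six_frame_translate(dna[:n])[1]
    return pep.rstrip("*")


# ---------------------------------------------------------------------------


def run_two_pass(
    genome: GenomeRecord,
    original_annotation: AnnotationSet,
    primary_proteome: dict[str, str],
    extended_proteome: dict[str, str] | None = None,
    params: PipelineParams | None = None,
    is_copies: list[tuple[int, int]] | None = None,
) -> ReconciledAnnotation:
    """Full two-pass discovery: pass 1 against the primary proteome, pass 2
    over re-extracted intergenic space against the extended proteome, then
    reconciliation of the union."""
    params = params or PipelineParams()
    extended_proteome = extended_proteome or primary_proteome

    regions1 = extract_intergenic(original_annotation, genome, params)
    calls1 = detect_pass(regions1, genome, primary_proteome, params, pass_no=1,
                         is_copies=is_copies)
    calls1 = [reconstruct_model(c, genome, primary_proteome, params) for c in calls1]

    aug_features = list(original_annotation.features)
    for i, c in enumerate(calls1, 1):
        disj = _disjoint_segments(c.segments)
        aug_features.append(
            Feature(f"pass1_{i:04d}", "pseudogene", c.strand,
                    disj if c.strand == "+" else disj[::-1])
        )
    augmented = AnnotationSet(original_annotation.genome_id, aug_features)

    regions2 = extract_intergenic(augmented, genome, params)
    calls2 = detect_pass(regions2, genome, extended_proteome, params, pass_no=2,
                         is_copies=is_copies)
    calls2 = [reconstruct_model(c, genome, extended_proteome, params) for c in calls2]

    both = {**primary_proteome, **extended_proteome}
    return merge_and_reconcile(
        calls1 + calls2, original_annotation, genome, both, is_copies, params
    )


# ---------------------------------------------------------------------------
# reciprocal-best-match annotation transfer


def transfer_annotation(
    query_proteins: dict[str, str],
    reference_proteins: dict[str, str],
    reference_qualifiers: dict[str, dict[str, str]] | None = None,
    params: PipelineParams | None = None,
    min_alignment_frac: float = 0.8,
    min_identity: float = 0.3,
) -> tuple[dict[str, str], dict[str, dict[str, str]]]:
    """Orthology by reciprocal best match with coverage/identity cutoffs.

    A query/reference pair is declared orthologous iff each is the other's
    best local-alignment hit, the alignment covers >= 80% of the shorter
    sequence, and identity is >= 30%.  Qualifiers (product, gene, EC_number,
    functional_class) are copied onto matched queries.
    """
    if not query_proteins or not reference_proteins:
        raise ValueError("both protein sets must be non-empty")
    params = params or PipelineParams()
    reference_qualifiers = reference_qualifiers or {}

    def best_hits(a_set, b_set):
        out = {}
        for aid, aseq in a_set.items():
            scored = []
            for bid, bseq in b_set.items():
                score, a_iv, b_iv, ident = local_align(aseq, bseq, params.search)
                if score > 0:
                    scored.append((-score, bid, a_iv, b_iv, ident))
            if scored:
                scored.sort()
                out[aid] = scored[0]
        return out

    fwd = best_hits(query_proteins, reference_proteins)
    rev = best_hits(reference_proteins, query_proteins)
    orthologs: dict[str, str] = {}
    transferred: dict[str, dict[str, str]] = {}
    for qid, (_, rid, q_iv, r_iv, ident) in fwd.items():
        back = rev.get(rid)
        if back is None or back[1] != qid:
            continue
        shorter = min(len(query_proteins[qid]), len(reference_proteins[rid]))
        aln_len = max(q_iv[1] - q_iv[0], r_iv[1] - r_iv[0])
        if aln_len < min_alignment_frac * shorter or ident < min_identity:
            continue
        orthologs[qid] = rid
        quals = reference_qualifiers.get(rid, {})
        transferred[qid] = {
            k: v for k, v in quals.items()
            if k in ("product", "gene", "EC_number", "functional_class")
        }
    return orthologs, transferred


# ---------------------------------------------------------------------------
# tabular outputs


def write_calls_tsv(rec: ReconciledAnnotation, path):
    with open(path, "w") as fh:
        fh.write("locus\tsubject\tcoverage\tframeshifts\tpremature_stops\tis_insertion\tpass\tstart\tend\tstrand\n")
        for f in rec.annotation.sorted_features():
            if f.kind != "pseudogene":
                continue
            q = f.qualifiers
            fh.write(
                f"{f.locus_tag}\t{q.get('subject','')}\t{q.get('coverage','')}\t"
                f"{q.get('frameshifts','')}\t{q.get('premature_stops','')}\t"
                f"{q.get('is_insertion','')}\t{q.get('pass','')}\t{f.start + 1}\t{f.end}\t{f.strand}\n"
            )


def write_splits_tsv(rec: ReconciledAnnotation, path):
    with open(path, "w") as fh:
        fh.write("start\tend\tgene\tsubject\tgene_coverage_pct\tpseudogene_coverage_pct\tgene_position\tpseudogene_position\n")
        for sp in rec.splits:
            s, e = sp.combined_interval
            other = "3P" if sp.relative_position == "5P" else "5P"
            fh.write(
                f"{s + 1}\t{e}\t{sp.gene_id}\t{sp.subject_id}\t"
                f"{100 * sp.gene_fraction:.1f}\t{100 * sp.pseudogene_fraction:.1f}\t"
                f"{sp.relative_position}\t{other}\n"
            )
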