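"""Insertion-sequence family discovery and characterization.

Repeat families are found by genome self-comparison (exact k-mer anchors
merged into repeat intervals, clustered by sequence identity), a consensus is
built per family by center-star multiple alignment, terminal inverted repeats
(TIR) and target-site duplications (TSD) are detected on the consensus and
copy flanks, divergent or partial copies are recovered by re-scanning the
genome with the consensus, per-copy transposase functionality is classified
from the alignment slice over the transposase ORF, and the family table
reports pairwise-deletion p-distance statistics, genome fraction and IS load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import edlib
import numpy as np
from Bio import Align

from .io_formats import GenomeRecord, revcomp
from .translated_search import SearchParams, six_frame_translate


@dataclass(frozen=True)
class ISParams:
    min_repeat_len: int = 500
    flank_len: int = 100
    cluster_min_identity: float = 0.80
    complete_min_frac: float = 0.95
    tir_min_len: int = 8
    tir_max_mismatch_per10: int = 1
    tsd_max_len: int = 15
    anchor_word_len: int = 21
    scan_min_len: int = 50
    scan_min_identity: float = 0.60
    min_transposase_orf: int = 300  # nt

    def __post_init__(self):
        if not (0 < self.cluster_min_identity <= 1 and 0 < self.complete_min_frac <= 1):
            raise ValueError("identity fractions must be in (0,1]")
        if min(self.min_repeat_len, self.flank_len, self.tir_min_len,
               self.anchor_word_len) <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class ISCopy:
    interval: tuple[int, int]
    strand: str
    completeness: str = "complete"          # complete | partial
    transposase_status: str = "absent"      # functional | defective | absent
    p_to_consensus: float = 0.0
    aligned_len: int = 0
    identity: float = 0.0

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class ISFamily:
    family_id: str
    consensus: str = ""
    copies: list[ISCopy] = field(default_factory=list)
    tir: dict | None = None                 # {"length", "left_seq", "right_seq", "internal"}
    tsd_len: int | None = None
    transposase_interval: tuple[int, int] | None = None
    msa: list[str] = field(default_factory=list)       # rows parallel to copies
    stats: dict = field(default_factory=dict)


def _round_half_up(x: float, nd: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * nd), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# repeat discovery


def _edlib_identity(a: str, b: str, mode: str = "NW") -> float:
    r = edlib.align(a, b, mode=mode)
    return 1.0 - r["editDistance"] / max(len(a), len(b))


def find_repeat_families(genome: GenomeRecord, params: ISParams | None = None) -> list[ISFamily]:
    """Candidate repeat families from exact-word self-comparison.

    Genome positions covered by a k-mer occurring more than once (strands
    collapsed to a canonical form) are merged into intervals; intervals of at
    least ``min_repeat_len`` are clustered single-linkage against a family
    representative at ``cluster_min_identity`` (both orientations tried);
    copies are strand-normalized to the representative's orientation.
    """
    params = params or ISParams()
    seq = genome.sequence
    k = params.anchor_word_len
    if len(seq) < 2 * params.min_repeat_len:
        return []
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        c = min(w, revcomp(w))
        counts[c] = counts.get(c, 0) + 1
    covered = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if counts[min(w, revcomp(w))] > 1 and "N" not in w:
            covered.append(i)
    intervals: list[tuple[int, int]] = []
    for i in covered:
        if intervals and i <= intervals[-1][1] + 100:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], i + k))
        else:
            intervals.append((i, i + k))
    intervals = [iv for iv in intervals if iv[1] - iv[0] >= params.min_repeat_len]

    families: list[ISFamily] = []
    for iv in intervals:
        sub = seq[iv[0] : iv[1]]
        placed = False
        for fam in families:
            rep = fam.stats["representative"]
            fwd = _edlib_identity(sub, rep, "HW" if len(sub) <= len(rep) else "NW")
            rev = _edlib_identity(revcomp(sub), rep, "HW" if len(sub) <= len(rep) else "NW")
            if max(fwd, rev) >= params.cluster_min_identity:
                strand = "+" if fwd >= rev else "-"
                fam.copies.append(ISCopy(interval=iv, strand=strand))
                if iv[1] - iv[0] > len(rep):
                    fam.stats["representative"] = sub if strand == "+" else revcomp(sub)
                placed = True
                break
        if not placed:
            fam = ISFamily(family_id=f"ISF{len(families) + 1}")
            fam.copies.append(ISCopy(interval=iv, strand="+"))
            fam.stats["representative"] = sub
            families.append(fam)
    return families


# ---------------------------------------------------------------------------
# consensus via center-star MSA


def _pairwise_rows(query: str, center: str) -> tuple[str, str]:
    """Global alignment rows (query_row, center_row) from an edlib path."""
    r = edlib.align(query, center, task="path", mode="NW")
    qi = ci = 0
    q_row = []
    c_row = []
    num = ""
    for ch in r["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            q_row.append(query[qi : qi + n])
            c_row.append(center[ci : ci + n])
            qi += n
            ci += n
        elif ch == "I":  # extra bases in query -> gap in center
            q_row.append(query[qi : qi + n])
            c_row.append("-" * n)
            qi += n
        elif ch == "D":  # extra bases in center -> gap in query
            q_row.append("-" * n)
            c_row.append(center[ci : ci + n])
            ci += n
    return "".join(q_row), "".join(c_row)


def build_consensus(copy_sequences: list[str]) -> tuple[str, list[str]]:
    """Center-star MSA + column-majority consensus.

    Center = the copy with the highest summed pairwise identity.  Consensus:
    majority base per column, ties -> N, gap-majority columns dropped.
    Returns (consensus, msa_rows) with rows parallel to the input order.
    """
    if not copy_sequences:
        raise ValueError("no copies")
    if len(copy_sequences) == 1:
        return copy_sequences[0], [copy_sequences[0]]
    n = len(copy_sequences)
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            ident = _edlib_identity(copy_sequences[i], copy_sequences[j])
            sums[i] += ident
            sums[j] += ident
    center_i = max(range(n), key=lambda i: sums[i])
    center = copy_sequences[center_i]

    aligned = []
    for s in copy_sequences:
        if s is center:
            aligned.append((center, center))
        else:
            aligned.append(_pairwise_rows(s, center))

    # merge on center coordinates: max insertion run after each center position
    ins_after = [0] * (len(center) + 1)
    for q_row, c_row in aligned:
        pos = 0
        run = 0
        for qc, cc in zip(q_row, c_row):
            if cc == "-":
                run += 1
            else:
                ins_after[pos] = max(ins_after[pos], run)
                run = 0
                pos += 1
        ins_after[pos] = max(ins_after[pos], run)

    def project(q_row: str, c_row: str) -> str:
        out = []
        pos = 0
        pending = []
        for qc, cc in zip(q_row, c_row):
            if cc == "-":
                pending.append(qc)
            else:
                out.append(pending + ["-"] * (ins_after[pos] - len(pending)))
                out.append([qc])
                pending = []
                pos += 1
        out.append(pending + ["-"] * (ins_after[pos] - len(pending)))
        return "".join("".join(x) for x in out)

    rows = [project(q, c) for q, c in aligned]

    cons = []
    width = len(rows[0])
    for col in range(width):
        column = [r[col] for r in rows]
        gaps = column.count("-")
        if gaps * 2 > len(column):
            continue
        best, tie = None, False
        for b in "ACGT":
            c = column.count(b)
            if best is None or c > best[1]:
                best, tie = (b, c), False
            elif c == best[1]:
                tie = True
        cons.append("N" if tie else best[0])
    return "".join(cons), rows


# ---------------------------------------------------------------------------
# TIR / TSD


def _tir_arm(consensus: str, params: ISParams, left_off: int = 0, right_off: int = 0):
    """Greedy arm extension from given offsets; trailing mismatches trimmed."""
    n = len(consensus)
    max_arm = min(60, (n - left_off - right_off) // 2)
    mismatch_at = []
    L = 0
    mism = 0
    while L < max_arm:
        a = consensus[left_off + L]
        b = consensus[n - 1 - right_off - L]
        ok = a in "ACGT" and b in "ACGT" and a == revcomp(b)
        if not ok:
            if (mism + 1) * 10 > params.tir_max_mismatch_per10 * (L + 1):
                break
            mism += 1
            mismatch_at.append(L)
        L += 1
    while L > 0 and (L - 1) in mismatch_at:
        L -= 1
    return L


def detect_tir(consensus: str, params: ISParams | None = None) -> dict | None:
    """Terminal inverted repeat of the consensus, or an internal IR near the
    termini (within 50 bp) when the true termini carry none."""
    params = params or ISParams()
    if len(consensus) < 2 * params.tir_min_len:
        return None
    L = _tir_arm(consensus, params)
    if L >= params.tir_min_len:
        return {
            "length": L,
            "left_seq": consensus[:L],
            "right_seq": consensus[-L:],
            "internal": False,
            "offsets": (0, 0),
        }
    best = None
    for lo in range(0, 51):
        for ro in range(0, 51):
            if lo == ro == 0:
                continue
            L = _tir_arm(consensus, params, lo, ro)
            if L >= params.tir_min_len and (best is None or L > best["length"]):
                n = len(consensus)
                best = {
                    "length": L,
                    "left_seq": consensus[lo : lo + L],
                    "right_seq": consensus[n - ro - L : n - ro],
                    "internal": True,
                    "offsets": (lo, ro),
                }
    return best


def detect_tsd(copies_with_flanks: list[tuple[str, str]], params: ISParams | None = None) -> int | None:
    """Family TSD length from per-copy flanks.

    Per copy: longest exact match between the upstream suffix and the
    downstream prefix (bounded by ``tsd_max_len``).  The family value is the
    modal per-copy length when supported by at least half of the copies;
    mode 0 (or no majority) means not-detected.
    """
    params = params or ISParams()
    if not copies_with_flanks:
        return None
    lengths = []
    for up, down in copies_with_flanks:
        L = 0
        for cand in range(min(params.tsd_max_len, len(up), len(down)), 0, -1):
            if up[-cand:] == down[:cand]:
                L = cand
                break
        lengths.append(L)
    vals, counts = np.unique(lengths, return_counts=True)
    order = sorted(zip(-counts, vals))
    mode_count, mode = -order[0][0], order[0][1]
    if mode == 0 or mode_count * 2 < len(lengths):
        return None
    return int(mode)


# ---------------------------------------------------------------------------
# copy scanning

_DNA_ALIGNER = None


def _dna_aligner():
    global _DNA_ALIGNER
    if _DNA_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -10
        a.extend_gap_score = -2
        _DNA_ALIGNER = a
    return _DNA_ALIGNER


def scan_copies(genome: GenomeRecord, consensus: str, params: ISParams | None = None) -> list[ISCopy]:
    """Locate complete, partial and divergent copies of a consensus.

    Exact 15-mer seeds of the consensus are clustered into candidate genomic
    windows; each window is locally aligned to the consensus on the seeded
    strand.  Hits of >= ``scan_min_len`` aligned nt and >= 60% identity
    become copies; completeness requires >= ``complete_min_frac`` of the
    consensus; p_to_consensus is differences/compared-columns with gapped
    columns excluded (pairwise deletion).
    """
    params = params or ISParams()
    seq = genome.sequence
    k = 15
    words: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        words.setdefault(consensus[i : i + k], []).append(i)
    rc_cons = revcomp(consensus)
    rc_words: dict[str, list[int]] = {}
    for i in range(len(rc_cons) - k + 1):
        rc_words.setdefault(rc_cons[i : i + k], []).append(i)

    hits: list[tuple[int, str]] = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w in words:
            hits.append((i, "+"))
        elif w in rc_words:
            hits.append((i, "-"))
    clusters: list[list[tuple[int, str]]] = []
    for pos, strand in hits:
        if clusters and pos - clusters[-1][-1][0] <= 300:
            clusters[-1].append((pos, strand))
        else:
            clusters.append([(pos, strand)])

    aligner = _dna_aligner()
    copies = []
    for cl in clusters:
        lo = max(0, cl[0][0] - 150)
        hi = min(len(seq), cl[-1][0] + k + 150)
        strand = "+" if sum(1 for _, s in cl if s == "+") >= len(cl) / 2 else "-"
        window = seq[lo:hi]
        target = window if strand == "+" else revcomp(window)
        score = aligner.score(consensus, target)
        if score <= 0:
            continue
        aln = aligner.align(consensus, target)[0]
        bc, bt = aln.aligned
        aligned_cols = sum(e - s for s, e in bc)
        if aligned_cols < params.scan_min_len:
            continue
        ident = 0
        diffs = 0
        for (c0, c1), (t0, t1) in zip(bc, bt):
            for i in range(c1 - c0):
                if consensus[c0 + i] == target[t0 + i]:
                    ident += 1
                else:
                    diffs += 1
        if ident / aligned_cols < params.scan_min_identity:
            continue
        t_iv = (int(bt[0][0]), int(bt[-1][1]))
        if strand == "+":
            g_iv = (lo + t_iv[0], lo + t_iv[1])
        else:
            g_iv = (hi - t_iv[1], hi - t_iv[0])
        copies.append(
            ISCopy(
                interval=g_iv,
                strand=strand,
                completeness="complete"
                if aligned_cols >= params.complete_min_frac * len(consensus)
                else "partial",
                p_to_consensus=diffs / aligned_cols,
                aligned_len=aligned_cols,
                identity=ident / aligned_cols,
            )
        )
    copies.sort(key=lambda c: c.interval)
    # merge overlapping duplicates (seed clusters can straddle)
    out: list[ISCopy] = []
    for c in copies:
        if out and c.interval[0] < out[-1].interval[1]:
            if c.aligned_len > out[-1].aligned_len:
                out[-1] = c
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# p-distance


def p_distance_matrix(aligned_copies: list[str]) -> tuple[np.ndarray, dict]:
    """Pairwise p-distances over one multiple alignment, pairwise deletion.

    Sites where either sequence has a gap are excluded per pair; a pair with
    zero comparable sites gets NaN and is excluded from the summary.
    """
    n = len(aligned_copies)
    if n == 0:
        return np.zeros((0, 0)), {"min": None, "max": None, "mean": None}
    arr = np.array([list(s) for s in aligned_copies])
    gap = arr == "-"
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                mat[i, j] = mat[j, i] = np.nan
                continue
            p = float((arr[i][ok] != arr[j][ok]).sum()) / m
            mat[i, j] = mat[j, i] = p
            vals.append(p)
    summary = {
        "min": min(vals) if vals else None,
        "max": max(vals) if vals else None,
        "mean": sum(vals) / len(vals) if vals else None,
    }
    return mat, summary


# ---------------------------------------------------------------------------
# transposase classification


def find_transposase_orf(consensus: str, min_len: int = 300) -> tuple[tuple[int, int], str] | None:
    """Longest ORF >= min_len nt on the consensus (both strands).

    Returns ``((start, end), strand)`` with the interval in consensus
    forward coordinates.
    """
    best = None
    n = len(consensus)
    for strand in "+-":
        s = consensus if strand == "+" else revcomp(consensus)
        for off in range(3):
            start = None
            for i in range(off, n - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in ("TAA", "TAG", "TGA") and start is not None:
                    length = i + 3 - start
                    if length >= min_len and (best is None or length > best[0]):
                        if strand == "+":
                            iv = (start, i + 3)
                        else:
                            iv = (n - (i + 3), n - start)
                        best = (length, iv, strand)
                    start = None
    return (best[1], best[2]) if best else None


def _slice_alignment(copy_row: str, cons_row: str, interval: tuple[int, int]):
    """Copy-row columns spanning a consensus interval (consensus coords)."""
    out_c = []
    out_q = []
    pos = 0
    for qc, cc in zip(copy_row, cons_row):
        if interval[0] <= pos < interval[1] and (cc != "-" or interval[0] < pos):
            out_q.append(qc)
            out_c.append(cc)
        if cc != "-":
            pos += 1
        if pos >= interval[1]:
            break
    return "".join(out_q), "".join(out_c)


def classify_transposase(
    consensus: str,
    copy_rows: list[str],
    cons_row: str | None = None,
    transposase_orf: tuple[tuple[int, int], str] | None = None,
    params: ISParams | None = None,
) -> list[str]:
    """Per-copy transposase status from MSA slices over the transposase ORF.

    absent: < 50% of the interval present in the copy; defective: internal
    stop in the transposase frame, or any indel run not a multiple of three,
    or a net indel sum not a multiple of three; else functional (amino-acid
    substitutions and in-frame indels are tolerated).
    """
    params = params or ISParams()
    if transposase_orf is None:
        transposase_orf = find_transposase_orf(consensus, params.min_transposase_orf)
    if transposase_orf is None:
        return ["absent"] * len(copy_rows)
    transposase_interval, orf_strand = transposase_orf
    cons_row = cons_row if cons_row is not None else consensus
    statuses = []
    span = transposase_interval[1] - transposase_interval[0]
    for row in copy_rows:
        q, c = _slice_alignment(row, cons_row, transposase_interval)
        present = sum(1 for qc, cc in zip(q, c) if qc != "-" and cc != "-")
        if present < 0.5 * span:
            statuses.append("absent")
            continue
        # indel runs within the slice
        bad_indel = False
        net = 0
        for row_pair, sign in ((q, -1), (c, +1)):
            run = 0
            for ch in row_pair:
                if ch == "-":
                    run += 1
                else:
                    if run:
                        net += sign * run
                        if run % 3:
                            bad_indel = True
                        run = 0
            if run:
                net += sign * run
                if run % 3:
                    bad_indel = True
        if bad_indel or net % 3:
            statuses.append("defective")
            continue
        degapped = q.replace("-", "")
        if orf_strand == "-":
            degapped = revcomp(degapped)
        pep = six_frame_translate(degapped[: 3 * (len(degapped) // 3)])[1]
        if "*" in pep[:-1]:
            statuses.append("defective")
        else:
            statuses.append("functional")
    return statuses


def _trim_weak_ends(consensus: str, copy_seqs: list[str], min_support: float = 0.85) -> str:
    """Drop terminal consensus columns matched by fewer than ``min_support``
    of the copies."""
    if not copy_seqs:
        return consensus
    width = len(consensus)
    match = np.zeros(width)
    for s in copy_seqs:
        q_row, c_row = _pairwise_rows(s, consensus)
        pos = 0
        for qc, cc in zip(q_row, c_row):
            if cc != "-":
                if qc == cc:
                    match[pos] += 1
                pos += 1
    frac = match / len(copy_seqs)
    lo, hi = 0, width
    while lo < hi and frac[lo] < min_support:
        lo += 1
    while hi > lo and frac[hi - 1] < min_support:
        hi -= 1
    return consensus[lo:hi]


# ---------------------------------------------------------------------------
# orchestration + summary


def characterize_family(
    genome: GenomeRecord, fam: ISFamily, params: ISParams | None = None
) -> ISFamily:
    """Build consensus, rescan for all copies, detect TIR/TSD, classify
    transposases and fill family statistics."""
    params = params or ISParams()
    seq = genome.sequence

    def extract(copies):
        out = []
        for c in copies:
            s = seq[c.interval[0] : c.interval[1]]
            out.append(s if c.strand == "+" else revcomp(s))
        return out

    # round 1: provisional consensus from raw repeat intervals (their ends
    # creep 1-3 bp into the flanks where flank bases match by chance)
    cons1, _ = build_consensus(extract(fam.copies))
    copies1 = scan_copies(genome, cons1, params)
    # round 2: rebuild from alignment-refined boundaries, then trim terminal
    # columns with weak match support — boundary creep into the flanks is
    # only chance-supported, while true element termini (TIRs) are conserved
    full = [c for c in copies1 if c.completeness == "complete"] or copies1
    consensus, _ = build_consensus(extract(full))
    consensus = _trim_weak_ends(consensus, extract(full))
    fam.consensus = consensus
    fam.copies = scan_copies(genome, consensus, params)

    # oriented copy sequences + MSA against the consensus
    oriented = []
    for c in fam.copies:
        s = seq[c.interval[0] : c.interval[1]]
        oriented.append(s if c.strand == "+" else revcomp(s))
    rows = []
    for s in oriented:
        q_row, c_row = _pairwise_rows(s, consensus)
        rows.append((q_row, c_row))
    fam.msa = [q for q, _ in rows]

    fam.tir = detect_tir(consensus, params)
    flanks = []
    for c in fam.copies:
        if c.completeness != "complete":
            continue
        lo, hi = c.interval
        up = seq[max(0, lo - params.flank_len) : lo]
        down = seq[hi : hi + params.flank_len]
        if c.strand == "-":
            up, down = revcomp(down), revcomp(up)
        flanks.append((up, down))
    fam.tsd_len = detect_tsd(flanks, params) if flanks else None

    orf = find_transposase_orf(consensus, params.min_transposase_orf)
    fam.transposase_interval = orf[0] if orf else None
    for c, (q_row, c_row) in zip(fam.copies, rows):
        c.transposase_status = classify_transposase(
            consensus, [q_row], cons_row=c_row,
            transposase_orf=orf, params=params,
        )[0]

    # pairwise p-distance over copies embedded in consensus coordinates
    _, proj_rows = _project_on_consensus(consensus, rows)
    if proj_rows:
        _, summary = p_distance_matrix(proj_rows)
    else:
        summary = {"min": None, "max": None, "mean": None}

    n_complete = sum(1 for c in fam.copies if c.completeness == "complete")
    n_partial = len(fam.copies) - n_complete
    fam.stats = {
        "consensus_len": len(consensus),
        "gc_pct": _round_half_up(
            100 * sum(consensus.count(b) for b in "GC") / max(1, len(consensus)), 1
        ),
        "n_orfs": 1 if fam.transposase_interval else 0,
        "tir_len": fam.tir["length"] if fam.tir else None,
        "tsd_len": fam.tsd_len,
        "n_complete": n_complete,
        "n_partial": n_partial,
        "n_functional_transposase": sum(
            1 for c in fam.copies if c.transposase_status == "functional"
        ),
        "p_min": summary["min"],
        "p_max": summary["max"],
        "p_mean": summary["mean"],
        "total_length_nt": sum(c.length for c in fam.copies),
    }
    return fam


def _project_on_consensus(consensus: str, rows: list[tuple[str, str]]):
    """Project per-pair alignments onto plain consensus coordinates (copy
    insertions relative to the consensus are dropped), giving equal-length
    rows usable for pairwise-deletion distances."""
    proj = []
    for q_row, c_row in rows:
        out = []
        for qc, cc in zip(q_row, c_row):
            if cc != "-":
                out.append(qc)
        s = "".join(out)
        if len(s) < len(consensus):
            s = s + "-" * (len(consensus) - len(s))
        proj.append(s)
    return consensus, proj


def find_is_families(genome: GenomeRecord, params: ISParams | None = None) -> list[ISFamily]:
    """Full IS characterization: discovery + per-family characterization."""
    params = params or ISParams()
    fams = find_repeat_families(genome, params)
    out = []
    for fam in fams:
        if len(fam.copies) < 2:
            continue
        out.append(characterize_family(genome, fam, params))
    return out


def is_disrupted_genes(
    genome: GenomeRecord,
    is_copies: list[ISCopy],
    proteome: dict[str, str],
    search_params: SearchParams | None = None,
    flank: int = 1000,
) -> list[dict]:
    """Genes disrupted by an IS insertion: both 1-kb flanks of a copy hit the
    same subject, same strand, subject intervals in insertion-consistent
    order with <= 30 aa overlap."""
    from .translated_search import ProteomeIndex, search_region

    search_params = search_params or SearchParams()
    index = ProteomeIndex(proteome, search_params.seed_word_len)
    db_len = sum(len(s) for s in proteome.values())
    out = []
    seq = genome.sequence
    for copy in is_copies:
        lo, hi = copy.interval
        left = seq[max(0, lo - flank) : lo]
        right = seq[hi : min(len(seq), hi + flank)]
        if len(left) < 30 or len(right) < 30:
            continue
        h_left = search_region(left, max(0, lo - flank), proteome, search_params,
                               index=index, db_len_aa=db_len)
        h_right = search_region(right, hi, proteome, search_params,
                                index=index, db_len_aa=db_len)
        best = None
        for hl in h_left:
            for hr in h_right:
                if hl.subject_id != hr.subject_id or hl.strand != hr.strand:
                    continue
                if hl.strand == "+":
                    first, second = hl, hr
                else:
                    first, second = hr, hl
                ov = first.subject_interval[1] - second.subject_interval[0]
                if ov > 30 or second.subject_interval[1] <= first.subject_interval[1]:
                    continue
                cov = (
                    (first.subject_interval[1] - first.subject_interval[0])
                    + (second.subject_interval[1] - second.subject_interval[0])
                ) / len(proteome[hl.subject_id])
                score = hl.score + hr.score
                if best is None or score > best["score"]:
                    best = {
                        "copy_interval": copy.interval,
                        "subject_id": hl.subject_id,
                        "strand": hl.strand,
                        "combined_coverage": cov,
                        "score": score,
                    }
        if best:
            out.append(best)
    return out


def family_summary(
    families: list[ISFamily],
    genome_len: int,
    extra_copy_count: int = 0,
    extra_length_nt: int = 0,
) -> dict:
    """Family table plus genome-wide IS statistics.

    ``genome_fraction_pct`` = 100 * total IS nt / genome length (2 dp);
    ``load_per_kb`` = copies / (genome length / 1000) (3 dp).  Single-copy
    elements found outside multi-copy families enter through the ``extra_*``
    arguments.
    """
    rows = []
    total_nt = extra_length_nt
    total_copies = extra_copy_count
    for fam in families:
        st = fam.stats
        rows.append({"family": fam.family_id, **st})
        total_nt += st["total_length_nt"]
        total_copies += st["n_complete"] + st["n_partial"]
    return {
        "families": rows,
        "total_length_nt": total_nt,
        "total_copies": total_copies,
        "genome_fraction_pct": _round_half_up(100.0 * total_nt / genome_len, 2),
        "load_per_kb": _round_half_up(total_copies / (genome_len / 1000.0), 3),
    }
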