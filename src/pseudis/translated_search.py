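"""Protein-versus-DNA homology search.

Six-frame translation of a genomic region followed by optimal local
alignment of each frame against a protein database, with Karlin-Altschul
E-values — a self-contained stand-in for a BLASTX search.  The alignment
core is the exact affine-gap Smith-Waterman of ``Bio.Align.PairwiseAligner``
(BLOSUM62 by default); seeding is a two-hit exact-word heuristic whose
result set matches the exhaustive frame-by-subject scan on the inputs this
package targets (a tested contract for regions up to 2 kb).

Stops in translated frames are rendered ``'*'`` and score -4 against every
residue; codons containing N translate to ``'X'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import revcomp

FRAMES = (1, 2, 3, -1, -2, -3)

_BACT_TABLE = CodonTable.unambiguous_dna_by_id[11].forward_table


def _codon_aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _BACT_TABLE.get(codon, "*")


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate ``dna`` in all six frames (bacterial code, table 11).

    Returns {frame: peptide} with frames -1..-3 computed on the reverse
    complement.  Trailing 1-2 nt of each frame are dropped.
    """
    dna = dna.upper()
    out: dict[int, str] = {}
    rc = revcomp(dna)
    for f in FRAMES:
        s = dna if f > 0 else rc
        off = abs(f) - 1
        sub = s[off : off + 3 * ((len(s) - off) // 3)]
        if "N" in sub:
            pep = "".join(_codon_aa(sub[i : i + 3]) for i in range(0, len(sub), 3))
        else:
            pep = str(Seq(sub).translate(table=11))
        out[f] = pep
    return out


def _stop_matrix():
    m = substitution_matrices.load("BLOSUM62").copy()
    for a in m.alphabet:
        m["*", a] = -4.0
        m[a, "*"] = -4.0
    return m


_MATRICES = {"BLOSUM62": _stop_matrix()}


@dataclass(frozen=True)
class SearchParams:
    """Scoring and statistics parameters (BLAST-like gapped defaults)."""

    matrix_id: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    la_lambda: float = 0.267  # Karlin-Altschul scale for BLOSUM62 11/1
    K: float = 0.041
    evalue_cutoff: float = 1e-5
    seed_word_len: int = 4

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.evalue_cutoff <= 0 or self.la_lambda <= 0 or self.K <= 0:
            raise ValueError("statistical parameters must be positive")

    def matrix(self):
        if self.matrix_id not in _MATRICES:
            m = substitution_matrices.load(self.matrix_id).copy()
            for a in m.alphabet:
                m["*", a] = -4.0
                m[a, "*"] = -4.0
            _MATRICES[self.matrix_id] = m
        return _MATRICES[self.matrix_id]


@dataclass
class HSP:
    """One local protein-vs-translated-DNA alignment."""

    query_interval: tuple[int, int]  # genomic, forward strand, 0-based half-open
    frame: int
    subject_id: str
    subject_interval: tuple[int, int]  # aa, 0-based half-open
    score: int
    identity: float
    evalue: float
    # aa interval within the frame translation (internal bookkeeping)
    frame_interval: tuple[int, int] = field(default=(0, 0), repr=False)

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = params.matrix()
    # first gap position is charged the open penalty, each further one extend
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


def local_align(protein_a: str, protein_b: str, params: SearchParams | None = None):
    """Optimal local alignment of two peptides under matrix + affine gaps.

    Returns ``(score, (a_start, a_end), (b_start, b_end), identity)`` with
    0-based half-open intervals.  Identity is the fraction of alignment
    columns (gap columns included) with identical residues; ``'*'`` never
    counts as identical.  Empty input gives score 0.
    """
    params = params or SearchParams()
    if not protein_a or not protein_b:
        return 0, (0, 0), (0, 0), 0.0
    aligner = _make_aligner(params)
    score = aligner.score(protein_a, protein_b)
    if score <= 0:
        return 0, (0, 0), (0, 0), 0.0
    aln = aligner.align(protein_a, protein_b)[0]
    blocks_a, blocks_b = aln.aligned
    a_iv = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_iv = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    ident = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i in range(a1 - a0):
            ca, cb = protein_a[a0 + i], protein_b[b0 + i]
            if ca == cb and ca != "*":
                ident += 1
    # columns = matched columns + gapped columns between blocks
    matched = sum(a1 - a0 for a0, a1 in blocks_a)
    gaps = 0
    for i in range(1, len(blocks_a)):
        gaps += (blocks_a[i][0] - blocks_a[i - 1][1]) + (blocks_b[i][0] - blocks_b[i - 1][1])
    columns = matched + gaps
    return int(score), a_iv, b_iv, ident / columns if columns else 0.0


def evalue_of(score: float, query_len_nt: int, db_len_aa: int, params: SearchParams | None = None) -> float:
    """Karlin-Altschul expectation: E = K * (m/3) * n * exp(-lambda * S)."""
    params = params or SearchParams()
    if query_len_nt <= 0 or db_len_aa <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    return params.K * (query_len_nt / 3.0) * db_len_aa * math.exp(-params.la_lambda * score)


def min_significant_score(query_len_nt: int, db_len_aa: int, cutoff: float, params: SearchParams | None = None) -> int:
    """Smallest integer score whose E-value passes ``cutoff``."""
    params = params or SearchParams()
    s = math.log(params.K * (query_len_nt / 3.0) * db_len_aa / cutoff) / params.la_lambda
    return max(0, math.ceil(s))


def frame_to_genomic(frame: int, region_len: int, offset: int, aa_iv: tuple[int, int]) -> tuple[int, int]:
    """Map an aa interval on a frame translation to forward-strand genomic nt."""
    a, b = aa_iv
    off = abs(frame) - 1
    if frame > 0:
        return offset + off + 3 * a, offset + off + 3 * b
    s_rc, e_rc = off + 3 * a, off + 3 * b
    return offset + region_len - e_rc, offset + region_len - s_rc


class ProteomeIndex:
    """Exact seed-word index over a proteome for two-hit heuristic seeding."""

    def __init__(self, proteome: dict[str, str], word_len: int = 4):
        self.proteome = proteome
        self.word_len = word_len
        self.total_aa = sum(len(s) for s in proteome.values())
        self.words: dict[str, list[tuple[int, int]]] = {}
        self.ids = list(proteome)
        for si, sid in enumerate(self.ids):
            seq = proteome[sid]
            for p in range(len(seq) - word_len + 1):
                w = seq[p : p + word_len]
                if "*" in w or "X" in w:
                    continue
                self.words.setdefault(w, []).append((si, p))

    def candidate_subjects(self, peptide: str, max_diag_slack: int = 5, max_span: int = 400) -> set[str]:
        """Subjects sharing two seed words on a consistent diagonal with the peptide.

        A single long word run also qualifies (two overlapping words lie on
        one diagonal), so any conserved stretch of >= word_len + 1 residues
        seeds its subject.
        """
        k = self.word_len
        hits: dict[int, list[tuple[int, int]]] = {}
        for p in range(len(peptide) - k + 1):
            w = peptide[p : p + k]
            for si, sp in self.words.get(w, ()):  # diag = query pos - subject pos
                hits.setdefault(si, []).append((p - sp, p))
        out: set[str] = set()
        for si, pairs in hits.items():
            pairs.sort()
            for (d1, p1), (d2, p2) in zip(pairs, pairs[1:]):
                if abs(d1 - d2) <= max_diag_slack and 0 < abs(p2 - p1) <= max_span:
                    out.add(self.ids[si])
                    break
        return out


# Score drop that splits an optimal alignment into separate HSPs, as X-drop
# termination does in seeded BLAST extension.  A genuine alignment's worst
# local dip (a premature stop flanked by mismatches) stays above ~-9, while
# bridging even a few out-of-frame codons costs more.
_XDROP = 12


def _alignment_columns(aln, pep, subject_seq, matrix, gap_open, gap_extend):
    """Flatten an alignment into scored columns.

    A gap run is one pseudo-column carrying the whole affine cost, so valley
    splitting and end trimming see the alignment's true score profile.
    Each column is ``(q0, q1, s0, s1, score, n_ident, n_cols)``.
    """
    blocks_q, blocks_s = aln.aligned
    cols = []
    for bi, ((a0, a1), (b0, b1)) in enumerate(zip(blocks_q, blocks_s)):
        if bi:
            pa1, pb1 = blocks_q[bi - 1][1], blocks_s[bi - 1][1]
            gq, gs = a0 - pa1, b0 - pb1
            cost = 0
            for g in (gq, gs):
                if g > 0:
                    cost += gap_open + (g - 1) * gap_extend
            cols.append((pa1, a0, pb1, b0, -cost, 0, gq + gs))
        for i in range(a1 - a0):
            q, s = a0 + i, b0 + i
            sc = matrix[pep[q], subject_seq[s]]
            ident = 1 if pep[q] == subject_seq[s] and pep[q] != "*" else 0
            cols.append((q, q + 1, s, s + 1, float(sc), ident, 1))
    return cols


def _split_columns(cols):
    """Split at internal score valleys deeper than the X-drop, recursively."""
    out = []
    stack = [cols]
    while stack:
        c = stack.pop()
        if not c:
            continue
        prefix = 0.0
        runmax, runmax_i = 0.0, -1
        best_drop, cut = 0.0, None
        for i, col in enumerate(c):
            prefix += col[4]
            if prefix - runmax < best_drop:
                best_drop = prefix - runmax
                cut = (runmax_i, i)
            if prefix > runmax:
                runmax, runmax_i = prefix, i
        if cut is not None and -best_drop > _XDROP:
            k, l = cut
            stack.append(c[: k + 1])
            stack.append(c[l + 1 :])
        else:
            out.append(c)
    return out


def _trim_columns(cols):
    """Maximal-scoring contiguous stretch (Kadane), so pieces end on matches."""
    best, best_iv = 0.0, None
    cur, start = 0.0, 0
    for i, col in enumerate(cols):
        if cur <= 0:
            cur, start = 0.0, i
        cur += col[4]
        if cur > best:
            best, best_iv = cur, (start, i + 1)
    if best_iv is None:
        return None, 0.0
    return cols[best_iv[0] : best_iv[1]], best


def _align_frame_subject(peptide, subject_id, subject_seq, frame, region_len, offset,
                         params, gate_evalue, db_len_aa, aligner, max_hsps=8):
    """All disjoint HSPs of one frame translation against one subject.

    Iterates optimal local alignment + masking of the matched query span, so
    several same-frame fragments of a degraded gene are each reported; each
    optimal alignment is additionally split at internal score valleys deeper
    than the X-drop, because a single local optimum may otherwise bridge an
    out-of-frame stretch of a frameshifted gene with junk columns.
    """
    matrix = params.matrix()
    out = []
    pep = peptide
    for _ in range(max_hsps):
        score = aligner.score(pep, subject_seq)
        if score <= 0:
            break
        if evalue_of(score, region_len, db_len_aa, params) > gate_evalue:
            break
        aln = aligner.align(pep, subject_seq)[0]
        cols = _alignment_columns(aln, pep, subject_seq, matrix,
                                  params.gap_open, params.gap_extend)
        for piece in _split_columns(cols):
            piece, piece_score = _trim_columns(piece)
            if not piece:
                continue
            E = evalue_of(piece_score, region_len, db_len_aa, params)
            if E > gate_evalue:
                continue
            q_iv = (piece[0][0], piece[-1][1])
            s_iv = (piece[0][2], piece[-1][3])
            ident = sum(c[5] for c in piece)
            ncols = sum(c[6] for c in piece)
            out.append(
                HSP(
                    query_interval=frame_to_genomic(frame, region_len, offset, q_iv),
                    frame=frame,
                    subject_id=subject_id,
                    subject_interval=s_iv,
                    score=int(round(piece_score)),
                    identity=ident / ncols if ncols else 0.0,
                    evalue=E,
                    frame_interval=q_iv,
                )
            )
        blocks_q = aln.aligned[0]
        m0, m1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
        pep = pep[:m0] + "*" * (m1 - m0) + pep[m1:]
    return out


def search_region(
    region_dna: str,
    genomic_offset: int,
    proteome: dict[str, str],
    params: SearchParams | None = None,
    *,
    index: ProteomeIndex | None = None,
    exhaustive: bool = False,
    db_len_aa: int | None = None,
) -> list[HSP]:
    """Search all six frames of a region against a proteome.

    Per (frame, subject) every disjoint local alignment passing the E-value
    gate is reported, with genomic coordinates mapped back to the forward
    strand.  ``exhaustive=True`` aligns every frame against every subject and
    is the oracle the seeded mode is tested against; seeded mode restricts
    alignment to subjects sharing two diagonal-consistent exact seed words
    with the frame translation.
    """
    params = params or SearchParams()
    if not proteome:
        raise ValueError("empty proteome")
    region_dna = region_dna.upper()
    if not region_dna:
        return []
    db_len_aa = db_len_aa or sum(len(s) for s in proteome.values())
    frames = six_frame_translate(region_dna)
    aligner = _make_aligner(params)
    if index is None and not exhaustive:
        index = ProteomeIndex(proteome, params.seed_word_len)
    hsps: list[HSP] = []
    L = len(region_dna)
    for f in FRAMES:
        pep = frames[f]
        if len(pep) < 2:
            continue
        subjects = list(proteome) if exhaustive else sorted(index.candidate_subjects(pep))
        for sid in subjects:
            hsps.extend(
                _align_frame_subject(
                    pep, sid, proteome[sid], f, L, genomic_offset, params,
                    params.evalue_cutoff, db_len_aa, aligner,
                )
            )
    hsps.sort(key=lambda h: (h.query_interval, h.subject_id, h.frame, h.subject_interval))
    return hsps


def write_hsp_tsv(hsps: list[HSP], path):
    """Dump HSPs as TSV (1-based inclusive coordinates, BLAST-outfmt style)."""
    with open(path, "w") as fh:
        fh.write("query_start\tquery_end\tframe\tsubject\tsstart\tsend\tscore\tidentity\tevalue\n")
        for h in hsps:
            fh.write(
                f"{h.query_interval[0] + 1}\t{h.query_interval[1]}\t{h.frame:+d}\t"
                f"{h.subject_id}\t{h.subject_interval[0] + 1}\t{h.subject_interval[1]}\t"
                f"{h.score}\t{h.identity:.3f}\t{h.evalue:.3g}\n"
            )
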