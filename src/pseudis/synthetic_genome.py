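"""Seeded synthetic bacterial chromosomes with planted ground truth.

The generator emulates an eroding endosymbiont genome: intact protein-coding
genes, pseudogenes carrying frameshifts and premature stop codons, multi-copy
IS element families with terminal inverted repeats (TIR) and target-site
duplications (TSD), genes split in two by an IS insertion, and genes
mis-annotated as a short 5' gene with the remainder left unannotated.

Everything is drawn from a single ``numpy.random.default_rng(seed)`` in a
fixed documented order (proteome, category assignment, IS elements, layout),
so a (seed, config) pair maps to byte-identical outputs.

Ground truth is recorded per feature as a :class:`TruthRecord`; disruption
counts reflect the events actually applied, with enough positional detail
kept for an independent recount from the emitted sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io_formats import AnnotationSet, Feature, GenomeRecord, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

# most frequent E. coli codon per residue: reproducible, non-degenerate composition
CODON_OF = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

# approximate background amino-acid composition of bacterial proteomes
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [0.089, 0.012, 0.054, 0.060, 0.039, 0.074, 0.022, 0.060, 0.058, 0.102,
     0.024, 0.043, 0.044, 0.044, 0.055, 0.058, 0.054, 0.071, 0.013, 0.028]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

FUNCTIONAL_CLASSES = (
    "surface protein",
    "mobile genetic element",
    "central metabolism",
    "information transfer",
    "regulation",
    "conserved hypothetical",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ISFamilySpec:
    """Design of one synthetic IS family."""

    element_len: int = 1052
    tir_len: int = 17
    tsd_len: int | None = 9
    transposase_span: tuple[int, int] = (60, 984)  # in-frame ORF on the element
    n_complete: int = 6       # intact full-length copies
    n_partial: int = 3        # 5'/3' truncations retaining 20-70% of the element
    n_defective: int = 2      # full-length copies with a stop in the transposase
    copy_divergence: float = 0.005  # substitutions/site between copies

    def __post_init__(self):
        s, e = self.transposase_span
        if not (0 <= s < e <= self.element_len):
            raise ConfigError("transposase_span outside element")
        if (e - s) % 3:
            raise ConfigError("transposase_span length must be a codon multiple")
        if self.tir_len and s < self.tir_len + 2:
            raise ConfigError("transposase_span overlaps the left TIR")
        if min(self.n_complete, self.n_partial, self.n_defective) < 0:
            raise ConfigError("IS copy counts must be >= 0")

    @property
    def n_copies(self) -> int:
        return self.n_complete + self.n_partial + self.n_defective


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic chromosome (~300 kb at defaults)."""

    seed: int = 0
    n_proteins: int = 220
    protein_len_range: tuple[int, int] = (100, 400)
    n_genes_placed: int = 200
    pseudo_fraction: float = 0.2
    frameshift_rate: float = 2.0   # expected frameshifts per degraded gene
    stop_rate: float = 1.0         # expected premature stops per degraded gene
    substitution_rate: float = 0.005  # per-site, degraded genes only
    is_families: tuple[ISFamilySpec, ...] = (
        ISFamilySpec(),
        ISFamilySpec(
            element_len=1175, tir_len=11, tsd_len=None,
            transposase_span=(80, 1004), n_complete=5, n_partial=2, n_defective=1,
        ),
    )
    n_is_split_genes: int = 5
    n_missplit_genes: int = 10
    intergenic_spacer_range: tuple[int, int] = (100, 500)

    def __post_init__(self):
        lo, hi = self.protein_len_range
        if lo > hi or lo < 30:
            raise ConfigError(f"degenerate protein_len_range {self.protein_len_range}")
        lo, hi = self.intergenic_spacer_range
        if lo > hi or lo < 60:
            raise ConfigError("intergenic spacers must allow >= 60 bp")
        if not (0 <= self.pseudo_fraction <= 1):
            raise ConfigError("pseudo_fraction must be in [0,1]")
        if min(self.frameshift_rate, self.stop_rate, self.substitution_rate) < 0:
            raise ConfigError("rates must be >= 0")
        if self.n_genes_placed > self.n_proteins:
            raise ConfigError("n_genes_placed exceeds n_proteins")
        need = self.n_pseudo + self.n_is_split_genes + self.n_missplit_genes
        if need > self.n_genes_placed:
            raise ConfigError(
                f"requested features exceed genome capacity: {need} degraded/split/"
                f"mis-split genes need n_genes_placed >= {need} (got {self.n_genes_placed})"
            )

    @property
    def n_pseudo(self) -> int:
        return int(round(self.pseudo_fraction * self.n_genes_placed))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "is_families" in d:
            d["is_families"] = tuple(
                ISFamilySpec(**{**f, "transposase_span": tuple(f["transposase_span"])})
                if isinstance(f, dict) else f
                for f in d["is_families"]
            )
        for k in ("protein_len_range", "intergenic_spacer_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    feature_id: str
    origin_protein_id: str | None
    planted_segments: list[tuple[int, int]]
    strand: str
    category: str  # intact_gene | pseudogene | is_copy | missplit_pair
    disruptions: dict = field(default_factory=lambda: {
        "frameshifts": 0, "premature_stops": 0, "is_insertion": False, "truncated": False,
    })
    extras: dict = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeRecord
    annotation: AnnotationSet          # the "original annotation" the pipeline starts from
    truth: list[TruthRecord]
    proteome: dict[str, str]
    is_elements: dict[str, str]        # family_id -> designed element sequence


# ---------------------------------------------------------------------------


def _random_dna(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_proteome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random proteins with a fixed background composition, all starting with M."""
    if config.n_proteins < 1:
        raise ConfigError("n_proteins must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.protein_len_range
    out = {}
    for i in range(config.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(list(_AA), size=n - 1, p=_AA_FREQ))
        out[f"P{i + 1:04d}"] = "M" + body
    return out


def reverse_translate(protein: str) -> str:
    """Fixed-table reverse translation; appends a single TAA stop."""
    return "".join(CODON_OF[a] for a in protein) + "TAA"


def _is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def degrade_gene(
    dna_cds: str,
    config: SimConfig,
    rng: np.random.Generator,
    require_event: bool = False,
) -> tuple[str, dict]:
    """Apply Poisson numbers of frameshifts and premature stops to a CDS.

    Mutations avoid the first and last 10 codons so both ends of the gene
    stay alignable.  Substitutions never create a stop codon (those are
    planted separately and counted); indels keep >= 9 nt mutual separation
    and stay clear of planted stops so every event is individually
    recountable from the emitted sequence.

    Returns ``(mutated_dna, events)`` where ``events`` holds the applied
    counts and positions.
    """
    n = len(dna_cds)
    if n % 3 or not dna_cds.startswith("ATG") or not _is_stop(dna_cds[-3:]):
        raise ValueError("input is not a valid CDS")
    n_codons = n // 3 - 1  # coding codons, terminal stop excluded
    if n_codons < 30:
        raise ValueError("CDS shorter than 30 codons: too short to degrade meaningfully")

    while True:
        n_fs = int(rng.poisson(config.frameshift_rate))
        n_stop = int(rng.poisson(config.stop_rate))
        if not require_event or n_fs + n_stop > 0:
            break

    codons = [dna_cds[i : i + 3] for i in range(0, n, 3)]
    lo_c, hi_c = 10, n_codons - 10

    # substitutions (background divergence; never creating or destroying stops)
    n_sub = 0
    if config.substitution_rate > 0:
        sites = np.nonzero(rng.random(n) < config.substitution_rate)[0]
        for p in sites:
            ci = p // 3
            if not (lo_c <= ci < hi_c):
                continue
            old = codons[ci]
            for _ in range(8):
                b = str(rng.choice([x for x in "ACGT" if x != dna_cds[p]]))
                cand = old[: p % 3] + b + old[p % 3 + 1 :]
                if not _is_stop(cand):
                    codons[ci] = cand
                    n_sub += 1
                    break

    # premature stops: codon -> TAA at distinct interior codons
    stop_codon_idx = sorted(
        int(i) for i in rng.choice(np.arange(lo_c, hi_c), size=min(n_stop, hi_c - lo_c), replace=False)
    ) if n_stop else []
    for ci in stop_codon_idx:
        codons[ci] = "TAA"
    seq = "".join(codons)

    # frameshifts: 1-2 bp indels at interior nt positions, well separated
    forbidden = set()
    for ci in stop_codon_idx:
        forbidden.update(range(3 * ci - 6, 3 * ci + 9))
    fs_events = []  # (nt_pos, signed_size) applied right-to-left
    lo_nt, hi_nt = 3 * lo_c, 3 * hi_c
    attempts = 0
    while len(fs_events) < n_fs and attempts < 200:
        attempts += 1
        p = int(rng.integers(lo_nt, hi_nt))
        if p in forbidden or any(abs(p - q) < 9 for q, _ in fs_events):
            continue
        size = int(rng.integers(1, 3))
        sign = -1 if rng.random() < 0.5 else 1
        fs_events.append((p, sign * size))
    fs_events.sort(reverse=True)
    for p, sz in fs_events:
        if sz < 0:
            seq = seq[:p] + seq[p - sz :]
        else:
            seq = seq[:p] + _random_dna(rng, sz) + seq[p:]

    events = {
        "frameshifts": len(fs_events),
        "premature_stops": len(stop_codon_idx),
        "substitutions": n_sub,
        "stop_positions": stop_codon_idx,       # codon index in the original frame
        "indels": sorted((p, sz) for p, sz in fs_events),  # original nt pos, +ins/-del
    }
    return seq, events


# ---------------------------------------------------------------------------
# IS elements


def _build_element(spec: ISFamilySpec, rng) -> str:
    """Design one IS element: TIR-bounded random sequence with an in-frame
    transposase ORF; the two columns inward of each TIR arm are forced
    non-complementary so the planted TIR length is maximal."""
    e = list(_random_dna(rng, spec.element_len))
    t = spec.tir_len
    if t:
        left = _random_dna(rng, t)
        # avoid homopolymeric arms (degenerate inverted repeats)
        while len(set(left)) < 2:
            left = _random_dna(rng, t)
        e[:t] = list(left)
        e[-t:] = list(revcomp(left))
        for off in (t, t + 1):  # break complementarity just inside the arms
            i, j = off, spec.element_len - 1 - off
            if _COMP[e[i]] == e[j]:
                choices = [b for b in "ACGT" if b != e[j] and _COMP[e[i]] != b]
                e[j] = str(rng.choice(choices))
    s, t0 = spec.transposase_span
    orf_len = t0 - s
    n_cod = orf_len // 3
    orf = ["ATG"]
    for _ in range(n_cod - 2):
        c = _random_dna(rng, 3)
        while _is_stop(c) or c == "ATG":
            c = _random_dna(rng, 3)
        orf.append(c)
    orf.append("TAA")
    e[s:t0] = list("".join(orf))
    return "".join(e)


def _mutate_copy(element: str, spec: ISFamilySpec, rng, defective: bool) -> str:
    """Per-copy divergence; terminal 25 bp conserved (TIRs under selection);
    never creates a stop in the transposase of an intended-functional copy."""
    e = list(element)
    n = len(e)
    s, t = spec.transposase_span
    guard = 25
    sites = np.nonzero(rng.random(n) < spec.copy_divergence)[0]
    for p in sites:
        if p < guard or p >= n - guard:
            continue
        for _ in range(8):
            b = str(rng.choice([x for x in "ACGT" if x != e[p]]))
            if s <= p < t:
                ci = (p - s) // 3
                cod = "".join(e[s + 3 * ci : s + 3 * ci + 3])
                cand = cod[: (p - s) % 3] + b + cod[(p - s) % 3 + 1 :]
                if not defective and _is_stop(cand):
                    continue
            e[p] = b
            break
    if defective:
        n_cod = (t - s) // 3
        ci = int(rng.integers(n_cod // 3, 2 * n_cod // 3))
        e[s + 3 * ci : s + 3 * ci + 3] = list("TAA")
    return "".join(e)


def _truncate(copy: str, spec: ISFamilySpec, rng) -> str:
    keep = float(rng.uniform(0.2, 0.7))
    k = max(60, int(round(keep * len(copy))))
    return copy[:k] if rng.random() < 0.5 else copy[len(copy) - k :]


# ---------------------------------------------------------------------------


def plant_genome(config: SimConfig) -> SimResult:
    """Assemble the chromosome, its (deliberately incomplete) annotation and
    the ground-truth manifest.

    Draw order from the single generator: proteome, gene categories, gene
    strands, IS element designs, spacer/copy placement, per-gene content.
    Degraded genes, both halves of IS-split genes and the 3' remainder of
    mis-split genes are *omitted* from the annotation — they are what the
    pipeline must rediscover.
    """
    rng = np.random.default_rng(config.seed)
    proteome = make_proteome(config, rng)
    pids = list(proteome)

    n = config.n_genes_placed
    n_pseudo = config.n_pseudo
    need = n_pseudo + config.n_is_split_genes + config.n_missplit_genes
    if need > n:
        raise ConfigError(
            f"requested {need} degraded/split/mis-split genes but only {n} genes placed"
        )
    order = rng.permutation(n)
    cat = {}
    for i in order[:n_pseudo]:
        cat[int(i)] = "pseudogene"
    for i in order[n_pseudo : n_pseudo + config.n_is_split_genes]:
        cat[int(i)] = "is_split"
    for i in order[n_pseudo + config.n_is_split_genes : need]:
        cat[int(i)] = "missplit"
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    classes = [str(rng.choice(FUNCTIONAL_CLASSES)) for _ in range(n)]

    elements = {
        f"ISF{fi + 1}": _build_element(spec, rng)
        for fi, spec in enumerate(config.is_families)
    }

    # allocate IS copies: split-gene insertions are drawn out of the complete
    # allocation (families in order), the rest go into intergenic spacers
    split_alloc: list[str] = []
    spacer_alloc: list[tuple[str, str]] = []  # (family_id, kind)
    remaining_split = config.n_is_split_genes
    for fi, spec in enumerate(config.is_families):
        fid = f"ISF{fi + 1}"
        take = min(remaining_split, spec.n_complete)
        remaining_split -= take
        split_alloc += [fid] * take
        spacer_alloc += [(fid, "complete")] * (spec.n_complete - take)
        spacer_alloc += [(fid, "defective")] * spec.n_defective
        spacer_alloc += [(fid, "partial")] * spec.n_partial
    if remaining_split:
        raise ConfigError(
            f"n_is_split_genes={config.n_is_split_genes} exceeds the complete IS copy budget"
        )
    n_spacers = n + 1
    if len(spacer_alloc) > n_spacers:
        raise ConfigError(
            f"{len(spacer_alloc)} spacer IS copies requested but only {n_spacers} spacers; "
            f"increase n_genes_placed to at least {len(spacer_alloc) - 1}"
        )
    host_spacers = set(
        int(i) for i in rng.choice(np.arange(n_spacers), size=len(spacer_alloc), replace=False)
    )
    spacer_plan: dict[int, tuple[str, str]] = {}
    for si, alloc in zip(sorted(host_spacers), spacer_alloc):
        spacer_plan[si] = alloc

    parts: list[str] = []
    pos = 0
    features: list[Feature] = []
    truth: list[TruthRecord] = []
    is_copy_counter = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start, pos

    def place_spacer(si: int):
        nonlocal is_copy_counter
        lo, hi = config.intergenic_spacer_range
        length = int(rng.integers(lo, hi + 1))
        spacer = _random_dna(rng, length)
        if si not in spacer_plan:
            emit(spacer)
            return
        fid, kind = spacer_plan[si]
        spec = config.is_families[int(fid[3:]) - 1]
        copy = _mutate_copy(elements[fid], spec, rng, defective=(kind == "defective"))
        if kind == "partial":
            copy = _truncate(copy, spec, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = copy if strand == "+" else revcomp(copy)
        p = int(rng.integers(20, length - 20))
        use_tsd = spec.tsd_len if kind != "partial" else None
        if use_tsd:
            tsd = spacer[p : p + use_tsd]
            while len(set(tsd)) < 2:  # periodic TSDs would blur the planted length
                repl = _random_dna(rng, use_tsd)
                spacer = spacer[:p] + repl + spacer[p + use_tsd :]
                tsd = repl
            left, right = spacer[: p + use_tsd], spacer[p:]
        else:
            if spacer[p - 1] == spacer[p]:  # keep the planted "no TSD" unambiguous
                alt = str(rng.choice([b for b in "ACGT" if b != spacer[p]]))
                spacer = spacer[:p] + alt + spacer[p + 1 :]
            left, right = spacer[:p], spacer[p:]
        emit(left)
        cstart, cend = emit(placed)
        emit(right)
        is_copy_counter += 1
        truth.append(
            TruthRecord(
                feature_id=f"isc_{is_copy_counter:04d}",
                origin_protein_id=None,
                planted_segments=[(cstart, cend)],
                strand=strand,
                category="is_copy",
                disruptions={
                    "frameshifts": 0, "premature_stops": 0,
                    "is_insertion": False, "truncated": kind == "partial",
                },
                extras={"family": fid, "kind": kind,
                        "tsd_len": use_tsd if use_tsd else 0},
            )
        )

    split_iter = iter(split_alloc)

    for gi in range(n):
        place_spacer(gi)
        pid = pids[gi]
        protein = proteome[pid]
        cds = reverse_translate(protein)
        strand = strands[gi]
        tag = f"SG{gi + 1:04d}"
        category = cat.get(gi, "intact")
        quals = {"product": f"hypothetical protein {pid}",
                 "functional_class": classes[gi]}

        if category == "intact":
            placed = cds if strand == "+" else revcomp(cds)
            s, e = emit(placed)
            features.append(Feature(tag, "gene", strand, [(s, e)], dict(quals)))
            truth.append(TruthRecord(tag, pid, [(s, e)], strand, "intact_gene"))

        elif category == "missplit":
            frac = float(rng.uniform(0.3, 0.6))
            n_cod = len(protein)
            k = max(10, int(round(frac * n_cod)))
            placed = cds if strand == "+" else revcomp(cds)
            s, e = emit(placed)
            if strand == "+":
                ann = (s, s + 3 * k)
            else:
                ann = (e - 3 * k, e)
            features.append(Feature(tag, "gene", strand, [ann], dict(quals)))
            truth.append(
                TruthRecord(
                    tag, pid, [(s, e)], strand, "missplit_pair",
                    extras={"annotated_interval": ann, "annotated_fraction": k / n_cod,
                            "gene_relative_position": "5P"},
                )
            )

        elif category == "pseudogene":
            mutated, events = degrade_gene(cds, config, rng, require_event=True)
            placed = mutated if strand == "+" else revcomp(mutated)
            s, e = emit(placed)
            truth.append(
                TruthRecord(
                    tag, pid, [(s, e)], strand, "pseudogene",
                    disruptions={
                        "frameshifts": events["frameshifts"],
                        "premature_stops": events["premature_stops"],
                        "is_insertion": False, "truncated": False,
                    },
                    extras={"events": events},
                )
            )

        elif category == "is_split":
            fid = next(split_iter)
            spec = config.is_families[int(fid[3:]) - 1]
            copy = _mutate_copy(elements[fid], spec, rng, defective=False)
            is_strand = "+" if rng.random() < 0.5 else "-"
            placed_is = copy if is_strand == "+" else revcomp(copy)
            n_cod = len(protein)
            c = int(rng.integers(15, n_cod - 15))
            pnt = 3 * c
            tsd = spec.tsd_len or 0
            body = cds[: pnt + tsd] + placed_is + cds[pnt:]
            if strand == "-":
                body = revcomp(body)
            s, e = emit(body)
            if strand == "+":
                seg5 = (s, s + pnt + tsd)
                isg = (s + pnt + tsd, s + pnt + tsd + len(placed_is))
                seg3 = (isg[1], e)
                is_strand_g = is_strand
            else:
                seg3 = (s, s + len(cds) - pnt)
                isg = (seg3[1], seg3[1] + len(placed_is))
                seg5 = (isg[1], e)
                is_strand_g = "+" if is_strand == "-" else "-"
            is_copy_counter += 1
            truth.append(
                TruthRecord(
                    tag, pid, [seg5, seg3] if strand == "+" else [seg5, seg3],
                    strand, "pseudogene",
                    disruptions={"frameshifts": 0, "premature_stops": 0,
                                 "is_insertion": True, "truncated": False},
                    extras={"is_family": fid, "split_codon": c},
                )
            )
            truth.append(
                TruthRecord(
                    feature_id=f"isc_{is_copy_counter:04d}",
                    origin_protein_id=None,
                    planted_segments=[isg],
                    strand=is_strand_g,
                    category="is_copy",
                    disruptions={"frameshifts": 0, "premature_stops": 0,
                                 "is_insertion": False, "truncated": False},
                    extras={"family": fid, "kind": "complete", "splits_gene": tag,
                            "tsd_len": tsd},
                )
            )

    place_spacer(n)

    genome = GenomeRecord("synthetic_chromosome", "".join(parts))
    annotation = AnnotationSet(genome.id, features, provenance="synthetic original annotation")
    return SimResult(config, genome, annotation, truth, proteome, elements)


# ---------------------------------------------------------------------------


def write_outputs(result: SimResult, outdir):
    """genome FASTA + original-annotation GFF3 + proteome FASTA + truth JSON."""
    import os

    from .io_formats import write_fasta, write_features_gff3

    os.makedirs(outdir, exist_ok=True)
    write_fasta([result.genome], os.path.join(outdir, "genome.fasta"))
    write_fasta(result.proteome.items(), os.path.join(outdir, "proteome.faa"))
    write_features_gff3(result.annotation, os.path.join(outdir, "annotation.gff3"), result.genome)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump([asdict(t) for t in result.truth], fh, indent=1, default=int)
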