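"""Sequence and annotation I/O plus the shared coordinate model.

Internal convention: 0-based, half-open intervals on the forward strand.
Everything written to disk (GFF3, EMBL-like feature tables) is 1-based
inclusive, as the formats require.

A :class:`Feature` may span several segments (a reconstructed pseudogene is
one feature whose open reading frames sit in different frames); segments are
kept in transcription order, i.e. ascending genomic coordinates on the plus
strand and descending on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed or empty input file."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the allowed alphabet."""


class CoordinateError(ValueError):
    """Feature coordinates fall outside the genome."""


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self):
        if not self.id:
            raise FormatError("genome record must carry a non-empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"record {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    """A located, stranded, possibly multi-segment annotation element."""

    locus_tag: str
    kind: str  # gene | pseudogene | is_element | misc_feature
    strand: str  # "+" | "-"
    segments: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    KINDS = ("gene", "pseudogene", "is_element", "misc_feature")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"{self.locus_tag}: unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if not self.segments:
            raise ValueError(f"{self.locus_tag}: feature needs at least one segment")
        for s, e in self.segments:
            if not (0 <= s < e):
                raise ValueError(f"{self.locus_tag}: bad segment ({s},{e})")
        genomic = sorted(self.segments)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.locus_tag}: overlapping segments")
        # transcription order: ascending for +, descending for -
        want = genomic if self.strand == "+" else genomic[::-1]
        if list(self.segments) != want:
            self.segments = want

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate."""
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (half-open)."""
        return max(e for _, e in self.segments)

    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def extract(self, genome_seq: str) -> str:
        """Spliced sequence in transcription orientation."""
        parts = [genome_seq[s:e] for s, e in sorted(self.segments)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class AnnotationSet:
    genome_id: str
    features: list[Feature] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        self.validate_tags()

    def validate_tags(self):
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus_tags: {dup}")

    def sorted_features(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, f.end, f.locus_tag))

    def validate_against(self, genome: GenomeRecord):
        for f in self.features:
            if f.end > len(genome):
                raise CoordinateError(
                    f"{f.locus_tag}: coordinate {f.end} beyond genome length {len(genome)}"
                )


# ---------------------------------------------------------------------------
# FASTA

def _check_dna(record_id: str, seq: str) -> str:
    seq = seq.upper()
    if "U" in seq:
        raise AlphabetError(f"record {record_id!r}: RNA letter 'U' (DNA expected)")
    for i, c in enumerate(seq):
        if c not in DNA_ALPHABET:
            raise AlphabetError(
                f"record {record_id!r}: illegal character {c!r} at position {i + 1}"
            )
    return seq


def parse_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA of DNA sequences.

    Lowercase is folded to uppercase; anything outside {A,C,G,T,N} is an
    error naming the record and 1-based position.
    """
    records = [
        GenomeRecord(r.id, _check_dna(r.id, str(r.seq))) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def parse_protein_fasta(path) -> dict[str, str]:
    """Read an amino-acid FASTA into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for r in SeqIO.parse(str(path), "fasta"):
        seq = str(r.seq).upper()
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(f"record {r.id!r}: illegal residues {sorted(bad)}")
        out[r.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(records, path, width: int = 70):
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, GenomeRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE = {
    "gene": "gene",
    "pseudogene": "pseudogene",
    "is_element": "mobile_genetic_element",
    "misc_feature": "sequence_feature",
}
_GFF_TYPE_BACK = {v: k for k, v in _GFF_TYPE.items()}


def _esc(text: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), str(text))


def _unesc(text: str) -> str:
    return re.sub(r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), text)


def write_features_gff3(annotation: AnnotationSet, path, genome: GenomeRecord | None = None):
    """Write an AnnotationSet as GFF3 (1-based inclusive coordinates).

    Multi-segment features are emitted as a parent record plus one child
    ``*_part`` line per segment sharing a Parent attribute.
    """
    if genome is not None:
        annotation.validate_against(genome)
    lines = ["##gff-version 3"]
    if genome is not None:
        lines.append(f"##sequence-region {annotation.genome_id} 1 {len(genome)}")
    for f in annotation.sorted_features():
        ftype = _GFF_TYPE[f.kind]
        attrs = [f"ID={_esc(f.locus_tag)}"]
        for k, v in sorted(f.qualifiers.items()):
            attrs.append(f"{_esc(k)}={_esc(v)}")
        lines.append(
            "\t".join(
                [
                    annotation.genome_id,
                    "pseudis",
                    ftype,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        if len(f.segments) > 1:
            for i, (s, e) in enumerate(sorted(f.segments), 1):
                lines.append(
                    "\t".join(
                        [
                            annotation.genome_id,
                            "pseudis",
                            ftype + "_part",
                            str(s + 1),
                            str(e),
                            ".",
                            f.strand,
                            ".",
                            f"ID={_esc(f.locus_tag)}.{i};Parent={_esc(f.locus_tag)}",
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_features_gff3(path) -> AnnotationSet:
    """Read GFF3 written by :func:`write_features_gff3` back into an AnnotationSet."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome_id = None
    parents: dict[str, Feature] = {}
    parts: dict[str, list[tuple[int, int]]] = {}
    for rec in db.all_features(order_by=("start",)):
        genome_id = genome_id or rec.seqid
        interval = (rec.start - 1, rec.end)
        if rec.featuretype.endswith("_part"):
            parent = _unesc(rec.attributes["Parent"][0])
            parts.setdefault(parent, []).append(interval)
            continue
        tag = _unesc(rec.id)
        quals = {
            _unesc(k): _unesc(v[0]) if v else ""
            for k, v in rec.attributes.items()
            if k not in ("ID", "Parent")
        }
        parents[tag] = Feature(
            locus_tag=tag,
            kind=_GFF_TYPE_BACK.get(rec.featuretype, "misc_feature"),
            strand=rec.strand,
            segments=[interval],
            qualifiers=quals,
        )
    for tag, segs in parts.items():
        parents[tag].segments = segs
        parents[tag].__post_init__()  # re-establish transcription order
    return AnnotationSet(genome_id=genome_id or "unknown", features=list(parents.values()))


# ---------------------------------------------------------------------------
# EMBL-like feature table (FT lines only)

_EMBL_KEY = {
    "gene": "CDS",
    "pseudogene": "CDS",
    "is_element": "repeat_unit",
    "misc_feature": "misc_feature",
}


def _embl_location(f: Feature) -> str:
    locs = [f"{s + 1}..{e}" for s, e in sorted(f.segments)]
    loc = locs[0] if len(locs) == 1 else "join(" + ",".join(locs) + ")"
    if f.strand == "-":
        loc = f"complement({loc})"
    return loc


def write_features_embl_like(annotation: AnnotationSet, path, genome: GenomeRecord | None = None):
    """Minimal EMBL feature table: FT lines with 1-based inclusive locations.

    Multi-segment features become ``join(a..b,c..d)``; minus strand wraps the
    location in ``complement(...)``; kind=pseudogene carries ``/pseudo``.
    """
    if genome is not None:
        annotation.validate_against(genome)
    lines = []
    for f in annotation.sorted_features():
        key = _EMBL_KEY[f.kind]
        lines.append(f"FT   {key:<16s}{_embl_location(f)}")
        lines.append(f'FT                   /locus_tag="{f.locus_tag}"')
        if f.kind == "pseudogene":
            lines.append("FT                   /pseudo")
        for k, v in sorted(f.qualifiers.items()):
            lines.append(f'FT                   /{k}="{v}"')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
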