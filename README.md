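# pseudis

Pseudogene discovery, insertion-sequence (IS) characterization and metabolic
pathway-completeness analysis for bacterial genomes undergoing reductive
evolution — the situation of recently host-restricted endosymbionts such as
*Sodalis glossinidius*, the secondary endosymbiont of tsetse flies, whose
chromosome still carries hundreds of recognizable gene relics.

## What it does

**Pseudogene discovery.** Degraded genes no longer look like ORFs, so ab
initio gene callers miss them. `pseudis` searches *intergenic* DNA directly:
regions ≥ 50 bp between non-overlapping annotated features are six-frame
translated and locally aligned against a reference proteome (BLOSUM62,
affine gaps 11/1, Karlin–Altschul E-values, E ≤ 10⁻⁵). Per subject protein,
colinear alignments are chained across reading frames; a chain is kept when
it covers ≥ 25% of the subject. Each chain becomes a reconstructed gene
model: one segment per alignment, frameshifts counted as frame changes
between consecutive segments, premature stops counted as in-frame stops
inside segments. A second pass re-extracts intergenic space (now also
bounded by first-pass pseudogenes) against an optional extended proteome.
Reconciliation then merges adjacent same-subject calls, rejoins genes split
in two by an IS insertion, and converts "short annotated gene + adjacent
pseudogene of the same ancestor" situations into split records.

**IS elements.** Repeat families are found by genome self-comparison
(exact 21-mer anchors, single-linkage clustering at ≥ 80% identity,
≥ 500 bp), a consensus is built per family (center-star alignment, majority
columns), terminal inverted repeats and target-site duplications are
measured, divergent/partial copies are recovered by re-scanning with the
consensus, per-copy transposase functionality is classified (internal stop
or frame-breaking indel ⇒ defective), and copy divergence is summarized as
pairwise-deletion p-distances.

**Pathway status.** Boolean reachability over reaction graphs whose gene
requirements are AND/OR expressions under a three-valued gene status
(functional / pseudogene / absent): a reaction fires iff its substrates are
producible and its requirement holds; producibility is the least fixed
point. Two-organism complementation couples the fixed points through an
exchangeable metabolite set. Fixtures for arginine, putrescine, lysine and
thiamine biosynthesis in *S. glossinidius* and *Wigglesworthia glossinidia*
are bundled.

**Synthetic genomes.** A seeded generator plants intact genes, pseudogenes
(Poisson frameshifts + premature stops), IS families with TIRs/TSDs
(complete, truncated and transposase-defective copies), genes split by an
IS insertion, and genes mis-annotated as a short 5' gene — with a ground
truth manifest, so the whole pipeline is testable without any downloads.

## Worked example

```
pseudis simulate --seed 1 --out-dir sim
pseudis find-is --genome sim/genome.fasta --out-prefix sim/is
pseudis find-pseudogenes --genome sim/genome.fasta \
    --annotation sim/annotation.gff3 --proteome sim/proteome.faa \
    --out-prefix sim/out
```

prints

```
genome 234180 bp, 155 annotated features, 219 truth records -> sim
2 families, 19 copies, 7.75% of genome, 0.081 elements/kb
45 pseudogenes, 10 gene+pseudogene splits
```

The simulated chromosome planted 200 genes of which 40 were degraded and 5
split by an IS insertion (45 pseudogenes to find), and 10 were mis-annotated
over their 5' portion only (10 splits to find). `find-is` recovers the two
planted IS families — for the first: consensus 1052 bp, 17 bp terminal
inverted repeat, 9 bp target-site duplication — and `find-pseudogenes`
recovers all 45 pseudogene models (`sim/out.calls.tsv` lists subject,
coverage, frameshift/stop counts, IS-insertion flag and discovery pass) and
all 10 splits (`sim/out.splits.tsv` mirrors the fraction of the ancestral
CDS covered by the annotated gene and by the flanking pseudogene, with 5P/3P
relative positions).

Pathway verdicts, e.g. thiamine complementation:

```
pseudis pathway --pathway src/pseudis/data/pathways/thiamine.json \
    --status-a src/pseudis/data/pathways/status_sodalis.json \
    --status-b src/pseudis/data/pathways/status_wigglesworthia.json \
    --exchange THZ-P,HMP-PP --out verdicts.tsv
```

yields thiamine diphosphate **blocked** for each organism alone and
**producible** for both when the thiazole (THZ-P) and pyrimidine (HMP-PP)
moieties are exchangeable — one organism contributes each moiety.

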