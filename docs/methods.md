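# Methods

## Translated homology search

Intergenic DNA is translated in all six frames (bacterial code, table 11;
stop codons become `*`, N-containing codons `X`) and each frame is aligned
against every candidate subject protein with the exact affine-gap local
aligner of `Bio.Align.PairwiseAligner` under BLOSUM62 with gap open 11 and
extend 1 (the first gap position is charged the open penalty; a gap of
length L costs 11 + (L−1)). `*` scores −4 against every residue and never
counts as an identity, so stops inside pseudogene alignments are permitted
but penalized. Significance follows the Karlin–Altschul form
E = K·(m/3)·n·exp(−λS) with the standard gapped BLOSUM62/11/1 constants
λ = 0.267, K = 0.041; edge-effect and composition corrections are out of
scope, which is acceptable because only the E ≤ 10⁻⁵ gate matters here, not
exact E-values.

Candidate subjects are selected by a two-hit seeding heuristic: exact
4-mer words shared between a frame translation and a subject, two hits on a
consistent diagonal (slack 5) within 400 residues. Any conserved stretch of
≥ 5 residues produces such a pair, so on the near-exact homology this
package targets the seeded search returns the same alignment set as the
exhaustive frame-by-subject scan — a contract enforced by test on regions
up to 2 kb. Per (frame, subject) the optimal alignment is found, its query
span masked, and the search repeated (up to 8 times), so several same-frame
fragments of one degraded gene are all reported; this matters because two
frameshifts cancel modulo 3 about half the time, putting two separate
fragments of the same gene in the same frame.

Each optimal alignment is additionally split at internal score valleys
deeper than an X-drop of 12 and each piece trimmed to its maximal-scoring
stretch. Without this, a single local optimum happily "bridges" a short
out-of-frame stretch between two frameshifts with junk columns, which
corrupts both frameshift and stop counts. The value 12 separates the worst
legitimate dip inside a genuine alignment (a premature stop flanked by
mismatches, ≈ −9) from the cost of bridging even a few out-of-frame codons.

## Pseudogene pipeline

Intergenic regions are the complement of the annotated features, kept at
≥ 50 bp, with chromosome ends included and flanking locus tags recorded.
Per region and subject, alignments are chained by dynamic programming:
ascending subject coordinates along the transcription direction, genomic
gap ≤ 3000 bp (bridges a 1–1.3 kb IS insertion), genomic overlap ≤ 45 nt
(target-site duplications), subject overlap ≤ 10 aa — relaxed to 30 aa when
the genomic gap spans a located IS copy, since alignment slop into the
element inflates the apparent overlap. The published cutoff (E ≤ 10⁻⁵) is
applied to the chain's total score; individual fragments enter chains at a
relaxed reporting floor (E ≤ 10), the chain playing the role of a linked
HSP set in BLAST's sum statistics. Sub-significant fragments must look like
genuine conserved sequence (score ≥ 2.5 per aligned residue) to join a
chain, which keeps diffuse chance matches from inflating coverage. Chains
covering < 25% of their subject are discarded; overlapping survivors on the
same genomic span are resolved by total score, then E-value, then subject
id (deterministic output).

Model reconstruction emits one segment per chained alignment and then
performs a rescue step: unexplained subject stretches between consecutive
segments or at the termini are re-aligned against the local genomic window
in all three frames of the call's strand and accepted at a floor of
max(15, 1.5 × gap-length) with ≥ 40% identity — genuine missing fragments
align near-perfectly (≈ 5 bits/residue), so the growing floor excludes junk
in wide windows (e.g. inside an inserted IS). Frameshifts are counted as
frame-label changes between consecutive segments (labels canonicalized to
genome phase), premature stops as `*` in segment translations, excluding a
terminal stop aligned at or beyond the subject C-terminus. Junctions whose
genomic gap spans an IS copy set `is_insertion` and are excluded from the
frameshift count, because the frame change there is an artefact of the
insertion length.

Reconciliation: (a) same-subject, same-strand calls within 3 kb and with
essentially disjoint subject intervals merge into one multi-segment call
whose coverage is the union; (b) IS-spanning junctions set the insertion
flag as above, and a call missing a subject terminus next to a located IS
copy is extended by re-aligning the missing tail immediately beyond the
element (floor max(15, 1.2 × gap), identity ≥ 0.5) — the analogue of
searching the element's flanking sequences, needed because a 10–50 aa
fragment beyond the insertion can never reach 25% coverage on its own;
(c) an annotated gene whose translation covers 5–90% of a
subject, adjacent (≤ 3 kb) to a call covering the complementary part of the
same subject (combined 0.6–1.05), becomes a split record carrying both
fractions and the gene's 5P/3P position, and the call leaves the pseudogene
set; (d) survivors are renumbered `ps_0001…` in genomic order. Calls exist
only through retained homology, so the elimination rule for
homology-free candidates reduces to construction.

Annotation transfer uses reciprocal best local-alignment matches with the
conventional cutoffs: alignment covering ≥ 80% of the shorter protein and
≥ 30% identity; qualifiers (product, gene, EC_number, functional_class) are
copied onto matched queries.

## IS characterization

Self-comparison uses exact 21-mer anchors with strands collapsed to a
canonical form; positions covered by a repeated word are merged (gap
≤ 100 bp) into repeat intervals ≥ 500 bp, clustered single-linkage against
a family representative at ≥ 80% identity (edlib edit distance, both
orientations). The consensus is built in two rounds: a provisional
center-star majority consensus from the raw intervals, a re-scan of the
genome with it, and a rebuild from the alignment-refined copies. Raw
interval boundaries creep 1–3 bp into the flanks wherever flank bases match
another copy by chance, and the majority vote is correlated with exactly
the copies that creep, so iteration alone does not converge; terminal
consensus columns matched by < 85% of the complete copies are therefore
trimmed. True element termini are transposase-binding inverted repeats and
essentially invariant, so the trim removes only chance-supported columns.

Terminal inverted repeats are detected by greedy arm extension from the
termini under ≤ 1 mismatch per 10 bp, with trailing mismatches trimmed and
a minimum of 8 bp; if the true termini carry none, offsets up to 50 bp are
scanned and a hit is reported as *internal* (some IS110-family elements
carry internal inverted repeats and no target-site duplication). The
target-site duplication is the modal per-copy longest exact match between
the upstream suffix and downstream prefix of complete copies, required in
≥ 50% of them; mode 0 means none.

Copies are re-scanned with the consensus (15-mer seeds, local DNA
alignment at match 2 / mismatch −3 / gap 10,2), kept at ≥ 50 aligned nt and
≥ 60% identity; "complete" means ≥ 95% of the consensus aligned (the
literature does not define the threshold; 0.95 is this package's choice).
Copy divergence is the pairwise-deletion p-distance — differing sites over
sites where neither copy has a gap — computed on the copies projected onto
consensus coordinates. Transposase functionality is judged on the
alignment slice over the transposase ORF (longest ORF ≥ 300 nt of the
consensus if not supplied): < 50% present ⇒ absent; an internal stop in the
transposase frame, any indel run not a multiple of three, or a net indel
sum not a multiple of three ⇒ defective; otherwise functional —
substitutions and in-frame indels are presumed tolerable. The family table
reports genome_fraction_pct = 100·Σ copy nt / genome length (2 dp,
half-up) and load_per_kb = copies per kilobase (3 dp); copy counts may be
augmented with single-copy elements found outside multi-copy families.

## Pathway reachability

Reactions carry AND/OR gene requirements over three-valued statuses;
pseudogene and absent both evaluate false (a pseudogene contributes no
activity) but are distinguished in reporting: a non-firing reaction is
*inactivated* when restoring its pseudogenes alone satisfies the
requirement, *missing* when restoring its absent genes alone does, and
flagged as both otherwise. Producibility is the least fixed point from the
external inputs; it is order-independent and monotone under status
upgrades because the requirements are monotone boolean formulas (both
properties are tested on randomized pathways). Complementation iterates
two organisms' fixed points, each receiving the exchangeable metabolites
the partner currently produces, to joint convergence.

The bundled thiamine fixture resolves an ambiguity in the source biology:
host thiamine is simultaneously needed for the thiazole salvage
(tenA2/thiM) and considered improbable as a free supply (which would
trivially yield the cofactor via thiK + thiL). Boolean logic cannot hold
both, so the fixture grants exogenous hydroxyethylthiazole (THZ) as the
salvage input — *S. glossinidius* phosphorylates it with thiM, while
*W. glossinidia* lacks thiM and cannot — and exposes free thiamine as an
explicit `inputs_override` toggle (`thiamine_ext`), under which THZ-P is
also producible via the transporter and tenA2, and the cofactor via thiK.
With the toggle off, each organism alone is blocked for thiamine
diphosphate and the consortium produces it by exchanging THZ-P and HMP-PP.

## Synthetic genomes

The generator emulates a recently host-restricted bacterial chromosome.
Defaults are the package's study conditions: 220 proteins of 100–400
residues (fixed background composition, all starting with M), 200 genes
placed with 100–500 bp spacers on random strands (~300 kb), 20% of genes
degraded, two IS families (1052 bp with 17 bp TIR and 9 bp TSD; 1175 bp
with 11 bp TIR and no TSD — an IS110-like design), five genes split by an
IS insertion and ten genes annotated only over a random 30–60% 5' portion.
Genes are reverse-translated with the most frequent codon per residue —
reproducibility over realism. Degradation applies Poisson numbers of 1–2 bp
indels (mean 2) and codon→TAA substitutions (mean 1), redrawn until at
least one event lands, plus background substitutions at 0.005/site that
never create stops; the literature gives no quantitative per-pseudogene
disruption distribution ("multiple frameshifts and premature stops"), so
these means are a simulation choice. All mutations avoid the first and
last 10 codons so the ≥ 25% coverage rule is exercised meaningfully rather
than vacuously; indels keep ≥ 9 nt separation and distance from planted
stops so every event is individually recountable from the emitted bytes.

IS copies diverge by 0.005 substitutions/site (within the published
p-distance range for such families), sparing the terminal 25 bp (TIRs are
under selection) and never creating stops in intended-functional
transposases (purifying selection); defective copies get one planted stop
mid-transposase; partial copies retain a uniform 20–70% of the element
from either end. So that planted TIR/TSD lengths are exact ground truth,
the two columns inward of each TIR arm are forced non-complementary, TSDs
are non-homopolymeric, and no-TSD insertion sites get unequal flanking
bases. Everything derives from a single `numpy.random.default_rng(seed)` in
a fixed draw order: (seed, config) ⇒ byte-identical genome, annotation and
manifest.

What the generator does **not** emulate: real codon usage and GC skew,
operons, prophages, circular chromosomes, genuinely divergent homology
(genes are near-identical to their reference proteins), IS nesting, and
erosion of pseudogene ends. Passing tests therefore demonstrate the
machinery is correct under clean, well-separated signals; on real genomes,
sensitivity depends on the evolutionary distance to the reference proteome
and the published genome-wide counts are not reproducible without the
era-specific databases that produced them.

## Problem sizes and determinism

Unit tests run on ~40 kb genomes (35 genes, 8 pseudogenes, one IS family);
the acceptance checks use the full study-scale defaults over five seeds.
All randomized tests are seeded; pipeline outputs are deterministic given
(seed, config), with ties broken by score, then E-value, then lexicographic
subject id. Known limitations: disruption counts are exact for ~85–95% of
recovered calls — indels clustered within a few codons leave fragments too
short to place even for the rescue step; chance flank matches can extend a
copy boundary by 1 bp in rare seeds (handled by the support trim, above);
and a partial IS copy that retains > 50% of a transposase without
frame-breaking damage is classified by content, i.e. "functional", which is
a statement about the slice, not the element.
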