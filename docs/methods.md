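# Methods

## Decoding model

The genetic code is the standard 64-codon RNA table (61 sense codons; UAA,
UAG, UGA stops). Anticodons are RNA triplets read 5'→3' (positions
34–36); the Watson–Crick anticodon of a codon is its reverse complement,
an involution. Decoding is modelled as: codon positions 1–2 pair
anticodon positions 36–35 by strict Watson–Crick complementarity, while
the set of codon third-position bases pairable by the wobble base
(position 34) comes from a rule table. A rule is either a *wobble rule*
`(wobble base, modification | unmodified, pairable third bases)` or a
*special rule* `(anticodon, modification, target codons, exclusive?)` that
adds (or, when exclusive, replaces with) whole codons. The default rule
set carries exactly the rules the archaeal replacement arguments need:

| rule | effect |
| --- | --- |
| G34, unmodified | pairs C and U |
| U34, unmodified | pairs A |
| U34 + cm5U | pairs A and G |
| C34, unmodified | pairs G |
| A34, unmodified | pairs U |
| CAU + agmatidine | additionally decodes AUA |

Other known wobble modifications (queuosine, cmnm⁵U, cmo⁵U, inosine,
lysidine, pseudouridine) are representable in the same YAML rule format but
are not shipped as defaults, because archaeal modification knowledge is
incomplete; users can override the rule set per run. Decoded sets never
contain stop codons, and the Watson–Crick codon is always included unless
an exclusive special rule removes it. Enabling more modifications can only
grow a repertoire's covered codon set (monotonicity), absent exclusive
rules.

One bookkeeping subtlety: exactly 15 sense NNG codons exist, so the CNN
family has 15 sense anticodon types; surveys that split CAU into initiator
and elongator Met count 16 "CNN tRNAs". The package reports 15 and exposes
the iMet/eMet split as an explicit matrix option instead of double
counting.

## Repertoire matrix

Annotation readers (tRNAscan-SE tabular, a minimal GFF3 subset with
`anticodon=`/`isotype=` attributes and `intron` child features, FASTA with
GtRNAdb-style `Isotype (ANT)` headers) normalise to 1-based inclusive
coordinates, RNA-alphabet anticodons, and gene-relative intron intervals.
Genes flagged as pseudogenes or with undetermined anticodons ("???"/NNN)
are excluded from counting by default; anticodons whose Watson–Crick codon
is a stop (suppressors) are excluded with a warning. The matrix has one row
per genome and one `Aa-NNN` column per sense anticodon (62 columns with the
iMet/eMet split; untagged CAU genes then count as eMet with a warning,
since no annotation-free rule for the split is defensible). Row sums equal
accepted gene counts by construction, and the TSV writer/reader round-trips
matrices bit-exactly.

## Codon usage and optimal codons

Counting starts at position 1 of each CDS; stops, codons containing
ambiguous bases, and trailing partial codons are tallied separately so
that sense counts + exclusions = positions scanned. Frequency ranks use
average ranks for ties (most frequent = 61); mean rank was chosen over
dense rank as the convention for tied counts. The expression partition is
keyword-based over product descriptions (case-insensitive substring):
ribosomal-protein matches are excluded first, then transcription/translation
matches form the highly expressed set, everything else the background —
keyword lists ship as editable defaults because the underlying gene lists
are inherently annotation-dependent. Optimal codons are computed from
counts pooled over the highly expressed genes (the simplest reading of
"most used codon"), with lexicographic tie-breaking and an explicit tie
flag. NNG proportions pool family counts within each degeneracy class
(twofold, fourfold, sixfold = Leu/Ser/Arg); the threefold Ile family and
single-codon families are excluded from that comparison.

## Histories on the species tree

A type is *present* in a genome iff its copy number is ≥ 1. Minimum change
counts use unit-cost dynamic programming over binary node states (Sankoff
recurrence), which is exact on polytomies where the classical
intersection/union rule is only heuristic; ties in the traceback resolve
toward the parent state and toward absence at the root. The Dollo
reconstruction places the single gain on the edge above the MRCA of the
present tips (no events at all when no tip is present — the "never
evolved" reading) and one loss per maximal all-absent subtree inside the
gain clade; replaying the event log from the root reproduces the tip
states exactly.

Classification is rule-based and deterministic, in priority order:
present nowhere → `ancestral_absence`; present in ≤ `gain_max` tips
(default 2, the scale of reported archaeal gains) → `recent_gain`; no
absences → `ubiquitous`; absent from every member of ≥ 1 named clade while
present in ≥ `background_frac` (default 0.75) of the remaining genomes →
`clade_specific_loss`; otherwise `sparse_loss`. The numeric thresholds are
package defaults, not field constants, and are configurable. Named clades
must be monophyletic (checked against the tree). Ubiquitous columns
contribute no events.

## Gain tracing

Candidate gains are matrix cells with copies of a `recent_gain` type.
Candidates are aligned globally (match +1, mismatch −1, linear gap −2;
Needleman–Wunsch) against the intron-spliced sequences of all other tRNA
genes in the input set — no remote database search. The best-scoring
homolog (ties: closer length, then input order) is inspected at the
anticodon windows (positions 34–36 of each ungapped sequence): windows
occupying the same gap-free columns with ≥ 1 internal mismatch →
`anticodon_substitution` (changed positions reported in 34/35/36
coordinates); a gap column inside either window → `anticodon_insertion`;
overall identity below 0.6, or non-overlapping windows →
`untraceable`. Mechanism calls are alignment-dependent, so every trace
records the scoring scheme. Thresholds are configurable.

## Statistics

All tests are two-sided. Exact Mann–Whitney p-values enumerate every
assignment of the pooled observations to the two groups (ties via average
ranks; permitted up to n₁+n₂ = 16, beyond which the normal approximation
with tie and continuity correction is used; `auto` switches at that
boundary). Pearson correlation uses the t-transform with n−2 degrees of
freedom and flags zero-variance input as undefined. Group reports compare
an in-group of genomes against the rest on total tRNA copies, CNN-family
copies, genome size, GC fraction, and (when CDS data are present) the NNG
fraction of optimal codons; raw p-values are reported, with optional
Benjamini–Hochberg adjustment, and values below 2.2e-16 are printed as
"< 2.2e-16" in text output while machine outputs keep exact floats.

## Synthetic data generator

The generator is first-class, tested code; it is the package's stand-in
for a multi-genome survey. One seed drives all stages through documented
sub-seeding (tree topology, repertoire evolution, each genome's CDS set),
and every derived seed stays below 2³¹.

*Tree*: random rooted bifurcating topology by iterated random joins
(coalescent-style), unit implicit branch lengths, tips `G001…`.

*Repertoires*: the root carries the 44-type repertoire, one copy per type
except CAU (1 iMet + 2 eMet copies — matching the observed elongator-Met
overrepresentation at roughly three CAU copies per genome). Down each
branch every present type is lost with probability 0.02, elevated to 0.8
for 10 designated CNN types on branches inside one designated clade
(6–16 tips, including its stem edge) — the clade-specific reductive-loss
scenario. Two gains are planted on distinct terminal branches by mutating
a present gene's anticodon: a point substitution at position 34 (→ A) or a
single-base insertion at the anticodon, both yielding A-starting types,
which are always sense and always root-absent. Gene sequences are 72-nt
random references per type with the anticodon at 34–36, per-gene
substitution noise of 0.02 per site outside the anticodon, and (for gained
genes, with probability 0.5) a 14-nt intron after position 37 recorded in
the annotation. The truth log records every event; replaying it from the
root reproduces the matrix exactly, and the matrix itself is produced by
feeding the generated gene records through the ordinary matrix builder, so
the I/O layer is on the tested path.

*CDS sets*: amino acids uniform, within-family codon choice weighted
`bias:1` toward a planted preferred codon (default 50 for the ~10% highly
expressed and ~5% ribosomal genes, 1 elsewhere), products carrying the
keywords the partitioner expects, one stop appended per gene. Defaults of
1000 genes × 300 codons per genome keep a full run to minutes on one CPU;
tests use smaller sets.

*Metadata*: in-clade genomes draw smaller sizes (≈1.8 Mb vs 2.6 Mb) and
lower GC (≈0.35 vs 0.46) than the background, mirroring the reduced-genome
contrast the group statistics are meant to detect.

What the generator does **not** emulate: realistic tRNA sequence evolution
(no substitution model beyond flat noise and the anticodon edits), genome
rearrangement or size evolution, horizontal transfer, trans-spliced or
permuted tRNAs, and annotation error beyond undetermined anticodons.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated generative assumptions, not robustness to real
annotation noise or alignment ambiguity.

A known behaviour worth stating: with loss probability applied
independently to every branch, occasional losses on near-root branches
erase a type from a large fraction of the out-group; the classifier then
(correctly, per its definition) labels that type `sparse_loss` rather than
`clade_specific_loss` even when the elevated-loss clade is fully absent.
Clade-loss recovery is therefore high per type (~85%) but not certain, and
whole-panel recovery (≥ 9 of 10 elevated types) holds in roughly half of
random simulations under the default conditions.

## Numerical and degenerate-input choices

DNA input (T) is normalised to RNA (U) at every boundary. Optimal-codon
ties break lexicographically with a flag; rank ties use means; alignment
co-optima resolve to the aligner's first reported alignment; parsimony
traceback ties prefer the parent state. Empty gene tables, empty samples,
zero-variance correlations, zero-usage families and genomes with zero
accepted genes all either raise with a named cause or return flagged
undefined values with a warning — never silent zeros. Internal tree nodes
are identified as `mrca(first,last,size)`, which is unique within a tree.

## Limitations

* The iMet/eMet split requires annotation tags; no sequence-based
  discrimination is attempted.
* Gain tracing searches only the supplied gene set and reports the single
  best homolog; it cannot distinguish duplication-then-mutation from
  in-place mutation.
* History classification is threshold-based, not model-based; no
  branch-length-aware or likelihood gain/loss rates are estimated.
* Codon-usage comparisons are not phylogenetically corrected (no
  independent contrasts).
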