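# trnaevo

Comparative analysis of tRNA anticodon repertoires across genomes on a
rooted species tree, built for the archaeal setting where most genomes
carry at most 44 of the 61 possible sense-anticodon tRNA types.

## The problem

A tRNA reads an mRNA codon through its anticodon (structural positions
34–36, 5'→3'). Strict Watson–Crick pairing would require 61 anticodon types
to read the 61 sense codons, but wobble pairing at position 34 and chemical
modifications of the wobble base let fewer types suffice:

* **G34** pairs codon third-position C *and* U, so GNN tRNAs also cover the
  NNU codons normally read by ANN tRNAs;
* **U34**, once modified to cm⁵U (by Elp3), pairs NNG in addition to NNA,
  so UNN tRNAs can replace CNN tRNAs;
* **agmatidine** on the CAU anticodon retargets it to the isoleucine codon
  AUA, covering for the absent UAU tRNA.

Under these rules the 44-type repertoire — all sense anticodons except the
16 A-starting (ANN) types and UAU — still decodes every sense codon. The 17
missing types are precisely the ones essentially never observed in archaeal
genomes, and whether their absence reflects an ancestor that never had them
(one explanation per type) or many independent losses is a parsimony
question on the species tree. Conversely, CNN types *are* widespread but
drop out wholesale in particular clades with reduced genomes, which looks
like convergent clade-specific loss; and occasional ANN/UAU genes in single
genomes are recent gains whose origin can be traced to an existing tRNA
gene carrying an anticodon point mutation or a single-base insertion.

`trnaevo` makes each of those arguments computable:

| stage | module |
| --- | --- |
| genetic code, wobble/modification decoding rules, repertoire coverage | `trnaevo.decoding` |
| tRNA annotation parsing (tRNAscan-SE tabular, GFF3, GtRNAdb-style FASTA) and the genome × anticodon copy-number matrix | `trnaevo.repertoire` |
| codon usage, frequency ranks, optimal codons of highly expressed genes, NNG proportions by degeneracy class | `trnaevo.codon_usage` |
| Fitch/Dollo parsimony and history classification (ancestral absence, clade-specific loss, sparse loss, recent gain) | `trnaevo.phylo` |
| gain-mechanism tracing by global alignment against homologs | `trnaevo.gains` |
| Mann–Whitney (exact and approximate), Pearson, group comparison reports | `trnaevo.stats` |
| synthetic tree/repertoire/CDS generator with a ground-truth event log | `trnaevo.simulate` |
| orchestration + `trnaevo` CLI | `trnaevo.pipeline`, `trnaevo.cli` |

## Worked example

Decoding coverage of the 44-type repertoire:

```python
>>> from trnaevo.decoding import core_repertoire, repertoire_coverage
>>> len(core_repertoire())
44
>>> sorted(repertoire_coverage(core_repertoire(),
...                            enabled_mods={"cm5U", "agmatidine"})[1])
[]
>>> sorted(repertoire_coverage(core_repertoire(), enabled_mods={"cm5U"})[1])
['AUA']
```

With G34 wobble, cm⁵U and agmatidine enabled, no sense codon is orphaned;
disable agmatidine and exactly AUA loses its reader — the quantitative form
of the argument that agmatidine-modified CAU stands in for the missing UAU
tRNA.

Simulate 64 genomes evolving from the 44-type root (elevated CNN loss
inside one clade, two planted anticodon-mutation gains), then classify
every type's history and trace the gains:

```python
from trnaevo.simulate import SimParams, simulate_tree, evolve_repertoires
from trnaevo.phylo import resolve_clades, map_matrix_events
from trnaevo.gains import trace_candidate_gains

params = SimParams()
tree = simulate_tree(params.n_tips, seed=7)
matrix, truth, genes = evolve_repertoires(tree, params, seed=7)
clades = resolve_clades(tree, {truth.clade_label: sorted(truth.clade_tips)})
events, categories = map_matrix_events(tree, matrix, clades)
print(categories["category"].value_counts().to_string())
```

```
sparse_loss            34
ancestral_absence      15
clade_specific_loss     9
recent_gain             2
ubiquitous              1
```

The 15 ancestral absences plus the 2 recent gains account for the 17
root-absent types; 9 of the 10 CNN types given elevated in-clade loss are
recovered as clade-specific losses. Tracing the two gained genes against
all other tRNA genes in the dataset:

```python
traces = trace_candidate_gains(matrix, categories, genes)
print(traces[["genome_id", "trna_type", "mechanism",
              "changed_positions", "identity"]].to_string(index=False))
```

```
genome_id trna_type              mechanism changed_positions  identity
     G041   Thr-AGU anticodon_substitution                34    0.9444
     G042   Ala-AGC    anticodon_insertion                      0.9726
```

Both planted mechanisms are recovered: a point substitution at the wobble
position (34) and a single-base insertion inside the anticodon.

The same analysis runs from the shell:

```sh
trnaevo simulate --n-tips 64 --seed 7 --out data/
trnaevo all --config config.yaml   # matrix, absence stats, categories,
                                   # events, gain traces, group statistics
```

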