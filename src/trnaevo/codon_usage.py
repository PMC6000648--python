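"""Per-genome codon usage: counts, frequency ranks, optimal codons, and
NNG proportions by degeneracy class.

Optimal codons are found by the comparison method: genes annotated with
transcription/translation keywords (ribosomal proteins excluded) form the
"highly expressed" set, and for each amino-acid family the most used codon
in that set is the optimal codon.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .decoding import GeneticCode

#: default keyword config for the high/low-expression gene partition.
#: Matching is case-insensitive substring; ribosomal exclusion wins.
DEFAULT_KEYWORDS = {
    "ribosomal": ["ribosomal protein", "ribosomal subunit protein"],
    "high": [
        "translation",
        "transcription",
        "elongation factor",
        "initiation factor",
        "release factor",
        "rna polymerase",
        "trna ligase",
        "trna synthetase",
        "aminoacyl",
    ],
}

#: degeneracy classes compared for NNG proportions; threefold (Ile) and
#: single-codon families (Met, Trp) are excluded.
DEGENERACY_CLASSES = {"twofold": 2, "fourfold": 4, "sixfold": 6}


@dataclass
class CodonUsageTable:
    """Counts over the 61 sense codons for one genome (or gene set)."""

    genome_id: str
    counts: pd.Series  # indexed by sense codon, int
    excluded: int = 0  # stops + ambiguous + trailing partial codons

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> pd.Series:
        tot = self.total
        if tot == 0:
            return self.counts.astype(float)
        return self.counts / tot


@dataclass
class GenePartition:
    high_ids: set[str] = field(default_factory=set)
    low_ids: set[str] = field(default_factory=set)
    excluded_ids: set[str] = field(default_factory=set)


def _sense_index(code: GeneticCode) -> list[str]:
    return sorted(code.sense_codons)


def count_codons(
    cds_records,
    genome_id: str = "",
    code: GeneticCode | None = None,
    gene_ids: set[str] | None = None,
) -> CodonUsageTable:
    """Count sense codons over CDS records.

    ``cds_records`` is an iterable of Bio.SeqRecord or ``(id, seq)`` pairs.
    Reading frame starts at position 1 of each CDS.  Stop codons, codons
    containing ambiguous bases, and trailing partial codons are excluded
    from the 61-codon counts but tallied in ``excluded``.  ``gene_ids``
    restricts counting to those record ids (used for the high/low split).
    """
    code = code or GeneticCode.standard()
    counter: Counter[str] = Counter()
    excluded = 0
    n_records = 0
    for rec in cds_records:
        rid, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        if gene_ids is not None and rid not in gene_ids:
            continue
        n_records += 1
        s = seq.strip().upper().replace("T", "U")
        if len(s) % 3:
            warnings.warn(
                f"CDS {rid}: length {len(s)} not divisible by 3; trailing "
                f"{len(s) % 3} base(s) ignored",
                stacklevel=2,
            )
            excluded += 1
        for i in range(0, len(s) - 2, 3):
            codon = s[i : i + 3]
            if codon in code.sense_codons:
                counter[codon] += 1
            else:
                excluded += 1
    if n_records == 0:
        raise ValueError("no CDS records to count")
    idx = _sense_index(code)
    counts = pd.Series([counter.get(c, 0) for c in idx], index=idx, dtype=int)
    return CodonUsageTable(genome_id=genome_id, counts=counts, excluded=excluded)


def rank_codon_frequencies(table: CodonUsageTable) -> pd.Series:
    """Frequency ranks over the 61 codons: most frequent gets rank 61.

    Ties share the mean of their rank range (average ranking), so the ranks
    are always a permutation-with-ties of 1..61.
    """
    return table.counts.rank(method="average", ascending=True)


def partition_by_annotation(
    gene_table: pd.DataFrame, keywords: dict | None = None
) -> GenePartition:
    """Split genes into high/low expression sets from product descriptions.

    ``gene_table`` needs columns ``gene_id`` and ``product``.  Ribosomal
    proteins are excluded outright; of the rest, products containing a
    transcription/translation keyword go to ``high``, everything else to
    ``low``.  Matching is case-insensitive substring.
    """
    if gene_table is None or len(gene_table) == 0:
        raise ValueError("empty gene table")
    kw = keywords or DEFAULT_KEYWORDS
    ribo = [k.lower() for k in kw["ribosomal"]]
    high = [k.lower() for k in kw["high"]]
    part = GenePartition()
    for gid, product in zip(gene_table["gene_id"], gene_table["product"]):
        p = str(product).lower()
        if any(k in p for k in ribo):
            part.excluded_ids.add(gid)
        elif any(k in p for k in high):
            part.high_ids.add(gid)
        else:
            part.low_ids.add(gid)
    if not part.high_ids:
        warnings.warn("no genes matched high-expression keywords", stacklevel=2)
    return part


def identify_optimal_codons(
    high_table: CodonUsageTable, code: GeneticCode | None = None
) -> pd.DataFrame:
    """Most used codon per synonymous family in the highly expressed set.

    Returns a DataFrame indexed by amino acid with columns ``codon``,
    ``tie`` (True when the maximum is shared; broken lexicographically) and
    ``defined`` (False when the family has zero usage).  Single-codon
    families (Met, Trp) are reported trivially.
    """
    code = code or GeneticCode.standard()
    rows = {}
    for aa in sorted(code.amino_acids()):
        fam = sorted(code.synonymous_family(aa))
        sub = high_table.counts.loc[fam]
        total = int(sub.sum())
        if total == 0:
            rows[aa] = {"codon": None, "tie": False, "defined": False}
            continue
        best = int(sub.max())
        winners = [c for c in fam if sub[c] == best]
        rows[aa] = {"codon": winners[0], "tie": len(winners) > 1, "defined": True}
    return pd.DataFrame.from_dict(rows, orient="index")


def degeneracy_class_families(code: GeneticCode | None = None) -> dict[str, list[str]]:
    """Amino acids grouped by synonymous-family size (two/four/sixfold)."""
    code = code or GeneticCode.standard()
    out: dict[str, list[str]] = {name: [] for name in DEGENERACY_CLASSES}
    for aa in sorted(code.amino_acids()):
        size = len(code.synonymous_family(aa))
        for name, n in DEGENERACY_CLASSES.items():
            if size == n:
                out[name].append(aa)
    return out


def nng_family_proportions(
    table: CodonUsageTable, code: GeneticCode | None = None
) -> dict[str, float | None]:
    """Proportion of family usage falling on NNG codons, per degeneracy class.

    For each class the member families' counts are pooled: NNG-codon counts
    divided by total counts of those families.  A class with zero usage is
    reported as None with a warning.
    """
    code = code or GeneticCode.standard()
    classes = degeneracy_class_families(code)
    out: dict[str, float | None] = {}
    for name, aas in classes.items():
        codons = [c for aa in aas for c in sorted(code.synonymous_family(aa))]
        total = int(table.counts.loc[codons].sum())
        if total == 0:
            warnings.warn(f"{name} families have zero usage", stacklevel=2)
            out[name] = None
            continue
        nng = int(table.counts.loc[[c for c in codons if c.endswith("G")]].sum())
        out[name] = nng / total
    return out


def optimal_nng_frequency(optimal: pd.DataFrame) -> float:
    """Fraction of defined optimal codons that are NNG codons."""
    defined = optimal[optimal["defined"]]
    if len(defined) == 0:
        return float("nan")
    return float(defined["codon"].str.endswith("G").mean())


def usage_table_from_fasta(
    path, genome_id: str = "", gene_ids: set[str] | None = None
) -> CodonUsageTable:
    """Count codons straight from a CDS FASTA file."""
    from Bio import SeqIO

    return count_codons(
        SeqIO.parse(str(path), "fasta"), genome_id=genome_id, gene_ids=gene_ids
    )


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, product."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "product"} - set(tab.columns)
    if missing:
        raise ValueError(f"gene table missing column(s): {sorted(missing)}")
    return tab
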