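"""Synthetic archaeal-style datasets with known ground truth.

Generates (i) a random rooted species tree, (ii) tRNA gene repertoires
evolved down that tree from a 44-type root (all sense anticodons except the
16 ANN types and UAU, i.e. 17 types ancestrally absent), with elevated loss
of designated CNN types inside one named clade and rare gains created by
anticodon point mutation or single-base insertion in an existing gene, and
(iii) codon-biased CDS sets whose "highly expressed" genes prefer planted
optimal codons.  Every event is logged in a :class:`SimTruth` so each
pipeline stage can be tested for recovery; replaying the log from the root
reproduces the emitted matrix exactly.

A single seed drives everything through documented sub-seeding (tree,
repertoire, each genome's CDS set draw from independent child seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decoding import GeneticCode, core_repertoire, family_members
from .phylo import Event, branch_id, _leaf_sets, replay_events
from .repertoire import TRNAGene, anticodon_label, build_repertoire_matrix

RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class CDSParams:
    """Codon-biased CDS simulation for one genome.

    ``bias_high``/``bias_low`` weight the planted preferred codon against
    the other family members (1 = uniform, no preference) in the
    high/low-expression gene sets.
    """

    n_genes: int = 1000
    n_codons: int = 300
    high_frac: float = 0.1
    ribosomal_frac: float = 0.05
    bias_high: float = 50.0
    bias_low: float = 1.0


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the repertoire simulation.

    Defaults mirror the archaeal setting: a 44-type root repertoire with
    one copy per type except CAU (1 iMet + 2 eMet copies), a low background
    per-branch loss probability, strongly elevated loss of 10 CNN types
    inside one designated clade, and two rare gains by anticodon mutation.
    """

    n_tips: int = 64
    loss_prob: float = 0.02
    clade_loss_prob: float = 0.8
    clade_label: str = "LossClade"
    clade_min_tips: int = 6
    clade_max_tips: int = 16
    n_elevated: int = 10
    elevated_family: str = "CNN"
    n_gains: int = 2
    gain_mechanisms: tuple[str, ...] = ("substitution", "insertion")
    imet_copies: int = 1
    emet_copies: int = 2
    seq_length: int = 72
    noise_rate: float = 0.02
    gain_intron_prob: float = 0.5
    intron_length: int = 14
    cds: CDSParams = field(default_factory=CDSParams)

    def __post_init__(self) -> None:
        for p in (self.loss_prob, self.clade_loss_prob, self.noise_rate,
                  self.gain_intron_prob, self.cds.high_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.cds.bias_high < 1 or self.cds.bias_low < 1:
            raise ValueError("bias strengths must be >= 1")


@dataclass
class GainRecord:
    tip: str
    trna_type: str  # column label of the gained type
    anticodon: str
    mechanism: str  # substitution | insertion
    source_type: str  # column label of the mutated source
    source_anticodon: str


@dataclass
class SimTruth:
    """Ground-truth log of a repertoire simulation."""

    events: list[Event]
    true_categories: dict[str, str]  # column label -> planted category
    clade_label: str
    clade_tips: frozenset[str]
    elevated_types: tuple[str, ...]  # column labels under elevated clade loss
    gains: list[GainRecord]
    root_types: frozenset[str]  # column labels present at the root
    copy_numbers: dict[str, int]  # column label -> copies when present
    seed: int
    optimal_codons: dict[str, dict[str, str]] = field(default_factory=dict)

    def expected_presence(self, tree: dendropy.Tree) -> pd.DataFrame:
        """Replay the event log; tips x type-label 0/1 DataFrame."""
        types = sorted(set(self.true_categories))
        by_type: dict[str, list[Event]] = {t: [] for t in types}
        for ev in self.events:
            by_type[ev.trna_type].append(ev)
        cols = {}
        for t in types:
            cols[t] = replay_events(tree, by_type[t], root_present=t in self.root_types)
        return pd.DataFrame(cols).astype(int)


def _sub_seed(seed: int, stream: int) -> int:
    """Derived child seed (kept below 2**31)."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Random rooted bifurcating tree with tips G001..Gnnn (coalescent-style
    random joins, deterministic for a fixed seed)."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(_sub_seed(seed, 0))
    nodes = [f"G{i + 1:03d}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    from .phylo import load_tree

    return load_tree(nodes[0] + ";")


def designate_clade(tree: dendropy.Tree, params: SimParams) -> frozenset[str]:
    """Label one internal node as the elevated-loss clade; returns its tips.

    The first preorder internal node (excluding the root) whose tip count
    falls in [clade_min_tips, clade_max_tips] is chosen; if none qualifies,
    the node closest in size to the midpoint of the range.
    """
    leaf_sets = _leaf_sets(tree)
    target = (params.clade_min_tips + params.clade_max_tips) / 2
    best, best_gap = None, None
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        size = len(leaf_sets[node])
        if params.clade_min_tips <= size <= params.clade_max_tips:
            node.label = params.clade_label
            return leaf_sets[node]
        gap = abs(size - target)
        if best is None or gap < best_gap:
            best, best_gap = node, gap
    best.label = params.clade_label
    return leaf_sets[best]


def _random_seq(rng: np.random.Generator, length: int, anticodon: str, start: int = 34) -> str:
    seq = rng.choice(RNA, size=length)
    seq[start - 1 : start + 2] = list(anticodon)
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, rate: float, protect: tuple[int, int]) -> str:
    """Per-site substitution noise outside the protected 1-based window."""
    if rate == 0:
        return seq
    chars = list(seq)
    lo, hi = protect
    for i in range(len(chars)):
        if lo - 1 <= i <= hi - 1:
            continue
        if rng.random() < rate:
            options = [b for b in "ACGU" if b != chars[i]]
            chars[i] = options[rng.integers(3)]
    return "".join(chars)


def evolve_repertoires(
    tree: dendropy.Tree, params: SimParams, seed: int
) -> tuple[pd.DataFrame, SimTruth, list[TRNAGene]]:
    """Evolve the root repertoire tipward and emit genes + truth.

    Per branch each type present in the parent is lost with the branch's
    loss probability -- ``clade_loss_prob`` for elevated types on branches
    inside the designated clade (including its stem edge), ``loss_prob``
    otherwise.  Gains are then planted on ``n_gains`` distinct terminal
    branches by mutating the anticodon of a type present at that tip;
    A-starting targets are always root-absent, so every gain creates a
    genuinely new type.  Returns (matrix, truth, genes); the matrix is the
    one produced by feeding the genes through the repertoire builder.
    """
    code = GeneticCode.standard()
    rng = np.random.default_rng(_sub_seed(seed, 1))
    leaf_sets = _leaf_sets(tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    root_anticodons = sorted(core_repertoire(code))
    label_of = {a: anticodon_label(a, code) for a in root_anticodons}
    copy_numbers = {label_of[a]: 1 for a in root_anticodons}
    copy_numbers[label_of["CAU"]] = params.imet_copies + params.emet_copies

    clade_tips = designate_clade(tree, params)
    clade_node = next(
        n for n in tree.preorder_internal_node_iter() if n.label == params.clade_label
    )
    in_clade = {clade_node} | set(clade_node.preorder_iter())

    family = sorted(family_members(params.elevated_family, code) & set(root_anticodons))
    elevated = sorted(rng.choice(family, size=min(params.n_elevated, len(family)), replace=False))

    events: list[Event] = []
    state: dict = {tree.seed_node: set(root_anticodons)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = set(state[node.parent_node])
        kept = set()
        for ac in sorted(parent):
            p = (
                params.clade_loss_prob
                if (ac in elevated and node in in_clade)
                else params.loss_prob
            )
            if rng.random() < p:
                events.append(
                    Event(label_of[ac], "loss", branch_id(node, leaf_sets), node=node)
                )
            else:
                kept.add(ac)
        state[node] = kept

    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    gain_tips = sorted(rng.choice(tips, size=min(params.n_gains, len(tips)), replace=False))
    gains: list[GainRecord] = []
    gained_refs: dict[str, tuple[str, str]] = {}  # new anticodon -> (mechanism, source ac)
    for k, tip in enumerate(gain_tips):
        mech = params.gain_mechanisms[k % len(params.gain_mechanisms)]
        leaf = leaf_by_label[tip]
        present = sorted(state[leaf])
        order = list(rng.permutation(present))
        chosen = None
        for src in order:
            if src == "CAU":
                continue
            target = "A" + src[1:] if mech == "substitution" else "A" + src[0] + src[1]
            if target in state[leaf] or target in gained_refs:
                continue
            chosen = (src, target)
            break
        if chosen is None:
            continue
        src, target = chosen
        tlabel = anticodon_label(target, code)
        state[leaf] = state[leaf] | {target}
        gained_refs[target] = (mech, src)
        copy_numbers[tlabel] = 1
        events.append(Event(tlabel, "gain", tip, note=mech, node=leaf))
        gains.append(
            GainRecord(tip, tlabel, target, mech, label_of[src], src)
        )

    # reference sequence per type (anticodon at positions 34-36)
    refs: dict[str, str] = {}
    for ac in root_anticodons:
        refs[ac] = _random_seq(rng, params.seq_length, ac)
    for target, (mech, src) in sorted(gained_refs.items()):
        base = refs[src]
        if mech == "substitution":
            refs[target] = base[:33] + "A" + base[34:]
        else:
            refs[target] = base[:33] + "A" + base[33:]

    genes: list[TRNAGene] = []
    for tip in tips:
        leaf = leaf_by_label[tip]
        pos = 1
        n = 0
        for ac in sorted(state[leaf]):
            label = label_of.get(ac) or anticodon_label(ac, code)
            tags: list[str | None]
            if ac == "CAU":
                tags = ["iMet"] * params.imet_copies + ["eMet"] * params.emet_copies
            else:
                tags = [None] * copy_numbers.get(label, 1)
            for tag in tags:
                n += 1
                seq = _mutate(rng, refs[ac], params.noise_rate, (34, 36))
                introns: list[tuple[int, int]] = []
                if ac in gained_refs and rng.random() < params.gain_intron_prob:
                    ilen = params.intron_length
                    intron = "".join(rng.choice(RNA, size=ilen))
                    seq = seq[:37] + intron + seq[37:]
                    introns = [(38, 37 + ilen)]
                aa3 = label.split("-")[0] if not tag else "Met"
                genes.append(
                    TRNAGene(
                        genome_id=tip,
                        isotype=aa3,
                        anticodon=ac,
                        contig=f"{tip}.chr",
                        start=pos,
                        end=pos + len(seq) - 1,
                        strand="+",
                        intron_intervals=introns,
                        sequence=seq,
                        met_tag=tag,
                        gene_id=f"{tip}.trna{n}",
                        anticodon_start=34,
                    )
                )
                pos += len(seq) + 50

    matrix = build_repertoire_matrix(genes, tips, code=code)

    true_categories: dict[str, str] = {}
    gained_labels = {g.trna_type for g in gains}
    elevated_labels = tuple(label_of[a] for a in elevated)
    for col in matrix.columns:
        if col in gained_labels:
            true_categories[col] = "recent_gain"
        elif col in elevated_labels:
            true_categories[col] = "clade_specific_loss"
        elif label_anticodon_root_absent(col, root_anticodons, code):
            true_categories[col] = "ancestral_absence"
        else:
            true_categories[col] = "background"

    truth = SimTruth(
        events=events,
        true_categories=true_categories,
        clade_label=params.clade_label,
        clade_tips=clade_tips,
        elevated_types=elevated_labels,
        gains=gains,
        root_types=frozenset(label_of[a] for a in root_anticodons),
        copy_numbers=copy_numbers,
        seed=seed,
    )
    return matrix, truth, genes


def label_anticodon_root_absent(label: str, root_anticodons, code) -> bool:
    from .repertoire import label_anticodon

    return label_anticodon(label) not in set(root_anticodons)


def plant_optimal_codons(rng: np.random.Generator, code: GeneticCode | None = None) -> dict[str, str]:
    """Pick one preferred codon per multi-codon synonymous family."""
    code = code or GeneticCode.standard()
    out = {}
    for aa in sorted(code.amino_acids()):
        fam = sorted(code.synonymous_family(aa))
        out[aa] = fam[rng.integers(len(fam))] if len(fam) > 1 else fam[0]
    return out


HIGH_PRODUCTS = [
    "translation initiation factor IF-2",
    "translation elongation factor EF-1 alpha",
    "DNA-directed RNA polymerase subunit B",
    "transcription elongation factor Spt5",
    "peptide chain release factor aRF-1",
    "methionine tRNA ligase",
]
RIBO_PRODUCTS = ["30S ribosomal protein S7", "50S ribosomal protein L2"]
LOW_PRODUCTS = [
    "hypothetical protein",
    "ABC transporter permease",
    "cation efflux pump",
    "glycosyltransferase family protein",
]


def simulate_cds_set(
    params: CDSParams,
    optimal_map: Mapping[str, str],
    seed: int,
    genome_id: str = "G001",
    code: GeneticCode | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate a codon-biased CDS FASTA set and its gene annotation table.

    Amino acids are drawn uniformly; within each synonymous family the
    planted preferred codon carries weight ``bias`` against 1 for the
    others (``bias_high`` for high-expression and ribosomal genes,
    ``bias_low`` elsewhere).  Product descriptions carry the keywords the
    annotation partitioner expects; one stop codon is appended per gene.
    """
    code = code or GeneticCode.standard()
    rng = np.random.default_rng(seed)
    aas = sorted(code.amino_acids())
    fams = {aa: sorted(code.synonymous_family(aa)) for aa in aas}

    n = params.n_genes
    roles = np.array(["low"] * n, dtype=object)
    n_high = int(round(params.high_frac * n))
    n_ribo = int(round(params.ribosomal_frac * n))
    idx = rng.permutation(n)
    roles[idx[:n_high]] = "high"
    roles[idx[n_high : n_high + n_ribo]] = "ribo"

    aa_matrix = rng.integers(len(aas), size=(n, params.n_codons))
    codon_matrix = np.empty((n, params.n_codons), dtype="<U3")
    for group, bias in (("high", params.bias_high), ("ribo", params.bias_high),
                        ("low", params.bias_low)):
        rows = np.where(roles == group)[0]
        if len(rows) == 0:
            continue
        sub = aa_matrix[rows]
        sub_codons = np.empty(sub.shape, dtype="<U3")
        for ai, aa in enumerate(aas):
            fam = fams[aa]
            w = np.array([bias if c == optimal_map[aa] else 1.0 for c in fam])
            w /= w.sum()
            mask = sub == ai
            count = int(mask.sum())
            if count == 0:
                continue
            draws = rng.choice(len(fam), size=count, p=w)
            sub_codons[mask] = np.array(fam, dtype="<U3")[draws]
        codon_matrix[rows] = sub_codons

    records, rows = [], []
    for i in range(n):
        gid = f"{genome_id}.g{i + 1:05d}"
        seq = "".join(codon_matrix[i]) + "UAA"
        if roles[i] == "high":
            product = HIGH_PRODUCTS[i % len(HIGH_PRODUCTS)]
        elif roles[i] == "ribo":
            product = RIBO_PRODUCTS[i % len(RIBO_PRODUCTS)]
        else:
            product = LOW_PRODUCTS[i % len(LOW_PRODUCTS)]
        records.append(
            SeqRecord(Seq(seq.replace("U", "T")), id=gid, description=product)
        )
        rows.append({"gene_id": gid, "product": product, "role": roles[i]})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset emission in the dialects the readers consume


def _write_trnascan_tabular(genes: list[TRNAGene], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tCove\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
        fh.write("--------\t------\t----\t------\t----\t-----\t-----\t----\t------\n")
        for i, g in enumerate(genes, 1):
            ib = ie = 0
            if g.intron_intervals:
                a, b = g.intron_intervals[0]
                ib, ie = g.start + a - 1, g.start + b - 1
            isotype = g.met_tag or g.isotype
            fh.write(
                f"{g.contig}\t{i}\t{g.start}\t{g.end}\t{isotype}\t"
                f"{g.anticodon.replace('U', 'T')}\t{ib}\t{ie}\t70.0\n"
            )


def _write_trna_fasta(genes: list[TRNAGene], path: Path) -> None:
    # spliced (intron-removed) sequences, GtRNAdb-style headers
    with open(path, "w") as fh:
        for g in genes:
            isotype = g.met_tag or g.isotype
            fh.write(f">{g.gene_id} {isotype} ({g.anticodon}) {len(g.spliced_sequence())} bp\n")
            fh.write(g.spliced_sequence() + "\n")


def simulate_metadata(
    tips: list[str], clade_tips: frozenset[str], clade_label: str, seed: int
) -> pd.DataFrame:
    """Genome metadata emulating reduced genomes/GC inside the loss clade.

    In-clade genomes draw size ~ N(1.8 Mb, 0.2 Mb) and GC ~ N(0.35, 0.03);
    others N(2.6 Mb, 0.4 Mb) and N(0.46, 0.04) -- the group contrasts
    reported for the reduced-genome clades.
    """
    rng = np.random.default_rng(_sub_seed(seed, 2))
    rows = []
    for tip in tips:
        if tip in clade_tips:
            size = rng.normal(1.8e6, 0.2e6)
            gc = rng.normal(0.35, 0.03)
            clade = clade_label
        else:
            size = rng.normal(2.6e6, 0.4e6)
            gc = rng.normal(0.46, 0.04)
            clade = "Other"
        rows.append(
            {
                "genome_id": tip,
                "genome_size": int(max(5e5, size)),
                "gc": float(np.clip(gc, 0.2, 0.7)),
                "clade": clade,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")


def write_dataset(
    outdir,
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    truth: SimTruth,
    genes: list[TRNAGene],
    metadata: pd.DataFrame,
    cds_by_genome: Mapping[str, tuple[list[SeqRecord], pd.DataFrame]] | None = None,
) -> None:
    """Write a full synthetic dataset in the pipeline's input dialects."""
    from Bio import SeqIO

    out = Path(outdir)
    (out / "trna").mkdir(parents=True, exist_ok=True)
    tree.write(path=str(out / "tree.nwk"), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    for tip in matrix.index:
        tip_genes = [g for g in genes if g.genome_id == tip]
        _write_trnascan_tabular(tip_genes, out / "trna" / f"{tip}.tsv")
        _write_trna_fasta(tip_genes, out / "trna" / f"{tip}.fasta")
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    with open(out / "clades.yaml", "w") as fh:
        yaml.safe_dump({truth.clade_label: sorted(truth.clade_tips)}, fh)
    pd.DataFrame(
        [
            {"trna_type": e.trna_type, "event": e.event, "branch_id": e.branch_id,
             "note": e.note}
            for e in truth.events
        ]
    ).to_csv(out / "truth_events.tsv", sep="\t", index=False)
    pd.Series(truth.true_categories, name="true_category").rename_axis(
        "trna_type"
    ).to_csv(out / "truth_categories.tsv", sep="\t")
    if cds_by_genome:
        (out / "cds").mkdir(exist_ok=True)
        for gid, (records, table) in cds_by_genome.items():
            SeqIO.write(records, str(out / "cds" / f"{gid}.fasta"), "fasta")
            table.to_csv(out / "cds" / f"{gid}.genes.tsv", sep="\t", index=False)


def simulate_dataset(
    params: SimParams, seed: int, with_cds: bool = False, cds_genomes: int = 4
) -> dict:
    """One-call simulation: tree, repertoires, metadata and (optionally) CDS
    sets for the first ``cds_genomes`` genomes.  Returns a dict bundle."""
    tree = simulate_tree(params.n_tips, seed)
    matrix, truth, genes = evolve_repertoires(tree, params, seed)
    tips = list(matrix.index)
    metadata = simulate_metadata(tips, truth.clade_tips, truth.clade_label, seed)
    cds = {}
    if with_cds:
        code = GeneticCode.standard()
        for k, gid in enumerate(tips[:cds_genomes]):
            g_seed = _sub_seed(seed, 100 + k)
            rng = np.random.default_rng(g_seed)
            optimal = plant_optimal_codons(rng, code)
            truth.optimal_codons[gid] = optimal
            cds[gid] = simulate_cds_set(params.cds, optimal, g_seed, gid, code)
    return {
        "tree": tree,
        "matrix": matrix,
        "truth": truth,
        "genes": genes,
        "metadata": metadata,
        "cds": cds,
        "params": params,
        "seed": seed,
    }
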