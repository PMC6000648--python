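"""End-to-end orchestration of the repertoire analysis.

``run_pipeline`` ties the stages together for a directory of per-genome
inputs: build the repertoire matrix, absence statistics, codon-usage ranks
and optimal codons (when CDS sets are supplied), history categories and
gain/loss events on the species tree, traces for candidate gains, and the
in-group vs out-group statistical report.  All analysis stages are
deterministic for fixed inputs, so re-running a config reproduces the
output bundle byte for byte; a JSON manifest records parameters, versions
and warnings.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_usage import (
    identify_optimal_codons,
    optimal_nng_frequency,
    partition_by_annotation,
    rank_codon_frequencies,
    read_gene_table,
    usage_table_from_fasta,
)
from .gains import AlignScoring, trace_candidate_gains
from .phylo import HistoryParams, load_tree, map_matrix_events, read_clades, tip_labels
from .repertoire import (
    absence_summary,
    build_repertoire_matrix,
    parse_trna_annotations,
    read_genome_metadata,
    write_matrix,
)
from .stats import group_compare_report

_DIALECT_EXT = {"trnascan_tabular": ".tsv", "gff3": ".gff3", "gtrnadb_fasta": ".fasta"}


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for a full pipeline run."""

    trna_dir: str
    tree: str
    out_dir: str
    trna_dialect: str = "gtrnadb_fasta"
    metadata: str | None = None
    clades: str | None = None
    cds_dir: str | None = None
    ruleset: str | None = None
    split_met: bool = False
    gain_max: int = 2
    background_frac: float = 0.75
    identity_threshold: float = 0.6
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    mw_mode: str = "auto"
    seed: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"extra"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.trna_dialect not in _DIALECT_EXT:
            raise ValueError(f"unknown dialect {self.trna_dialect!r}")
        for name in ("trna_dir", "tree", "metadata", "clades", "cds_dir", "ruleset"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{name}: {val} does not exist")


def _collect_genes(cfg: PipelineConfig):
    ext = _DIALECT_EXT[cfg.trna_dialect]
    files = sorted(Path(cfg.trna_dir).glob(f"*{ext}"))
    files = [f for f in files if not f.name.endswith(".genes.tsv")]
    if not files:
        raise FileNotFoundError(f"no {ext} files in {cfg.trna_dir}")
    genes = []
    genome_ids = []
    for f in files:
        gid = f.stem
        genome_ids.append(gid)
        genes.extend(parse_trna_annotations(f, cfg.trna_dialect, genome_id=gid))
    return genes, genome_ids


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a name -> path map of the written outputs."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        genes, genome_ids = _collect_genes(cfg)
        tree = load_tree(cfg.tree)
        tips = set(tip_labels(tree))
        if tips != set(genome_ids):
            raise ValueError(
                "tree/annotation mismatch before computation: "
                f"only in tree {sorted(tips - set(genome_ids))}, "
                f"only in annotations {sorted(set(genome_ids) - tips)}"
            )
        clades = read_clades(cfg.clades, tree) if cfg.clades else {}
        meta = read_genome_metadata(cfg.metadata) if cfg.metadata else pd.DataFrame(index=genome_ids)

        # repertoire matrix + absence statistics
        matrix = build_repertoire_matrix(genes, genome_ids, split_met=cfg.split_met)
        outputs["matrix"] = out / "matrix.tsv"
        write_matrix(matrix, outputs["matrix"])
        per_genome, per_type = absence_summary(matrix)
        outputs["genome_summary"] = out / "genome_summary.tsv"
        per_genome.to_csv(outputs["genome_summary"], sep="\t", index_label="genome_id")
        outputs["absence_by_type"] = out / "absence_by_type.tsv"
        per_type.to_csv(outputs["absence_by_type"], sep="\t", index_label="trna_type")

        # codon usage (optional)
        nng_optimal: dict[str, float] = {}
        if cfg.cds_dir:
            rank_rows, opt_rows = {}, []
            for fa in sorted(Path(cfg.cds_dir).glob("*.fasta")):
                gid = fa.stem
                table = usage_table_from_fasta(fa, genome_id=gid)
                rank_rows[gid] = rank_codon_frequencies(table)
                gene_tab_path = fa.with_suffix("").with_suffix(".genes.tsv")
                if gene_tab_path.exists():
                    part = partition_by_annotation(read_gene_table(gene_tab_path))
                    high = usage_table_from_fasta(fa, genome_id=gid, gene_ids=part.high_ids)
                    optimal = identify_optimal_codons(high)
                    nng_optimal[gid] = optimal_nng_frequency(optimal)
                    for aa, row in optimal.iterrows():
                        opt_rows.append(
                            {"genome_id": gid, "amino_acid": aa,
                             "codon": row["codon"] or "", "tie": row["tie"],
                             "defined": row["defined"]}
                        )
            if rank_rows:
                outputs["codon_ranks"] = out / "codon_ranks.tsv"
                pd.DataFrame(rank_rows).T.to_csv(
                    outputs["codon_ranks"], sep="\t", index_label="genome_id"
                )
            if opt_rows:
                outputs["optimal_codons"] = out / "optimal_codons.tsv"
                pd.DataFrame(opt_rows).to_csv(outputs["optimal_codons"], sep="\t", index=False)

        # histories on the tree
        params = HistoryParams(gain_max=cfg.gain_max, background_frac=cfg.background_frac)
        events, categories = map_matrix_events(tree, matrix, clades, params)
        outputs["events"] = out / "events.tsv"
        events.to_csv(outputs["events"], sep="\t", index=False)
        outputs["categories"] = out / "type_categories.tsv"
        categories.to_csv(outputs["categories"], sep="\t", index_label="trna_type")

        # gain tracing
        scoring = AlignScoring(cfg.match, cfg.mismatch, cfg.gap)
        traces = trace_candidate_gains(
            matrix, categories, genes, scoring, cfg.identity_threshold
        )
        outputs["gain_traces"] = out / "gain_traces.tsv"
        traces.to_csv(outputs["gain_traces"], sep="\t", index=False)

        # group statistics (needs clades + metadata)
        if clades and len(meta.columns):
            in_group = frozenset().union(*clades.values())
            extra = {"nng_optimal_codon_frac": nng_optimal} if (
                nng_optimal and set(nng_optimal) == set(matrix.index)
            ) else None
            report = group_compare_report(
                matrix, meta, in_group, group_label="+".join(sorted(clades)),
                extra_variables=extra, mode=cfg.mw_mode,
            )
            outputs["group_stats"] = out / "group_stats.tsv"
            report.to_csv(outputs["group_stats"], sep="\t", index=False)

        caught = [str(w.message) for w in wlist]

    manifest = {
        "tool": "trnaevo",
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "extra"
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
        "n_genomes": len(genome_ids),
        "n_genes": len(genes),
        "warnings": caught,
    }
    outputs["manifest"] = out / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs
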