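"""tRNA gene annotation parsing and the genome x anticodon copy-number matrix.

Readers for three annotation dialects (tRNAscan-SE tabular, GFF3, FASTA with
GtRNAdb-style headers) produce :class:`TRNAGene` records; those are counted
into a pandas DataFrame with one row per genome and one column per sense
anticodon type, labelled ``Aa-NNN`` (three-letter amino acid + anticodon).
The CAU column can be split into initiator and elongator Met when the
annotations carry iMet/eMet tags.

All coordinates are 1-based inclusive (the tRNAscan-SE convention); intron
intervals are positions within the gene sequence, 5'->3'.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .decoding import (
    AA_THREE,
    DecodingError,
    GeneticCode,
    normalize_rna,
    sense_anticodons,
    watson_crick_codon,
)

log = logging.getLogger(__name__)

IMET_LABEL = "iMet-CAU"
EMET_LABEL = "eMet-CAU"


class ParseError(ValueError):
    """Malformed annotation input (carries the offending line number)."""


@dataclass
class TRNAGene:
    """One annotated tRNA gene.

    ``anticodon`` is RNA, 5'->3'; ``undetermined`` marks genes whose
    anticodon could not be called (e.g. "???" / NNN in tRNAscan output) --
    such genes are excluded from matrix building.  ``met_tag`` is
    ``"iMet"``/``"eMet"`` when the annotation distinguishes initiator from
    elongator Met, else None.  ``anticodon_start`` is the 1-based position
    of the anticodon within the intron-spliced gene sequence (canonically
    34) when known.
    """

    genome_id: str
    isotype: str
    anticodon: str
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    sequence: str | None = None
    pseudo: bool = False
    undetermined: bool = False
    met_tag: str | None = None
    gene_id: str = ""
    anticodon_start: int | None = None

    def __post_init__(self) -> None:
        if not self.undetermined:
            self.anticodon = normalize_rna(self.anticodon)
        if self.start and self.end and self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id or self.contig}: start {self.start} > end {self.end}"
            )

    def spliced_sequence(self) -> str | None:
        """Gene sequence with annotated introns removed (None if no seq)."""
        if self.sequence is None:
            return None
        seq = self.sequence
        keep = []
        cut = sorted(self.intron_intervals)
        prev = 1
        for a, b in cut:
            keep.append(seq[prev - 1 : a - 1])
            prev = b + 1
        keep.append(seq[prev - 1 :])
        return "".join(keep)


def anticodon_label(anticodon: str, code: GeneticCode | None = None) -> str:
    """Column label ``Aa-NNN`` for an anticodon (e.g. GAG -> "Leu-GAG")."""
    code = code or GeneticCode.standard()
    aa = code.amino_acid(watson_crick_codon(anticodon))
    return f"{AA_THREE[aa]}-{anticodon}"


def label_anticodon(label: str) -> str:
    """Inverse of :func:`anticodon_label`; handles the iMet/eMet columns."""
    return label.rsplit("-", 1)[1]


def matrix_columns(split_met: bool = False, code: GeneticCode | None = None) -> list[str]:
    """Ordered column labels for the repertoire matrix (61 or 62 columns)."""
    code = code or GeneticCode.standard()
    labels = sorted(anticodon_label(a, code) for a in sense_anticodons(code))
    if split_met:
        i = labels.index("Met-CAU")
        labels[i : i + 1] = [IMET_LABEL, EMET_LABEL]
    return labels


# ---------------------------------------------------------------------------
# Parsers


_UNDETERMINED = {"???", "NNN", ""}


def _parse_trnascan_tabular(path: Path, genome_id: str) -> list[TRNAGene]:
    genes: list[TRNAGene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            # three-line header of tRNAscan-SE -o output
            if line.startswith(("Sequence", "Name", "----")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 8:
                raise ParseError(f"{path}:{lineno}: expected >=8 columns, got {len(parts)}")
            try:
                seqname = parts[0].strip()
                begin, end = int(parts[2]), int(parts[3])
                isotype = parts[4].strip()
                anticodon = parts[5].strip().upper()
                ib, ie = int(parts[6]), int(parts[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = "+"
            if begin > end:
                begin, end = end, begin
                strand = "-"
            introns = []
            if ib and ie:
                lo, hi = min(ib, ie), max(ib, ie)
                # convert genomic intron bounds to gene-relative 1-based
                if strand == "+":
                    introns = [(lo - begin + 1, hi - begin + 1)]
                else:
                    introns = [(end - hi + 1, end - lo + 1)]
            note = " ".join(parts[9:]).lower() if len(parts) > 9 else ""
            undet = anticodon in _UNDETERMINED
            met_tag = isotype if isotype in ("iMet", "eMet") else None
            genes.append(
                TRNAGene(
                    genome_id=genome_id,
                    isotype="Met" if met_tag else isotype,
                    anticodon="" if undet else anticodon,
                    contig=seqname,
                    start=begin,
                    end=end,
                    strand=strand,
                    intron_intervals=introns,
                    pseudo="pseudo" in note,
                    undetermined=undet,
                    met_tag=met_tag,
                    gene_id=f"{seqname}.trna{parts[1].strip()}",
                )
            )
    return genes


_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _parse_gff3(path: Path, genome_id: str) -> list[TRNAGene]:
    genes: dict[str, TRNAGene] = {}
    order: list[str] = []
    introns: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr_s = cols
            attrs = {k.strip(): v.strip() for k, v in _GFF_ATTR.findall(attr_s)}
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            if ftype in ("tRNA", "tRNA_gene"):
                anticodon = attrs.get("anticodon", "").upper()
                undet = anticodon in _UNDETERMINED
                isotype = attrs.get("isotype", "")
                met_tag = isotype if isotype in ("iMet", "eMet") else None
                gid = attrs.get("ID", f"{seqid}:{start}-{end}")
                genes[gid] = TRNAGene(
                    genome_id=genome_id,
                    isotype="Met" if met_tag else isotype,
                    anticodon="" if undet else anticodon,
                    contig=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    pseudo=attrs.get("pseudo", "").lower() in ("true", "1", "yes"),
                    undetermined=undet,
                    met_tag=met_tag,
                    gene_id=gid,
                )
                order.append(gid)
            elif ftype == "intron":
                parent = attrs.get("Parent", "")
                introns.append((parent, start_i, end_i))
    for parent, s, e in introns:
        gene = genes.get(parent)
        if gene is None:
            log.warning("intron with unknown Parent=%s ignored", parent)
            continue
        if gene.strand == "+":
            gene.intron_intervals.append((s - gene.start + 1, e - gene.start + 1))
        else:
            gene.intron_intervals.append((gene.end - e + 1, gene.end - s + 1))
    return [genes[g] for g in order]


_GTRNADB_HEADER = re.compile(
    r"(?P<isotype>[A-Za-z]{3,4})\s*\((?P<anticodon>[A-Za-z?]{3})\)"
)


def _parse_gtrnadb_fasta(path: Path, genome_id: str) -> list[TRNAGene]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GTRNADB_HEADER.search(rec.description)
        if m is None:
            raise ParseError(
                f"{path}: header {rec.description!r} lacks 'Isotype (ANT)' token"
            )
        anticodon = m.group("anticodon").upper()
        undet = anticodon in _UNDETERMINED or "?" in anticodon
        isotype = m.group("isotype")
        met_tag = isotype if isotype in ("iMet", "eMet") else None
        genes.append(
            TRNAGene(
                genome_id=genome_id,
                isotype="Met" if met_tag else isotype,
                anticodon="" if undet else anticodon,
                contig=rec.id,
                start=1,
                end=len(rec.seq),
                sequence=str(rec.seq).upper().replace("T", "U"),
                undetermined=undet,
                met_tag=met_tag,
                gene_id=rec.id,
                pseudo="pseudo" in rec.description.lower(),
            )
        )
    return genes


_DIALECTS = {
    "trnascan_tabular": _parse_trnascan_tabular,
    "gff3": _parse_gff3,
    "gtrnadb_fasta": _parse_gtrnadb_fasta,
}


def parse_trna_annotations(
    path, dialect: str, genome_id: str | None = None
) -> list[TRNAGene]:
    """Parse a per-genome tRNA annotation file into :class:`TRNAGene` records.

    ``genome_id`` defaults to the file stem.  Genes with undetermined
    anticodons are returned flagged (``undetermined=True``) and are skipped
    by :func:`build_repertoire_matrix`.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    genes = _DIALECTS[dialect](path, gid)
    code = GeneticCode.standard()
    for g in genes:
        if g.undetermined or not g.isotype or g.isotype in ("Sup", "Undet"):
            continue
        try:
            aa = code.amino_acid(watson_crick_codon(g.anticodon))
        except (KeyError, DecodingError):
            continue
        expect = AA_THREE.get(aa, aa)
        if g.isotype not in (expect, aa):
            warnings.warn(
                f"{g.gene_id}: isotype {g.isotype} inconsistent with anticodon "
                f"{g.anticodon} (expected {expect})",
                stacklevel=2,
            )
    return genes


# ---------------------------------------------------------------------------
# Matrix assembly


def build_repertoire_matrix(
    genes: Iterable[TRNAGene],
    genome_ids: Sequence[str],
    split_met: bool = False,
    include_pseudo: bool = False,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Count genes into a genomes x anticodon-type copy-number matrix.

    Pseudogenes and undetermined anticodons are excluded by default, as are
    suppressor anticodons (Watson-Crick codon is a stop; warned).  With
    ``split_met`` the CAU column is divided into iMet-CAU/eMet-CAU using the
    genes' ``met_tag``; untagged CAU genes then count as eMet with a warning.
    """
    code = code or GeneticCode.standard()
    cols = matrix_columns(split_met, code)
    mat = pd.DataFrame(0, index=list(genome_ids), columns=cols, dtype=int)
    untagged_cau = 0
    for g in genes:
        if g.genome_id not in mat.index:
            raise ValueError(f"gene {g.gene_id!r} has unknown genome {g.genome_id!r}")
        if g.undetermined:
            log.info("gene %s: undetermined anticodon, excluded", g.gene_id)
            continue
        if g.pseudo and not include_pseudo:
            continue
        if not code.is_sense_anticodon(g.anticodon):
            warnings.warn(
                f"gene {g.gene_id}: anticodon {g.anticodon} decodes a stop codon; excluded",
                stacklevel=2,
            )
            continue
        if split_met and g.anticodon == "CAU":
            if g.met_tag == "iMet":
                label = IMET_LABEL
            else:
                if g.met_tag is None:
                    untagged_cau += 1
                label = EMET_LABEL
        else:
            label = anticodon_label(g.anticodon, code)
        mat.loc[g.genome_id, label] += 1
    if untagged_cau:
        warnings.warn(
            f"{untagged_cau} CAU gene(s) without iMet/eMet tag counted as eMet",
            stacklevel=2,
        )
    empty = mat.index[mat.sum(axis=1) == 0]
    for gid in empty:
        warnings.warn(f"genome {gid} has zero counted tRNA genes", stacklevel=2)
    return mat


def absence_summary(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-genome presence/absence totals and per-type absence counts.

    Returns ``(per_genome, per_type)`` where ``per_genome`` has columns
    ``types_present``, ``types_absent``, ``total_copies`` and ``per_type``
    counts, for each anticodon column, the number of genomes lacking it.
    """
    present = matrix > 0
    per_genome = pd.DataFrame(
        {
            "types_present": present.sum(axis=1),
            "types_absent": (~present).sum(axis=1),
            "total_copies": matrix.sum(axis=1),
        }
    )
    per_type = (~present).sum(axis=0).rename("genomes_lacking")
    return per_genome, per_type


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write the repertoire matrix as TSV (index column ``genome_id``)."""
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id")


def read_genome_metadata(path) -> pd.DataFrame:
    """Genome metadata TSV: genome_id, genome_size (bp), gc, clade[, ...]."""
    meta = pd.read_csv(path, sep="\t", index_col="genome_id")
    if "gc" in meta and ((meta["gc"] < 0) | (meta["gc"] > 1)).any():
        raise ValueError("gc must be a fraction in [0, 1]")
    if "genome_size" in meta and (meta["genome_size"] <= 0).any():
        raise ValueError("genome_size must be positive")
    return meta
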