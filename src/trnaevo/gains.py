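"""Tracing the origin of recently gained tRNA genes.

Candidate gains are matrix cells whose type was classified recent_gain.
Each candidate's intron-spliced sequence is globally aligned against the
intron-spliced sequences of the other tRNA genes in the input set; the best
hit is inspected at the anticodon (structural positions 34-36) to decide
whether the new specificity arose by point substitution inside the
anticodon or by a single-base insertion -- the two mechanisms that have
been traced for archaeal ANN/UAU gains.  Calls are alignment-dependent, so
every trace records the scoring scheme used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .repertoire import TRNAGene, label_anticodon


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scoring: match/mismatch with a linear gap penalty."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        """Identical columns / aligned columns (gaps count as columns)."""
        n = len(self.aligned_a)
        if n == 0:
            return 0.0
        same = sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-")
        return same / n


@dataclass
class TraceResult:
    candidate_id: str
    homolog_id: str | None
    mechanism: str  # anticodon_substitution | anticodon_insertion | untraceable
    changed_positions: tuple[int, ...] = ()  # anticodon-relative: 34, 35, 36
    identity: float = 0.0
    score: float = 0.0
    scoring: AlignScoring = field(default_factory=AlignScoring)
    alignment: Alignment | None = None
    note: str = ""


def global_align(seq_a: str, seq_b: str, scoring: AlignScoring = AlignScoring()) -> Alignment:
    """Optimal global pairwise alignment (Needleman-Wunsch, linear gaps).

    Deterministic: of the co-optimal alignments the aligner's first is
    returned.  The score is symmetric in the arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return Alignment(a, b, float(aln.score))


def _window_columns(aligned: str, start: int, end: int) -> list[int]:
    """Alignment columns covering ungapped positions [start, end] (1-based)."""
    cols = []
    pos = 0
    for i, ch in enumerate(aligned):
        if ch != "-":
            pos += 1
            if start <= pos <= end:
                cols.append(i)
    return cols


def classify_anticodon_change(
    alignment: Alignment,
    anticodon_window_a: tuple[int, int],
    anticodon_window_b: tuple[int, int],
    identity_threshold: float = 0.6,
) -> TraceResult:
    """Decide the gain mechanism from an alignment and anticodon windows.

    Windows are 1-based inclusive positions of the anticodon on each
    *ungapped* sequence (canonically (34, 36)).  Substitution: the windows
    occupy the same gap-free columns with at least one mismatch inside;
    insertion/deletion: a gap column falls inside either window;
    untraceable: overall identity below ``identity_threshold`` or the
    windows do not overlap in the alignment.
    """
    a, b = alignment.aligned_a, alignment.aligned_b
    for window, seq, name in (
        (anticodon_window_a, a, "a"),
        (anticodon_window_b, b, "b"),
    ):
        length = sum(1 for ch in seq if ch != "-")
        if window[0] < 1 or window[1] > length:
            raise ValueError(
                f"anticodon window {window} outside sequence {name} (length {length})"
            )
    if alignment.identity < identity_threshold:
        return TraceResult(
            "", None, "untraceable", identity=alignment.identity,
            score=alignment.score, alignment=alignment,
            note=f"identity {alignment.identity:.2f} < {identity_threshold}",
        )
    cols_a = _window_columns(a, *anticodon_window_a)
    cols_b = _window_columns(b, *anticodon_window_b)
    window_cols = sorted(set(cols_a) | set(cols_b))
    if not set(cols_a) & set(cols_b):
        return TraceResult(
            "", None, "untraceable", identity=alignment.identity,
            score=alignment.score, alignment=alignment,
            note="anticodon windows do not overlap in the alignment",
        )
    has_gap = any(a[i] == "-" or b[i] == "-" for i in window_cols)
    if has_gap:
        return TraceResult(
            "", None, "anticodon_insertion", identity=alignment.identity,
            score=alignment.score, alignment=alignment,
        )
    mismatches = [i for i in cols_a if a[i] != b[i]]
    if cols_a == cols_b and mismatches:
        positions = tuple(34 + cols_a.index(i) for i in mismatches)
        return TraceResult(
            "", None, "anticodon_substitution", changed_positions=positions,
            identity=alignment.identity, score=alignment.score,
            alignment=alignment,
        )
    return TraceResult(
        "", None, "untraceable", identity=alignment.identity,
        score=alignment.score, alignment=alignment,
        note="no change detected inside the anticodon window",
    )


def find_candidate_gains(
    matrix: pd.DataFrame, categories: pd.DataFrame
) -> list[tuple[str, str]]:
    """(genome, type) cells with copies of a recent_gain-classified type."""
    out = []
    gained = categories.index[categories["category"] == "recent_gain"]
    for col in gained:
        for genome in matrix.index[matrix[col] >= 1]:
            out.append((genome, col))
    return sorted(out)


def _anticodon_window(gene: TRNAGene) -> tuple[int, int]:
    start = gene.anticodon_start or 34
    return (start, start + 2)


def trace_gain(
    candidate: TRNAGene,
    homologs: Sequence[TRNAGene],
    scoring: AlignScoring = AlignScoring(),
    identity_threshold: float = 0.6,
    top_n: int = 1,
) -> TraceResult:
    """Align a candidate gained gene against homologs and call the mechanism.

    Introns are removed (per annotation) before aligning.  Homologs with
    the same anticodon as the candidate, without sequence, or identical to
    the candidate record are skipped; the best remaining hit by alignment
    score is classified.  ``top_n`` reserved for reporting more hits.
    """
    cand_seq = candidate.spliced_sequence()
    if not cand_seq:
        return TraceResult(candidate.gene_id, None, "untraceable", note="candidate has no sequence")
    best = None  # (sort key, homolog id, alignment, homolog gene)
    for hom in homologs:
        if hom is candidate or hom.gene_id == candidate.gene_id:
            continue
        if hom.anticodon == candidate.anticodon:
            continue
        seq = hom.spliced_sequence()
        if not seq:
            continue
        aln = global_align(cand_seq, seq, scoring)
        # ties: prefer closer length, then first in input order (stable)
        key = (aln.score, -abs(len(seq) - len(cand_seq)))
        if best is None or key > best[0]:
            best = (key, hom.gene_id, aln, hom)
    if best is None:
        return TraceResult(candidate.gene_id, None, "untraceable", note="no homolog available")
    _, hom_id, aln, hom = best
    result = classify_anticodon_change(
        aln, _anticodon_window(candidate), _anticodon_window(hom), identity_threshold
    )
    result.candidate_id = candidate.gene_id
    result.homolog_id = hom_id
    result.scoring = scoring
    return result


def trace_candidate_gains(
    matrix: pd.DataFrame,
    categories: pd.DataFrame,
    genes: Iterable[TRNAGene],
    scoring: AlignScoring = AlignScoring(),
    identity_threshold: float = 0.6,
) -> pd.DataFrame:
    """Trace every recent-gain candidate in the matrix; returns a TSV-ready table."""
    genes = list(genes)
    candidates = find_candidate_gains(matrix, categories)
    rows = []
    for genome, type_label in candidates:
        anticodon = label_anticodon(type_label)
        cand_genes = [
            g for g in genes if g.genome_id == genome and g.anticodon == anticodon
        ]
        for cand in cand_genes:
            res = trace_gain(cand, genes, scoring, identity_threshold)
            rows.append(
                {
                    "genome_id": genome,
                    "trna_type": type_label,
                    "candidate_id": res.candidate_id,
                    "homolog_id": res.homolog_id or "",
                    "mechanism": res.mechanism,
                    "changed_positions": ",".join(map(str, res.changed_positions)),
                    "identity": round(res.identity, 4),
                    "score": res.score,
                    "scoring": f"match={scoring.match},mismatch={scoring.mismatch},gap={scoring.gap}",
                    "note": res.note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "trna_type", "candidate_id", "homolog_id", "mechanism",
            "changed_positions", "identity", "score", "scoring", "note",
        ],
    )
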