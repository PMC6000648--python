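"""Group comparisons linking repertoires to genome features.

Mann-Whitney U tests (exact by full enumeration for small samples, normal
approximation with tie and continuity correction otherwise), Pearson
correlation, and a report comparing an in-group of genomes (e.g. the clades
with reduced genomes) against the rest on tRNA copy totals, CNN-family
copies, genome size, GC content and the NNG fraction of optimal codons.

All tests are two-sided; p-values are reported raw (no multiple-testing
correction by default, Benjamini-Hochberg available via a flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: p-values below this are rendered as "< 2.2e-16" in text reports
P_FLOOR = 2.2e-16

EXACT_MAX_N = 16  # full enumeration allowed up to n1 + n2 = 16


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str


@dataclass
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    statistic: float
    pvalue: float
    test: str


def format_p(p: float) -> str:
    """Human-readable p-value ("< 2.2e-16" below float precision)."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    """U of the first sample from pooled (average) ranks."""
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates every assignment of the pooled observations
    to the two groups (ties handled through average ranks); allowed for
    n1+n2 <= 16.  ``mode="approx"`` uses the normal approximation with tie
    correction and continuity correction.  ``"auto"`` picks exact when
    small enough.  The reported statistic is U of ``x``; the two-sided p is
    symmetric in the argument order.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both samples; p = 1", stacklevel=2)
        return TestResult(n1 * n2 / 2.0, 1.0, "degenerate")
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_MAX_N else "approx"
    if mode == "exact":
        if n1 + n2 > EXACT_MAX_N:
            raise ValueError(f"exact mode limited to n1+n2 <= {EXACT_MAX_N}")
        ranks = sps.rankdata(pooled)
        u_obs = _u_statistic(np.concatenate([ranks[:n1], ranks[n1:]]), n1)
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        n = n1 + n2
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            r1 = ranks[list(idx)].sum()
            u = r1 - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return TestResult(u_obs, hits / total, "mann-whitney exact")
    if mode == "approx":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney normal approx")
    raise ValueError(f"unknown mode {mode!r}")


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the t-transform p-value (n-2 df).

    Requires equal lengths >= 3 and non-zero variance in both variables;
    degenerate input yields (nan, nan) with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return TestResult(math.nan, math.nan, "pearson (undefined)")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson")


def _compare(
    variable: str,
    a: np.ndarray,
    b: np.ndarray,
    label_a: str,
    label_b: str,
    mode: str,
) -> GroupComparison:
    res = mann_whitney(a, b, mode=mode)
    return GroupComparison(
        variable=variable,
        group_a=label_a,
        group_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=res.statistic,
        pvalue=res.pvalue,
        test=res.method,
    )


def group_compare_report(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    group_tips: frozenset[str] | set[str],
    group_label: str = "in_group",
    extra_variables: Mapping[str, Mapping[str, float]] | None = None,
    mode: str = "auto",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """In-group vs out-group comparisons over repertoire and genome features.

    Variables: total tRNA copies, CNN-family copies (columns whose anticodon
    starts with C), plus any numeric metadata columns (genome_size, gc) and
    optional per-genome ``extra_variables`` (e.g. NNG optimal-codon
    fraction).  With ``bh_correct`` a Benjamini-Hochberg adjusted column is
    appended.
    """
    genomes = list(matrix.index)
    in_g = [g for g in genomes if g in group_tips]
    out_g = [g for g in genomes if g not in group_tips]
    if not in_g or not out_g:
        raise ValueError("both groups must be non-empty")
    cnn_cols = [c for c in matrix.columns if c.rsplit("-", 1)[1].startswith("C")]
    variables: dict[str, pd.Series] = {
        "total_trna_copies": matrix.sum(axis=1),
        "cnn_trna_copies": matrix[cnn_cols].sum(axis=1),
    }
    for col in ("genome_size", "gc"):
        if col in meta.columns:
            variables[col] = meta.loc[genomes, col]
    for name, mapping in (extra_variables or {}).items():
        variables[name] = pd.Series({g: mapping[g] for g in genomes})
    rows = []
    for name, series in variables.items():
        comp = _compare(
            name,
            series.loc[in_g].to_numpy(dtype=float),
            series.loc[out_g].to_numpy(dtype=float),
            group_label,
            "others",
            mode,
        )
        rows.append(vars(comp))
    report = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        report["pvalue_bh"] = multipletests(report["pvalue"], method="fdr_bh")[1]
    report["pvalue_text"] = report["pvalue"].map(format_p)
    return report
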