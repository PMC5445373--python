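"""Identification workflow: prioritize exons, test array scores, rank.

Heterogeneity between arrays (a high exon score) is necessary but not
sufficient for *differential* splicing between experimental conditions:
the array scores of a prioritized exon must additionally separate the
groups.  The workflow is

1. keep exons with exon score strictly above a threshold (default 0.5);
2. t-test the array scores between the two groups (Welch by default, or
   a paired t-test on within-pair differences for paired designs);
3. Benjamini-Hochberg FDR adjustment across tested exons;
4. rank by adjusted p-value.

A gene-level t-test on the per-array expression summaries c_i separates
four scenarios: whether the gene is differentially expressed (DE) and
whether the exon is alternatively spliced (AS) are independent axes, so a
high exon score with a non-significant array-score test flags DE without
AS, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ArrayMetadata
from .reids_core import ReidsFit

__all__ = [
    "prioritize",
    "test_array_scores",
    "bh_fdr",
    "classify_scenario",
    "rank_calls",
    "build_splice_call_table",
]

SCENARIOS = ("no-DE/no-AS", "no-DE/AS", "DE/no-AS", "DE/AS")


def prioritize(fits: Iterable[ReidsFit], rho_threshold: float = 0.5) -> pd.DataFrame:
    """Exons whose exon score strictly exceeds the threshold.

    Returns a DataFrame (gene_id, probeset_id, exon_index, exon_score);
    empty when nothing passes.
    """
    if not (0.0 < rho_threshold < 1.0):
        raise ValueError("rho_threshold must lie strictly inside (0, 1)")
    rows = []
    for fit in fits:
        for k, ps in enumerate(fit.probeset_ids):
            if fit.exon_scores[k] > rho_threshold:
                rows.append((fit.gene_id, ps, k, float(fit.exon_scores[k])))
    return pd.DataFrame(
        rows, columns=["gene_id", "probeset_id", "exon_index", "exon_score"]
    )


def _split_groups(
    scores: np.ndarray, array_ids: Sequence[str], meta: ArrayMetadata
) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = meta.groups
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g0, g1 = groups
    group_of = meta.group_of()
    scores = np.asarray(scores, dtype=float)
    mask0 = np.array([group_of[a] == g0 for a in array_ids])
    mask1 = np.array([group_of[a] == g1 for a in array_ids])
    return g0, g1, scores[mask0], scores[mask1]


def test_array_scores(
    scores: np.ndarray,
    array_ids: Sequence[str],
    meta: ArrayMetadata,
    paired: bool = False,
    test: str = "welch",
) -> tuple[float, float]:
    """Two-sided t-test of one exon's array scores between two groups.

    Unpaired designs use Welch's t-test (``test="pooled"`` switches to the
    equal-variance form); paired designs use a one-sample t-test on the
    within-pair differences.  Returns (t, p).
    """
    if test not in ("welch", "pooled"):
        raise ValueError(f"unknown test {test!r}")
    if paired:
        df = meta.data
        if "pair_id" not in df.columns or df["pair_id"].isna().any():
            raise ValueError("paired test requires complete pair_id metadata")
        g0, g1 = meta.groups
        score_of = dict(zip(array_ids, np.asarray(scores, dtype=float)))
        diffs = []
        for pair_id, pair in df.groupby("pair_id"):
            a0 = pair.loc[pair["group"] == g0, "array_id"].iloc[0]
            a1 = pair.loc[pair["group"] == g1, "array_id"].iloc[0]
            diffs.append(score_of[a0] - score_of[a1])
        if len(diffs) < 2:
            raise ValueError("paired test needs >= 2 complete pairs")
        t, p = stats.ttest_1samp(diffs, 0.0)
    else:
        _, _, x0, x1 = _split_groups(scores, array_ids, meta)
        if len(x0) < 2 or len(x1) < 2:
            raise ValueError("each group needs >= 2 arrays")
        t, p = stats.ttest_ind(x0, x1, equal_var=(test == "pooled"))
    if np.isnan(t):  # zero variance in both samples with equal means
        t, p = 0.0, 1.0
    return float(t), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_scenario(
    exon_score: float,
    exon_test_p: float,
    gene_level_p: float,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
) -> str:
    """Quadrant label separating differential expression from splicing.

    An exon score at or below the threshold means no between-array signal:
    the gene is neither DE nor carries AS evidence at this exon.  Above
    the threshold, the array-score test decides AS and the gene-level test
    decides DE, independently.
    """
    for name, v in (
        ("exon_score", exon_score),
        ("exon_test_p", exon_test_p),
        ("gene_level_p", gene_level_p),
    ):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing or non-finite {name}")
    if exon_score <= rho_threshold:
        return "no-DE/no-AS"
    de = gene_level_p < alpha
    as_ = exon_test_p < alpha
    return f"{'DE' if de else 'no-DE'}/{'AS' if as_ else 'no-AS'}"


def rank_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Rank by ascending adjusted p, then |t| descending, then probeset_id."""
    df = table.copy()
    if len(df) == 0:
        df["rank"] = pd.Series(dtype=int)
        return df
    df["_abs_t"] = df["t_statistic"].abs()
    df = df.sort_values(
        ["adjusted_p", "_abs_t", "probeset_id"], ascending=[True, False, True]
    ).drop(columns="_abs_t")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def build_splice_call_table(
    fits: Sequence[ReidsFit],
    meta: ArrayMetadata,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    paired: bool = False,
    test: str = "welch",
) -> pd.DataFrame:
    """Full workflow over fitted genes: prioritize, test, adjust, rank.

    Returns the splice-call table with columns probeset_id, gene_id,
    exon_score, t_statistic, p_value, adjusted_p, mean_group_difference,
    rank, scenario, direction.  ``mean_group_difference`` is the mean
    array score in the lexicographically first group minus the second;
    its sign sets ``direction`` (enrichment when positive).
    """
    fit_by_gene = {f.gene_id: f for f in fits}
    selected = prioritize(fits, rho_threshold)
    columns = [
        "probeset_id",
        "gene_id",
        "exon_score",
        "t_statistic",
        "p_value",
        "adjusted_p",
        "mean_group_difference",
        "rank",
        "scenario",
        "direction",
    ]
    if len(selected) == 0:
        return pd.DataFrame(columns=columns)

    gene_p: dict[str, float] = {}
    rows = []
    for _, rec in selected.iterrows():
        fit = fit_by_gene[rec["gene_id"]]
        scores = fit.array_scores[:, int(rec["exon_index"])]
        t, p = test_array_scores(scores, fit.array_ids, meta, paired=paired, test=test)
        if fit.gene_id not in gene_p:
            _, gp = test_array_scores(
                fit.c, fit.array_ids, meta, paired=paired, test=test
            )
            gene_p[fit.gene_id] = gp
        _, _, x0, x1 = _split_groups(scores, fit.array_ids, meta)
        diff = float(x0.mean() - x1.mean())
        rows.append(
            {
                "probeset_id": rec["probeset_id"],
                "gene_id": rec["gene_id"],
                "exon_score": rec["exon_score"],
                "t_statistic": t,
                "p_value": p,
                "mean_group_difference": diff,
                "direction": "enrichment" if diff > 0 else "depletion",
            }
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_fdr(df["p_value"].to_numpy())
    df["scenario"] = [
        classify_scenario(
            r["exon_score"],
            r["p_value"],
            gene_p[r["gene_id"]],
            rho_threshold=rho_threshold,
            alpha=alpha,
        )
        for _, r in df.iterrows()
    ]
    return rank_calls(df)[columns]
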