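"""Informative/Non-Informative (I/NI) probe-set filtering.

Splicing detection suffers from false positives when probe sets are
non-responsive: their probes carry no coherent between-array signal.  The
I/NI score of a probe set is the intraclass correlation of the balanced
random-intercept model

    Y_ij = mu + probe_j + a_i + e_ij,   a_i ~ N(0, tau2_a),  e_ij ~ N(0, sigma2_e)

fitted on the arrays x probes log2 matrix of that probe set:

    ICC = tau2_a / (tau2_a + sigma2_e).

Probe effects are fixed, so the score is invariant to probe-specific
offsets.  Responsive probe sets track the sample-to-sample expression of
their gene (high ICC); background-only probe sets have ICC near zero.
Filtering removes probe sets scoring below a threshold (default 0.5)
before model fitting.

The default estimator is the closed-form ANOVA/REML solution of the
balanced two-way layout; a Gibbs sampler sharing the conjugate machinery
of :mod:`reids.reids_core` is provided as a cross-check.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import ProbeIntensityTable

logger = logging.getLogger("reids")

__all__ = ["ini_score", "ini_score_gibbs", "filter_probe_sets"]


def _as_matrix(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected an arrays x probes matrix")
    n, J = Y.shape
    if n < 2 or J < 2:
        raise ValueError("I/NI score needs >= 2 arrays and >= 2 probes")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite intensities")
    return Y


def ini_score(Y: np.ndarray) -> float:
    """Intraclass correlation of one probe set (arrays x probes).

    Closed-form ANOVA/REML estimator for the balanced layout: after
    removing probe (column) means, the between-array mean square MS_a and
    the residual mean square MS_e give tau2_a = max((MS_a - MS_e)/J, 0)
    and ICC = tau2_a/(tau2_a + MS_e), clipped to [0, 1].
    """
    Y = _as_matrix(Y)
    n, J = Y.shape
    R = Y - Y.mean(axis=0, keepdims=True)  # remove fixed probe effects
    row_means = R.mean(axis=1)
    ms_array = J * float(np.sum(row_means**2)) / (n - 1)
    sse = float(np.sum((R - row_means[:, None]) ** 2))
    ms_error = sse / ((n - 1) * (J - 1))
    tau2_a = max((ms_array - ms_error) / J, 0.0)
    denom = tau2_a + ms_error
    if denom == 0.0:
        return 0.0
    return float(np.clip(tau2_a / denom, 0.0, 1.0))


def ini_score_gibbs(
    Y: np.ndarray,
    n_iter: int = 2000,
    n_burnin: int = 1000,
    seed: int = 0,
    alpha: float = 1e-4,
    beta: float = 1e-4,
    psi: float = 1.0,
    omega: float = 1.0,
) -> float:
    """Bayesian I/NI score: posterior mean of tau2_a/(tau2_a + sigma2_e).

    Gibbs sampler for the random-intercept model with fixed probe effects,
    using the same conjugate updates as the splicing model restricted to a
    single exon-level random effect per array.
    """
    Y = _as_matrix(Y)
    n, J = Y.shape
    rng = np.random.default_rng(seed)

    p = Y.mean(axis=0)
    a = np.zeros(n)
    resid0 = Y - p[None, :]
    tau2 = sigma2 = max(float(resid0.var()), 1e-6)

    total = 0.0
    kept = 0
    for it in range(n_iter):
        p = rng.normal((Y - a[:, None]).mean(axis=0), np.sqrt(sigma2 / n))
        prec = 1.0 / tau2 + J / sigma2
        a = rng.normal(
            ((Y - p[None, :]).sum(axis=1) / sigma2) / prec, np.sqrt(1.0 / prec)
        )
        tau2 = max(
            ((omega + float(np.sum(a**2))) / 2.0)
            / rng.gamma((psi + n) / 2.0),
            1e-12,
        )
        resid = Y - p[None, :] - a[:, None]
        eta = beta + 0.5 * float(np.sum(resid**2))
        sigma2 = max(1.0 / rng.gamma(alpha + 0.5 * Y.size, 1.0 / eta), 1e-12)
        if it >= n_burnin:
            total += tau2 / (tau2 + sigma2)
            kept += 1
    return total / kept


def filter_probe_sets(
    table: ProbeIntensityTable,
    threshold: float = 0.5,
    method: str = "reml",
    seed: int = 0,
) -> tuple[ProbeIntensityTable, pd.DataFrame]:
    """Score every probe set and drop the non-informative ones.

    Returns the retained table (probe sets with score >= threshold) and a
    score table for *all* probe sets with columns probeset_id, gene_id,
    ini_score, informative.  Genes losing every probe set are dropped with
    a logged warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if method not in ("reml", "gibbs"):
        raise ValueError(f"unknown method {method!r}")

    records = []
    for (gene_id, probeset_id), sub in table.data.groupby(
        ["gene_id", "probeset_id"], sort=True
    ):
        wide = sub.pivot(index="array_id", columns="probe_id", values="intensity")
        Y = wide.sort_index().to_numpy(dtype=float)
        if not table.is_log2:
            Y = np.log2(Y)
        score = ini_score(Y) if method == "reml" else ini_score_gibbs(Y, seed=seed)
        records.append((probeset_id, gene_id, score, score >= threshold))

    scores = pd.DataFrame(
        records, columns=["probeset_id", "gene_id", "ini_score", "informative"]
    ).sort_values("probeset_id").reset_index(drop=True)

    keep = set(scores.loc[scores["informative"], "probeset_id"])
    retained = table.data.loc[table.data["probeset_id"].isin(keep)].reset_index(
        drop=True
    )

    lost_genes = set(table.gene_ids) - set(retained["gene_id"].unique())
    for g in sorted(lost_genes):
        logger.warning("gene %s lost all probe sets in I/NI filtering", g)
    logger.info(
        "I/NI filter: retained %d / %d probe sets at threshold %.3g",
        len(keep),
        len(scores),
        threshold,
    )
    return ProbeIntensityTable(retained, is_log2=table.is_log2), scores
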