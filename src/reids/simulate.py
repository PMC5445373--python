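"""Synthetic probe-level data with splicing ground truth, and AUC scoring.

Two generative protocols, both producing the tidy probe-intensity table
consumed by the fitting modules together with per-unit truth labels.

Cassette-exon splicing study.  Each gene's probe intensity on array i,
probe j is

    y_ij = log2( B_j + I_ij * 2^(c_i + P_j) + eps_ij )

with probe-specific background B_j (shared across arrays), probe affinity
P_j ~ N(0, 3), array-level expression c_i ~ N(mu_c, 1.5^2) with mu_c in
{7, 10}, and measurement noise eps_ij ~ N(0, 0.7^2) on the linear scale.
The background level is drawn as N(5, 0.35^2) on the log2 scale, i.e.
B_j = 2^N(5, 0.35^2) ~ 32 linear, the typical level of RMA
background-corrected arrays; a toggle interprets the same numbers as
linear-scale background instead.  The indicator I_ij is 0 for probes of
the spliced exons on arrays carrying the spliced isoform (those probes
fall to background) and 1 otherwise.  The spliced exon pattern is drawn
uniformly from a pre-defined pattern set (single cassette exons 3..8 and
one adjacent pair); arrays carry the spliced isoform independently with a
configurable probability.  Default design: 40 arrays, 10 exons, 4 probes
per exon.

Non-responsive probe-set study.  Responsive probe sets follow the model
above with I = 1 everywhere; non-responsive probe sets are background plus
noise only (y = log2(B_j + eps_ij)).  Each gene carries non-responsive
probe sets with a configurable probability; the truth table labels every
probe set.

Detector performance is summarized by the rank-based (Mann-Whitney) AUC of
a score against truth labels.  Splicing detection is scored per
(exon, array) cell — a cell is positive when its exon is in the spliced
pattern *and* its array carries the spliced isoform — pooled across genes
(per-gene averaging is available).  The cell score is
exon_score_k * |array_score_ik| for the mixed model and |F_ik| for FIRMA;
per-exon detectors (exon score rho_k, max_i |F_ik|) are also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .datamodel import ProbeIntensityTable, build_gene_tensor
from .firma import FirmaFit, fit_firma_gene
from .reids_core import ChainSettings, PriorSpec, ReidsFit, fit_reids_gene

__all__ = [
    "SpliceSimConfig",
    "SimTruth",
    "DEFAULT_PATTERNS",
    "simulate_splicing_gene",
    "simulate_splicing_study",
    "simulate_nonresponsive_study",
    "evaluate_auc",
    "reids_detector_scores",
    "firma_detector_scores",
    "splicing_benchmark",
    "nonresponsive_benchmark",
]

#: Default cassette patterns (0-based exon indices for a 10-exon gene):
#: each of exons 3..8 skipped singly, plus one adjacent double skip.
DEFAULT_PATTERNS: tuple[tuple[int, ...], ...] = (
    (2,),
    (3,),
    (4,),
    (5,),
    (6,),
    (7,),
    (4, 5),
)

#: Floor for the log2 argument, guarding rare negative background+noise draws.
LOG_FLOOR = 2.0**-20


@dataclass(frozen=True)
class SpliceSimConfig:
    """Study conditions of the cassette-exon simulation."""

    n_arrays: int = 40
    n_exons: int = 10
    probes_per_exon: int = 4
    mu_c: float = 7.0
    sd_c: float = 1.5
    bg_mean: float = 5.0
    bg_sd: float = 0.35
    probe_sd: float = math.sqrt(3.0)
    noise_sd: float = 0.7
    splice_array_prob: float = 0.8
    n_genes: int = 1000
    pattern_set: tuple[tuple[int, ...], ...] = DEFAULT_PATTERNS
    seed: int = 0
    background_log2_scale: bool = True
    background_per_array: bool = False

    def __post_init__(self) -> None:
        for name in ("sd_c", "bg_sd", "probe_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.splice_array_prob <= 1.0):
            raise ValueError("splice_array_prob must lie in (0, 1]")
        if len(self.pattern_set) == 0:
            raise ValueError("pattern_set must not be empty")
        for pat in self.pattern_set:
            if any(k < 0 or k >= self.n_exons for k in pat):
                raise ValueError(
                    f"pattern {pat} outside exon range 0..{self.n_exons - 1}"
                )

    def with_(self, **kwargs) -> "SpliceSimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth labels for one simulated gene."""

    gene_id: str
    pattern: tuple[int, ...]
    spliced_exons: tuple[int, ...]
    spliced_arrays: tuple[int, ...]

    def exon_labels(self, n_exons: int) -> np.ndarray:
        """Boolean per-exon labels: True for exons in the spliced pattern."""
        return np.isin(np.arange(n_exons), self.spliced_exons)

    def cell_labels(self, n_arrays: int, n_exons: int) -> np.ndarray:
        """(n_arrays x n_exons) labels: True where the exon is spliced on
        an array that carries the spliced isoform."""
        lab = np.zeros((n_arrays, n_exons), dtype=bool)
        if self.spliced_arrays and self.spliced_exons:
            lab[np.ix_(list(self.spliced_arrays), list(self.spliced_exons))] = True
        return lab


def _ids(prefix: str, n: int) -> list[str]:
    width = max(len(str(n)), 2)
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _gene_frame(gene_id: str, y: np.ndarray, probesets, probes, arrays) -> pd.DataFrame:
    n, J = y.shape
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "probeset_id": np.tile(probesets, n),
            "probe_id": np.tile(probes, n),
            "array_id": np.repeat(arrays, J),
            "intensity": y.ravel(),
        }
    )


def _draw_background(
    cfg: SpliceSimConfig, rng: np.random.Generator, n: int, J: int
) -> np.ndarray:
    size = (n, J) if cfg.background_per_array else J
    B = rng.normal(cfg.bg_mean, cfg.bg_sd, size=size)
    if cfg.background_log2_scale:
        B = np.exp2(B)
    return np.broadcast_to(B, (n, J))


def simulate_splicing_gene(
    cfg: SpliceSimConfig,
    rng: np.random.Generator,
    gene_id: str = "g00001",
) -> tuple[pd.DataFrame, SimTruth]:
    """One gene under the cassette-exon model; log2-scale intensities."""
    n, K, m = cfg.n_arrays, cfg.n_exons, cfg.probes_per_exon
    J = K * m
    exon_of_probe = np.repeat(np.arange(K), m)

    B = _draw_background(cfg, rng, n, J)
    P = rng.normal(0.0, cfg.probe_sd, size=J)
    c = rng.normal(cfg.mu_c, cfg.sd_c, size=n)
    eps = rng.normal(0.0, cfg.noise_sd, size=(n, J))

    pattern = cfg.pattern_set[rng.integers(len(cfg.pattern_set))]
    spliced_arrays = np.flatnonzero(rng.random(n) < cfg.splice_array_prob)

    I = np.ones((n, J))
    probe_mask = np.isin(exon_of_probe, pattern)
    I[np.ix_(spliced_arrays, np.flatnonzero(probe_mask))] = 0.0

    signal = B + I * np.exp2(c[:, None] + P[None, :]) + eps
    y = np.log2(np.maximum(signal, LOG_FLOOR))

    exon_ids = _ids(f"{gene_id}_ps", K)
    probesets = np.repeat(exon_ids, m)
    probes = [f"{ps}_p{j % m + 1}" for j, ps in zip(range(J), probesets)]
    arrays = _ids("a", n)

    truth = SimTruth(
        gene_id=gene_id,
        pattern=tuple(int(k) for k in pattern),
        spliced_exons=tuple(int(k) for k in pattern),
        spliced_arrays=tuple(int(i) for i in spliced_arrays),
    )
    return _gene_frame(gene_id, y, probesets, probes, arrays), truth


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_splicing_study(
    cfg: SpliceSimConfig,
) -> tuple[ProbeIntensityTable, list[SimTruth]]:
    """Independent genes under the cassette-exon model.

    Per-gene RNG streams are keyed by gene index, so the first m genes of
    an n-gene study coincide with an m-gene study at the same seed.
    """
    width = max(len(str(cfg.n_genes)), 5)
    frames = []
    truths = []
    for g in range(cfg.n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        frame, truth = simulate_splicing_gene(cfg, _gene_rng(cfg.seed, g), gene_id)
        frames.append(frame)
        truths.append(truth)
    table = ProbeIntensityTable(pd.concat(frames, ignore_index=True), is_log2=True)
    return table, truths


def simulate_nonresponsive_study(
    n_genes: int,
    probesets_per_gene: int,
    p_nonresponsive: float,
    n_nonresponsive: int,
    cfg: SpliceSimConfig | None = None,
    seed: int = 0,
) -> tuple[ProbeIntensityTable, pd.DataFrame]:
    """Mixture of responsive and background-only probe sets.

    Each gene independently carries, with probability ``p_nonresponsive``,
    ``n_nonresponsive`` background-only probe sets (chosen uniformly);
    all other probe sets follow the responsive model (I = 1 everywhere).
    Returns the table and a truth frame (probeset_id, gene_id, responsive).
    """
    if not (0.0 <= p_nonresponsive <= 1.0):
        raise ValueError("p_nonresponsive must lie in [0, 1]")
    if not (0 <= n_nonresponsive <= probesets_per_gene):
        raise ValueError("n_nonresponsive must not exceed probesets_per_gene")
    cfg = cfg or SpliceSimConfig()
    n, m = cfg.n_arrays, cfg.probes_per_exon
    K = probesets_per_gene
    J = K * m

    width = max(len(str(n_genes)), 5)
    frames = []
    truth_rows = []
    for g in range(n_genes):
        rng = _gene_rng(seed, g)
        gene_id = f"g{g + 1:0{width}d}"

        B = _draw_background(cfg, rng, n, J)
        P = rng.normal(0.0, cfg.probe_sd, size=J)
        c = rng.normal(cfg.mu_c, cfg.sd_c, size=n)
        eps = rng.normal(0.0, cfg.noise_sd, size=(n, J))

        nonresp: set[int] = set()
        if n_nonresponsive > 0 and rng.random() < p_nonresponsive:
            nonresp = set(
                int(k) for k in rng.choice(K, size=n_nonresponsive, replace=False)
            )
        exon_of_probe = np.repeat(np.arange(K), m)
        responsive_probe = ~np.isin(exon_of_probe, sorted(nonresp))

        signal = B + eps + responsive_probe[None, :] * np.exp2(
            c[:, None] + P[None, :]
        )
        y = np.log2(np.maximum(signal, LOG_FLOOR))

        exon_ids = _ids(f"{gene_id}_ps", K)
        probesets = np.repeat(exon_ids, m)
        probes = [f"{ps}_p{j % m + 1}" for j, ps in zip(range(J), probesets)]
        frames.append(_gene_frame(gene_id, y, probesets, probes, _ids("a", n)))
        for k, ps in enumerate(exon_ids):
            truth_rows.append((ps, gene_id, k not in nonresp))

    table = ProbeIntensityTable(pd.concat(frames, ignore_index=True), is_log2=True)
    truth = pd.DataFrame(truth_rows, columns=["probeset_id", "gene_id", "responsive"])
    return table, truth


def evaluate_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUC of detector scores against truth.

    Probability that a randomly chosen positive outscores a randomly
    chosen negative (ties count 1/2).  Requires both classes present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    if labels.all() or not labels.any():
        raise ValueError("AUC needs at least one positive and one negative unit")
    return float(roc_auc_score(labels, scores))


def reids_detector_scores(fit: ReidsFit, level: str = "cell") -> np.ndarray:
    """Detector scores from a mixed-model fit.

    ``cell``: exon_score_k * |array_score_ik| per (array, exon) cell —
    the exon score gates exons with between-array signal, the array score
    magnitude localizes the affected arrays.  ``exon``: the exon score
    rho_k alone.
    """
    if level == "cell":
        return np.abs(fit.array_scores) * fit.exon_scores[None, :]
    if level == "exon":
        return fit.exon_scores
    raise ValueError(f"unknown level {level!r}")


def firma_detector_scores(
    fit_or_scores, level: str = "cell", reduce: str = "max"
) -> np.ndarray:
    """Detector scores from FIRMA scores F (matrix or :class:`FirmaFit`).

    ``cell``: |F_ik| per (array, exon) cell.  ``exon``: |F| reduced over
    arrays (``max`` by default, ``mean`` optionally).
    """
    F = fit_or_scores.scores if isinstance(fit_or_scores, FirmaFit) else fit_or_scores
    if level == "cell":
        return np.abs(F)
    if level == "exon":
        if reduce == "max":
            return np.abs(F).max(axis=0)
        if reduce == "mean":
            return np.abs(F).mean(axis=0)
        raise ValueError(f"unknown reduce {reduce!r}")
    raise ValueError(f"unknown level {level!r}")


def splicing_benchmark(
    cfg: SpliceSimConfig,
    chain: ChainSettings | None = None,
    prior: PriorSpec | None = None,
    level: str = "cell",
    pooling: str = "pooled",
) -> dict:
    """Simulate, fit REIDS and both FIRMA variants, and score by AUC.

    Returns a dict with AUCs for ``reids``, ``firma_mean``,
    ``firma_median``, the average posterior-mean noise variance
    ``sigma2_mean``, the fraction of genes whose top exon score lands on a
    truly spliced exon (``top_rho_fraction``), and bookkeeping counts.
    ``pooling`` is ``pooled`` (one AUC over all units) or ``per_gene``
    (mean of within-gene AUCs).
    """
    if pooling not in ("pooled", "per_gene"):
        raise ValueError(f"unknown pooling {pooling!r}")
    chain = chain or ChainSettings()
    table, truths = simulate_splicing_study(cfg)

    pooled = {"reids": [], "firma_mean": [], "firma_median": [], "labels": []}
    per_gene = {"reids": [], "firma_mean": [], "firma_median": []}
    sigma2 = []
    top_ok = 0
    for idx, truth in enumerate(truths):
        tensor = build_gene_tensor(table, truth.gene_id)
        seed = np.random.SeedSequence(chain.seed, spawn_key=(idx,)).generate_state(1)[0]
        fit = fit_reids_gene(tensor, prior, chain.with_seed(int(seed % 2**31)))
        firma_mean = fit_firma_gene(tensor, variant="mean")
        firma_median = fit_firma_gene(tensor, variant="median")

        if level == "cell":
            labels = truth.cell_labels(cfg.n_arrays, cfg.n_exons).ravel()
            scores = {
                "reids": reids_detector_scores(fit, "cell").ravel(),
                "firma_mean": firma_detector_scores(firma_mean, "cell").ravel(),
                "firma_median": firma_detector_scores(firma_median, "cell").ravel(),
            }
        elif level == "exon":
            labels = truth.exon_labels(cfg.n_exons)
            scores = {
                "reids": reids_detector_scores(fit, "exon"),
                "firma_mean": firma_detector_scores(firma_mean, "exon"),
                "firma_median": firma_detector_scores(firma_median, "exon"),
            }
        else:
            raise ValueError(f"unknown level {level!r}")

        pooled["labels"].extend(labels)
        for key in ("reids", "firma_mean", "firma_median"):
            pooled[key].extend(scores[key])
        if labels.any() and not labels.all():
            for key in ("reids", "firma_mean", "firma_median"):
                per_gene[key].append(evaluate_auc(scores[key], labels))

        sigma2.append(fit.sigma2)
        if int(np.argmax(fit.exon_scores)) in truth.spliced_exons:
            top_ok += 1

    if pooling == "pooled":
        auc = {
            key: evaluate_auc(pooled[key], pooled["labels"])
            for key in ("reids", "firma_mean", "firma_median")
        }
    else:
        auc = {key: float(np.mean(per_gene[key])) for key in per_gene}
    return {
        **auc,
        "sigma2_mean": float(np.mean(sigma2)),
        "top_rho_fraction": top_ok / cfg.n_genes,
        "n_genes": cfg.n_genes,
        "n_units": len(pooled["labels"]),
        "level": level,
        "pooling": pooling,
    }


def nonresponsive_benchmark(
    n_genes: int,
    probesets_per_gene: int,
    p_nonresponsive: float,
    n_nonresponsive: int,
    cfg: SpliceSimConfig | None = None,
    seed: int = 0,
) -> dict:
    """I/NI identification of non-responsive probe sets, scored by AUC.

    The detector is 1 - ICC for the "non-responsive" label (equivalently
    ICC for "responsive"); probe sets pool across genes.  Returns the AUC
    and the count of each class.
    """
    from .ini_filter import ini_score

    table, truth = simulate_nonresponsive_study(
        n_genes, probesets_per_gene, p_nonresponsive, n_nonresponsive, cfg, seed
    )
    scores = []
    for probeset_id, sub in table.data.groupby("probeset_id", sort=True):
        wide = sub.pivot(index="array_id", columns="probe_id", values="intensity")
        scores.append((probeset_id, ini_score(wide.to_numpy(dtype=float))))
    score_df = pd.DataFrame(scores, columns=["probeset_id", "ini_score"])
    merged = truth.merge(score_df, on="probeset_id", validate="one_to_one")
    n_nonresp = int((~merged["responsive"]).sum())
    if n_nonresp == 0 or n_nonresp == len(merged):
        raise ValueError(
            "degenerate truth: need both responsive and non-responsive probe sets"
        )
    auc = evaluate_auc(
        1.0 - merged["ini_score"].to_numpy(), (~merged["responsive"]).to_numpy()
    )
    return {
        "auc": auc,
        "n_probesets": len(merged),
        "n_nonresponsive": n_nonresp,
    }
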