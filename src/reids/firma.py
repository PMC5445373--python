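"""FIRMA baseline: robust additive fit plus residual-based splicing scores.

FIRMA treats alternative splicing as outlier detection.  A gene-level
additive model Y_ij = c_i + p_j + e_ij is fitted to the arrays x probes
log2 matrix by Tukey's median polish; an exon whose probes systematically
deviate on some arrays leaves large residuals there.  The score of exon k
on array i is the median (or mean) of that cell's probe residuals divided
by a MAD-based scale s, making scores comparable across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GeneTensor

__all__ = ["MedianPolishResult", "FirmaFit", "median_polish", "firma_scores", "fit_firma_gene"]

#: MAD consistency factor for the normal distribution.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


@dataclass(frozen=True)
class FirmaFit:
    """Median-polish effects and per-(exon, array) splicing scores."""

    gene_id: str
    probeset_ids: tuple[str, ...]
    array_ids: tuple[str, ...]
    p: np.ndarray  # probe effects (overall absorbed into row/col split)
    c: np.ndarray  # array effects = summarized gene level per array
    residuals: np.ndarray  # (n_arrays, n_probes)
    scale: float
    scores: np.ndarray  # (n_arrays, n_exons)
    variant: str


def median_polish(
    Y: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> MedianPolishResult:
    """Tukey median polish of a complete two-way table.

    Alternately sweeps row medians into row effects and column medians
    into column effects until the sum of absolute residuals changes by
    less than ``tol`` times its current value (or ``max_iter`` sweeps).
    The decomposition is exact: overall + row_i + col_j + residual_ij
    reconstructs Y.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    if not np.all(np.isfinite(Y)):
        raise ValueError("median_polish requires finite entries")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    z = Y.copy()
    n, m = z.shape
    t = 0.0
    row = np.zeros(n)
    col = np.zeros(m)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        t += delta

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        t += delta

        newsum = float(np.abs(z).sum())
        if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum

    return MedianPolishResult(
        overall=t,
        row_effects=row,
        col_effects=col,
        residuals=z,
        converged=converged,
        n_iter=it,
    )


def firma_scores(
    polish: MedianPolishResult,
    exon_of_probe: np.ndarray,
    variant: str = "median",
    scale: float | None = None,
) -> tuple[np.ndarray, float]:
    """Per-(array, exon) splicing scores F_ik from polish residuals.

    F_ik summarizes (median or mean) the residuals of exon k's probes on
    array i, divided by the scale s = 1.4826 x MAD of the gene's
    residuals.  A precomputed ``scale`` (e.g. chip-wide) may be supplied.
    When every residual is identically zero s = 0 and F is defined as the
    zero matrix.
    """
    if variant not in ("median", "mean"):
        raise ValueError(f"unknown variant {variant!r}; use 'median' or 'mean'")
    eps = polish.residuals
    exon_of_probe = np.asarray(exon_of_probe, dtype=int)
    n_exons = int(exon_of_probe.max()) + 1

    if scale is None:
        med = np.median(eps)
        scale = MAD_SCALE * float(np.median(np.abs(eps - med)))
        # an (all but) exactly additive matrix has no meaningful scale;
        # tie the cutoff to the fitted magnitude so it is scale-equivariant
        fitted_mag = abs(polish.overall) + np.abs(polish.row_effects).max(initial=0.0) \
            + np.abs(polish.col_effects).max(initial=0.0)
        if scale <= 1e-12 * max(1.0, fitted_mag):
            scale = 0.0
    if scale < 0:
        raise ValueError("scale must be nonnegative")

    reducer = np.median if variant == "median" else np.mean
    F = np.column_stack(
        [reducer(eps[:, exon_of_probe == k], axis=1) for k in range(n_exons)]
    )
    if scale == 0.0:
        return np.zeros_like(F), 0.0
    return F / scale, float(scale)


def fit_firma_gene(
    tensor: GeneTensor,
    variant: str = "median",
    scale: float | None = None,
    max_iter: int = 10,
    tol: float = 0.01,
) -> FirmaFit:
    """FIRMA fit for one gene: median polish then residual scores.

    Rows are arrays (array effects = gene-level summaries), columns are
    probes (probe effects absorb the exon effects, since probes are nested
    within exons).
    """
    polish = median_polish(tensor.Y, max_iter=max_iter, tol=tol)
    F, s = firma_scores(polish, tensor.exon_of_probe, variant=variant, scale=scale)
    return FirmaFit(
        gene_id=tensor.gene_id,
        probeset_ids=tensor.probeset_ids,
        array_ids=tensor.array_ids,
        p=polish.overall + polish.col_effects,
        c=polish.row_effects,
        residuals=polish.residuals,
        scale=s,
        scores=F,
        variant=variant,
    )
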