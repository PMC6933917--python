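"""From quantified expression to analysis-ready matrix.

Low-expression filtering on TPM, log2(TPM+1) transform, ComBat-style
location/scale batch correction with parametric empirical-Bayes shrinkage,
and sample-space PCA for inspecting batch and strain structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PcaResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(vf < -1e-12) or np.any(np.diff(vf) > 1e-12) or vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must be in [0,1], non-increasing")


def filter_low_expression(
    tpm: ExpressionMatrix, min_tpm: float = 10.0, max_frac_below: float = 0.9
) -> ExpressionMatrix:
    """Drop genes with TPM below ``min_tpm`` in more than ``max_frac_below``
    of samples (strict inequality: a gene at exactly the boundary is kept)."""
    if tpm.scale_tag != "tpm":
        raise ValueError("filter_low_expression expects a TPM matrix")
    frac_below = (tpm.values < min_tpm).mean(axis=1)
    keep = frac_below <= max_frac_below
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all genes removed by the low-expression filter")
    log.info("low-expression filter removed %d of %d genes", n_removed, keep.size)
    return ExpressionMatrix(tpm.data.loc[keep], "tpm")


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if tpm.scale_tag != "tpm":
        raise ValueError("log_transform expects a TPM matrix")
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values")
    return ExpressionMatrix(np.log2(tpm.data + 1.0), "log2tpm")


def _design_matrices(meta: pd.DataFrame, use_covariates: bool):
    batches = meta["batch"].astype(str)
    batch_levels = list(dict.fromkeys(batches))
    B = np.column_stack([(batches == b).to_numpy(float) for b in batch_levels])
    C = np.empty((len(meta), 0))
    if use_covariates:
        strains = meta["strain"].astype(str)
        strain_levels = list(dict.fromkeys(strains))[1:]  # drop reference level
        if strain_levels:
            C = np.column_stack([(strains == s).to_numpy(float) for s in strain_levels])
    return batch_levels, B, C


def correct_batch(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    eb: bool = True,
    covariates: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ExpressionMatrix:
    """ComBat-style per-gene location/scale batch adjustment.

    Each gene is standardized against a model holding batch indicators and
    (by default) strain indicators, so biological signal is not absorbed
    into the batch terms. With ``eb=True`` the per-batch locations and
    scales are shrunk across genes by parametric empirical Bayes (normal
    prior on locations, inverse-gamma on scales, method-of-moments
    hyperparameters, fixed-point iteration). A single batch is an identity.
    """
    if expr.scale_tag != "log2tpm":
        raise ValueError("correct_batch expects a log2tpm matrix")
    tab = meta.table.loc[expr.samples]
    batch_levels, B, C = _design_matrices(tab, covariates)
    n_batches = len(batch_levels)
    if n_batches == 1:
        return ExpressionMatrix(expr.data.copy(), "log2tpm")
    batch_sizes = B.sum(axis=0)
    if not eb and batch_sizes.min() < 2:
        small = [b for b, s in zip(batch_levels, batch_sizes) if s < 2]
        raise ValueError(f"batches with a single sample need eb=True: {small}")

    Y = expr.values  # genes x samples
    n = Y.shape[1]
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        log.warning("batch/covariate design is collinear; dropping covariates")
        X = B
        C = np.empty((n, 0))
    # per-gene OLS with a shared design
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]  # p x genes
    gamma_hat_ols = beta[:n_batches]  # batch locations per gene
    alpha = (batch_sizes / n) @ gamma_hat_ols  # grand mean per gene
    cov_part = (C @ beta[n_batches:]).T if C.shape[1] else 0.0
    stand_mean = alpha[:, None] + cov_part  # genes x samples
    resid = Y - (X @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    out = np.empty_like(Y)
    batch_masks = [B[:, i].astype(bool) for i in range(n_batches)]
    for i, mask in enumerate(batch_masks):
        Zi = Z[:, mask]
        ni = Zi.shape[1]
        g_hat = Zi.mean(axis=1)
        d_hat = Zi.var(axis=1, ddof=1) if ni > 1 else np.ones(Zi.shape[0])
        d_hat = np.maximum(d_hat, 1e-12)
        if eb:
            g_star, d_star = _eb_shrink(Zi, g_hat, d_hat, max_iter, tol)
        else:
            g_star, d_star = g_hat, d_hat
        out[:, mask] = (Zi - g_star[:, None]) / np.sqrt(d_star)[:, None]
    out = out * sd + stand_mean
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.genes, columns=expr.samples), "log2tpm"
    )


def _eb_shrink(Zi, g_hat, d_hat, max_iter, tol):
    """Parametric empirical-Bayes fixed point for one batch.

    Normal prior on the location gamma, inverse-gamma on the scale delta^2;
    hyperparameters by method of moments across genes.
    """
    ni = Zi.shape[1]
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1) if g_hat.size > 1 else 1.0
    t2 = max(t2, 1e-12)
    m = d_hat.mean()
    s2 = d_hat.var(ddof=1) if d_hat.size > 1 else 1.0
    s2 = max(s2, 1e-12)
    a_prior = (2.0 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2
    g_star, d_star = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (ni * t2 * g_hat + d_star * g_bar) / (ni * t2 + d_star)
        sse = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (b_prior + 0.5 * sse) / (ni / 2.0 + a_prior - 1.0)
        d_new = np.maximum(d_new, 1e-12)
        change = max(
            np.abs(g_new - g_star).max() / (np.abs(g_star).max() + 1e-12),
            np.abs(d_new - d_star).max() / (np.abs(d_star).max() + 1e-12),
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def run_pca(
    expr: ExpressionMatrix, center: bool = True, scale: bool = False
) -> PcaResult:
    """PCA over samples with genes as variables (gene-centering only by
    default). Component orientation is fixed by making the largest-magnitude
    gene loading positive, so results are deterministic."""
    values = expr.values.T  # samples x genes
    if values.shape[0] < 2:
        raise ValueError("run_pca requires >= 2 samples")
    X = values - values.mean(axis=0) if center else values.copy()
    if scale:
        sds = X.std(axis=0, ddof=1)
        X = X / np.where(sds > 0, sds, 1.0)
    total_var = (X ** 2).sum()
    if total_var <= 0:
        raise ValueError("constant matrix: PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation: dominant loading of each component positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    var_frac = (S ** 2) / (S ** 2).sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(pd.DataFrame(scores, index=expr.samples, columns=cols), var_frac)
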