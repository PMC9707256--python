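"""Variance and covariance normalization of fitness matrices.

Two sample-level variance normalizations are provided: quantile
normalization to the rank mean (no reference distribution) and removal of
the top principal components of a control-gene (e.g. olfactory receptor)
submatrix. Covariance normalization ("whitening" / "sphering") removes
dependencies between cell lines — e.g. tissue overrepresentation — by a
linear transform W of each gene profile such that the transformed matrix
has identity sample covariance:

    X~ = W X,  Cov(X~) = I

with W = L' from the Cholesky factorization of the inverse covariance
(Sigma^-1 = L L'), or W = D^{-1/2} E' from the eigendecomposition
(Sigma = E D E'). The two transforms differ (they are related by a
rotation) but whiten identically.

Covariance is estimated in sample space: Sigma is cell-line x cell-line,
with genes as observations, after centering each cell-line column by its
mean across genes. This is the orientation in which the identity-covariance
contract is testable at DepMap shapes (hundreds of cell lines, tens of
thousands of genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .matrix_io import FitnessMatrix

logger = logging.getLogger(__name__)

#: relative ridge added to the covariance diagonal when it is not
#: positive definite (fraction of the mean diagonal entry)
DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class WhiteningOperator:
    """A sample-space whitening transform with its provenance.

    ``transform`` (n_samples x n_samples) maps centered gene profiles to
    whitened profiles; ``transform @ covariance @ transform.T`` is the
    identity to 1e-8 per entry.
    """

    transform: np.ndarray
    method: str  # "cholesky" | "pca" | "identity"
    covariance: np.ndarray
    eigenvalues: np.ndarray | None = None
    ridge_used: float = 0.0

    def __post_init__(self) -> None:
        w, s = np.asarray(self.transform), np.asarray(self.covariance)
        if w.shape != s.shape or w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("transform and covariance must be square and congruent")
        resid = w @ s @ w.T - np.eye(w.shape[0])
        if np.abs(resid).max() > 1e-8:
            raise ValueError(
                f"whitening contract violated: max |W S W' - I| = {np.abs(resid).max():.3g}")

    @property
    def n_samples(self) -> int:
        return self.transform.shape[0]


def quantile_normalize(m: FitnessMatrix) -> FitnessMatrix:
    """Quantile-normalize each cell line to the cross-sample rank mean.

    Genes are ranked by value within each sample; the values of all genes
    occupying the same rank are replaced by the mean value at that rank,
    then restored to the original gene order. Every column ends up with
    the identical sorted value multiset and its within-column ordering
    preserved. Ties are resolved by a stable sort of the input order.
    """
    vals = m.values
    if vals.shape[1] < 1:
        raise ValueError("need at least one sample")
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    np.put_along_axis(out, order, np.broadcast_to(
        rank_means[:, None], vals.shape), axis=0)
    return FitnessMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def boyle_pca_correct(m: FitnessMatrix, control_genes, n_components: int = 4) -> FitnessMatrix:
    """Remove the top principal components of a control-gene submatrix.

    The control genes (classically olfactory receptors, which should show
    no knockout fitness effect) define artifactual sample-space components:
    the top ``n_components`` right singular vectors of the column-centered
    control submatrix. The whole matrix is projected off their span, so the
    output has zero inner product with each removed component.
    """
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    if n_components == 0:
        return FitnessMatrix(m.data.copy())
    present = [g for g in control_genes if g in m.data.index]
    if not present:
        raise ValueError("control gene list is disjoint from the matrix genes")
    if len(present) < n_components:
        raise ValueError(
            f"{len(present)} control genes present but {n_components} components requested")
    sub = m.data.loc[present].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(sub)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds control submatrix rank {rank}")
    # right singular vectors = sample-space components
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    v_k = vt[:n_components].T  # (n_samples, k), orthonormal
    x = m.values
    out = x - (x @ v_k) @ v_k.T
    return FitnessMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))


def sample_covariance(m: FitnessMatrix, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Cell-line x cell-line covariance, treating genes as observations.

    Each column is centered by its mean across genes; the denominator is
    n_genes - 1. When the raw matrix is not positive definite (smallest
    eigenvalue <= 0), ``ridge * mean(diagonal)`` is added to the diagonal.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    x = m.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes to estimate covariance")
    xc = x - x.mean(axis=0, keepdims=True)
    sigma = xc.T @ xc / (x.shape[0] - 1)
    sigma = (sigma + sigma.T) / 2.0
    if ridge > 0:
        smallest = scipy.linalg.eigvalsh(sigma, subset_by_index=(0, 0))[0]
        if smallest <= 0:
            bump = ridge * float(np.mean(np.diag(sigma)))
            logger.warning("covariance not positive definite (min eig %.3g); "
                           "adding ridge %.3g to the diagonal", smallest, bump)
            sigma = sigma + bump * np.eye(sigma.shape[0])
    return sigma


def _check_spd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    return (sigma + sigma.T) / 2.0


def cholesky_whitening_operator(sigma: np.ndarray) -> WhiteningOperator:
    """Whitening transform W = L' with Sigma^-1 = L L' (L lower triangular)."""
    sigma = _check_spd(sigma)
    try:
        c_upper = scipy.linalg.cholesky(sigma, lower=False)
    except scipy.linalg.LinAlgError as e:
        raise ValueError(
            "covariance is not positive definite; re-estimate with a ridge "
            "(sample_covariance(..., ridge=1e-6))") from e
    # Sigma = U'U  =>  Sigma^-1 = U^-1 U^-T = L L' with L = U^-1 lower? U^-1 is
    # upper triangular, so factor the inverse explicitly instead.
    sigma_inv = scipy.linalg.cho_solve((c_upper, False), np.eye(sigma.shape[0]))
    sigma_inv = (sigma_inv + sigma_inv.T) / 2.0
    l_lower = scipy.linalg.cholesky(sigma_inv, lower=True)
    return WhiteningOperator(transform=l_lower.T, method="cholesky", covariance=sigma)


def pca_whitening_operator(sigma: np.ndarray) -> WhiteningOperator:
    """Whitening transform W = D^{-1/2} E' from Sigma = E D E'."""
    sigma = _check_spd(sigma)
    eigvals, eigvecs = scipy.linalg.eigh(sigma)
    if eigvals[0] <= 0:
        raise ValueError(
            "covariance is not positive definite; re-estimate with a ridge "
            "(sample_covariance(..., ridge=1e-6))")
    desc = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[desc], eigvecs[:, desc]
    transform = (eigvecs / np.sqrt(eigvals)).T
    return WhiteningOperator(transform=transform, method="pca",
                             covariance=sigma, eigenvalues=eigvals)


def apply_whitening(m: FitnessMatrix, w: WhiteningOperator) -> FitnessMatrix:
    """Transform every gene profile by the whitening operator.

    Columns are centered by their mean across genes (the same centering
    used when estimating the covariance), then each gene's profile vector
    is multiplied by ``w.transform``. When the operator was built from this
    matrix the result has identity sample covariance.
    """
    if w.n_samples != m.shape[1]:
        raise ValueError(
            f"operator is {w.n_samples}-dimensional but matrix has {m.shape[1]} samples")
    x = m.values
    xc = x - x.mean(axis=0, keepdims=True)
    out = xc @ w.transform.T
    return FitnessMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))
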