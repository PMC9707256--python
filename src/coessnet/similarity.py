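"""All-pairs similarity of gene fitness profiles, with ranking.

Two measures of coessentiality are supported: the Pearson correlation
rho = cov(x, y) / (sigma_x sigma_y) of two gene profiles, and per-pair
ordinary least squares y = b x + intercept scored by the two-sided t-test
P-value of the slope. After covariance whitening the two measures carry
identical information and produce the same pair ranking; the OLS route is
kept because it is the form used by generalized least squares pipelines.

Ranking is by descending signed score: coessentiality is positive
co-dependency, and a negative correlation is a distinct signal (it is the
parent-parent signature in moonlighting trios), not a weaker form of the
same one. For OLS the ranking score is sign(slope) * (-log10 P), which is
a strictly increasing function of rho at fixed sample size, so the OLS
ranking coincides with the Pearson ranking by construction; the unsigned
log10 P and slope are recorded per pair. An ``absolute`` flag ranks by
magnitude instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import FitnessMatrix

logger = logging.getLogger(__name__)

#: smallest positive double; P-values that underflow are capped here
#: before taking logs (exact-fit pairs occur in synthetic data)
_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class SimilarityRanking:
    """Ranked unordered gene pairs with similarity scores.

    ``edges`` has columns gene_a, gene_b (gene_a < gene_b), score, rank
    (1-based dense, best first; ties broken by (gene_a, gene_b)), plus
    measure-specific columns (``rho`` always; ``slope`` and ``log10_p``
    for OLS).
    """

    edges: pd.DataFrame
    measure: str  # "pcc" | "ols"

    def __post_init__(self) -> None:
        e = self.edges
        if (e["gene_a"] >= e["gene_b"]).any():
            raise ValueError("pairs must be stored with gene_a < gene_b")
        if e.duplicated(["gene_a", "gene_b"]).any():
            raise ValueError("duplicate pairs in ranking")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])


def _correlation_matrix(m: FitnessMatrix) -> tuple[np.ndarray, list[str]]:
    """Gene-gene Pearson matrix, dropping zero-variance rows with a warning."""
    x = m.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s",
                       len(dropped), dropped[:10])
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(x[keep])
    return corr, genes


def _rank_edges(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["score", "gene_a", "gene_b"],
                        ascending=[False, True, True], kind="stable")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _upper_triangle_pairs(corr: np.ndarray, genes: list[str]) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(genes), k=1)
    garr = np.asarray(genes, dtype=object)
    return pd.DataFrame({
        "gene_a": garr[iu],
        "gene_b": garr[ju],
        "rho": np.clip(corr[iu, ju], -1.0, 1.0),
    })


def pcc_all_pairs(m: FitnessMatrix, absolute: bool = False) -> SimilarityRanking:
    """Pearson correlation for all unordered gene pairs, ranked best-first."""
    corr, genes = _correlation_matrix(m)
    df = _upper_triangle_pairs(corr, genes)
    df["score"] = df["rho"].abs() if absolute else df["rho"]
    df = _rank_edges(df[["gene_a", "gene_b", "score", "rho"]])
    return SimilarityRanking(edges=df, measure="pcc")


def _log10_p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided slope t-test P-value (log10) for correlation rho at n samples."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(dof / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isfinite(t), p, _P_FLOOR)  # |rho| = 1: exact fit
    p = np.maximum(p, _P_FLOOR)
    return np.log10(p)


def ols_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares fit y = b x + c; returns (slope, log10 of slope P-value).

    The P-value is the two-sided t-test for b != 0 with n - 2 degrees of
    freedom; underflow is capped at the smallest positive double.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("zero-variance x")
    design = np.column_stack([x, np.ones(n)])
    (slope, _), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rss = float(resid @ resid)
    se = np.sqrt(rss / (n - 2) / sxx)
    if se == 0:
        return float(slope), float(np.log10(_P_FLOOR))
    t = slope / se
    p = max(2.0 * float(stats.t.sf(abs(t), n - 2)), _P_FLOOR)
    return float(slope), float(np.log10(p))


def ols_all_pairs(m: FitnessMatrix, absolute: bool = False) -> SimilarityRanking:
    """Per-pair OLS for all unordered gene pairs, ranked best-first.

    Computed in closed form from the correlation matrix and per-gene
    standard deviations (normal equations; no iterative fitting): for the
    pair (a, b) with a < b, slope = rho * sd_b / sd_a of the fit of b on a,
    and the slope t-statistic equals rho * sqrt((n-2) / (1-rho^2)).
    """
    corr, genes = _correlation_matrix(m)
    df = _upper_triangle_pairs(corr, genes)
    sd = pd.Series(m.values.std(axis=1, ddof=1), index=m.gene_ids)
    df["slope"] = df["rho"].to_numpy() * (sd[df["gene_b"]].to_numpy()
                                          / sd[df["gene_a"]].to_numpy())
    df["log10_p"] = _log10_p_from_rho(df["rho"].to_numpy(), m.shape[1])
    signed = -df["log10_p"] * np.sign(df["rho"]).replace(0, 1)
    df["score"] = signed.abs() if absolute else signed
    df = _rank_edges(df[["gene_a", "gene_b", "score", "rho", "slope", "log10_p"]])
    return SimilarityRanking(edges=df, measure="ols")


def top_k(ranking: SimilarityRanking, k: int) -> SimilarityRanking:
    """The best k pairs, ranks 1..k preserved."""
    if k < 1 or k > len(ranking):
        raise ValueError(f"k={k} out of range (1..{len(ranking)})")
    return SimilarityRanking(edges=ranking.edges.iloc[:k].reset_index(drop=True),
                             measure=ranking.measure)
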