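"""Partial-correlation detection of context-dependent gene interactions.

A "moonlighting" gene x interacts with two parents y and z in mutually
exclusive cellular contexts (the KRAS / NRAS / RAF1 pattern: RAF1 is
essential in both KRAS-mutant and NRAS-mutant lines, while KRAS and NRAS
are essential in disjoint line sets). The marginal correlations of x with
each parent are diluted by the lines where the other parent carries the
signal; removing one parent's effect by the first-order partial
correlation

    rho_{x,y|z} = (rho_xy - rho_xz rho_yz)
                  / sqrt((1 - rho_xz^2)(1 - rho_yz^2))

recovers ("boosts") the interaction. A trio is called when x correlates
positively with both parents, the parents correlate negatively with each
other, and both partial correlations exceed their marginals; the boost is
quantified by the squared ratio rho_{x,y|z}^2 / rho_xy^2.

Note the correlation gate (default |rho| > 0.15) is calibrated to a
DepMap-sized cohort (~700 cell lines); with far fewer samples the null
spread of rho is wider and the gate should be raised accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: candidate controllers with |rho| within this distance of 1 are skipped
#: inside scans (degenerate denominator, e.g. duplicated genes)
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class MoonlightTrio:
    """A candidate moonlighter x with parents y, z and its coefficients."""

    x: str
    y: str
    z: str
    rho_xy: float
    rho_xz: float
    rho_yz: float
    pcorr_xy_given_z: float
    pcorr_xz_given_y: float

    @property
    def boost_xy(self) -> float:
        return boost_ratio(self.pcorr_xy_given_z, self.rho_xy)

    @property
    def boost_xz(self) -> float:
        return boost_ratio(self.pcorr_xz_given_y, self.rho_xz)


def partial_correlation(rho_xy: float, rho_xz: float, rho_yz: float) -> float:
    """First-order partial correlation rho_{x,y|z} by the recursive formula.

    Symmetric in exchanging x and y. Controlling a gene independent of
    both (rho_xz = rho_yz = 0) returns the marginal unchanged.
    """
    if abs(rho_xz) >= 1 or abs(rho_yz) >= 1:
        raise ValueError("|rho_xz| and |rho_yz| must be < 1")
    return (rho_xy - rho_xz * rho_yz) / np.sqrt(
        (1 - rho_xz ** 2) * (1 - rho_yz ** 2))


def boost_ratio(pcorr: float, marginal: float) -> float:
    """Squared ratio pcorr^2 / marginal^2 (sign-insensitive)."""
    if marginal == 0:
        raise ValueError("marginal correlation is zero")
    return (pcorr / marginal) ** 2


def _as_corr_frame(corr) -> pd.DataFrame:
    if isinstance(corr, pd.DataFrame):
        c = corr
    else:
        c = pd.DataFrame(np.asarray(corr, dtype=float))
        c.index = c.columns = [f"g{i}" for i in range(len(c))]
    mat = c.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return c


def best_controller(x: str, y: str, corr) -> tuple[str, float]:
    """The gene z maximizing rho_{x,y|z}, scanned over every other gene.

    Candidates with |rho_xz| or |rho_yz| at 1 (within 1e-12) are skipped;
    exact ties resolve to the lexicographically smallest gene, so the
    result does not depend on gene order in the matrix.
    """
    c = _as_corr_frame(corr)
    genes = list(c.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    mat = c.to_numpy(dtype=float)
    ix, iy = genes.index(x), genes.index(y)
    rho_xy = mat[ix, iy]
    rxz = mat[ix, :]
    ryz = mat[iy, :]
    valid = np.ones(len(genes), dtype=bool)
    valid[[ix, iy]] = False
    valid &= np.abs(rxz) < 1 - _DEGENERATE_TOL
    valid &= np.abs(ryz) < 1 - _DEGENERATE_TOL
    if not valid.any():
        raise ValueError("no valid controller candidates")
    with np.errstate(invalid="ignore"):
        pc = (rho_xy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    pc[~valid] = -np.inf
    best = np.max(pc)
    ties = [genes[i] for i in np.flatnonzero(pc == best)]
    z = min(ties)
    return z, float(pc[genes.index(z)])


def find_trios(corr, min_rho: float = 0.15,
               min_boost: float = 1.0) -> list[MoonlightTrio]:
    """Scan a correlation matrix for moonlighting trios.

    For every moonlighter candidate x, parent pairs (y, z) are taken from
    the genes correlated with x above ``min_rho``; a trio is reported when
    rho_xy > min_rho, rho_xz > min_rho, rho_yz < 0, both partial
    correlations strictly exceed their marginals, and both squared-ratio
    boosts exceed ``min_boost``. Each trio is reported once with parents
    in lexicographic order (y < z); an empty list is a valid result.
    """
    c = _as_corr_frame(corr)
    genes = np.asarray(c.index, dtype=object)
    mat = c.to_numpy(dtype=float)
    n = len(genes)
    trios: list[MoonlightTrio] = []
    for ix in range(n):
        row = mat[ix]
        cand = np.flatnonzero((row > min_rho) & (np.arange(n) != ix)
                              & (np.abs(row) < 1 - _DEGENERATE_TOL))
        for a in range(len(cand)):
            for b in range(a + 1, len(cand)):
                iy, iz = cand[a], cand[b]
                if genes[iy] > genes[iz]:
                    iy, iz = iz, iy
                rho_yz = mat[iy, iz]
                if rho_yz >= 0 or abs(rho_yz) >= 1 - _DEGENERATE_TOL:
                    continue
                rho_xy, rho_xz = mat[ix, iy], mat[ix, iz]
                p_xy = partial_correlation(rho_xy, rho_xz, rho_yz)
                p_xz = partial_correlation(rho_xz, rho_xy, rho_yz)
                if p_xy <= rho_xy or p_xz <= rho_xz:
                    continue
                if (p_xy / rho_xy) ** 2 <= min_boost or (p_xz / rho_xz) ** 2 <= min_boost:
                    continue
                trios.append(MoonlightTrio(
                    x=str(genes[ix]), y=str(genes[iy]), z=str(genes[iz]),
                    rho_xy=float(rho_xy), rho_xz=float(rho_xz),
                    rho_yz=float(rho_yz),
                    pcorr_xy_given_z=float(p_xy), pcorr_xz_given_y=float(p_xz)))
    return trios


def export_trio_network(trios: Sequence[MoonlightTrio], path) -> None:
    """Write a trio list as a Cytoscape-importable edge table.

    Moonlighter-parent edges carry the boosted partial coefficient
    (edge_type ``boosted_partial``); parent-parent edges carry the
    (negative) marginal correlation (``negative_pcc``). Edges shared by
    several trios are written once; an empty trio list yields a
    header-only file.
    """
    rows: dict[tuple[str, str], tuple[str, float]] = {}
    for t in trios:
        for a, b, kind, coef in (
                (t.x, t.y, "boosted_partial", t.pcorr_xy_given_z),
                (t.x, t.z, "boosted_partial", t.pcorr_xz_given_y),
                (t.y, t.z, "negative_pcc", t.rho_yz)):
            key = (min(a, b), max(a, b))
            if key not in rows or kind == "boosted_partial":
                rows[key] = (kind, coef)
    df = pd.DataFrame(
        [(a, b, kind, coef) for (a, b), (kind, coef) in sorted(rows.items())],
        columns=["gene_a", "gene_b", "edge_type", "coefficient"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
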