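"""Log-likelihood pathway-enrichment scoring of ranked networks.

A ranked network is benchmarked against a pathway reference (GMT format):
pairs annotated in the same pathway are true positives, pairs whose genes
are annotated only in different pathways are false positives, and pairs
with an unannotated gene are not counted. The log-likelihood score

    LLS = log2( (P(TP) / P(FP)) / (P(ref pos) / P(ref neg)) )

compares the sample's TP:FP odds to the background odds over all
annotated gene pairs in the reference. LLS > 0 means the network links
same-pathway genes more often than chance; the score is computed both
cumulatively and locally over bins of ranked pairs (bins of 1000 pairs
over the top 50,000 by default).

References are filtered to pathways of 5-400 genes before scoring; very
large pathways (classically the mitochondrial ribosome and oxidative
phosphorylation sets) contribute a quadratic number of "true positive"
pairs and can inflate apparent network quality, so a name-based exclusion
list is supported ("CleanReactome"-style filtering).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: pathway-name terms whose matches are removed to build a
#: CleanReactome-style reference (case-insensitive substrings)
DEFAULT_EXCLUDE_TERMS = (
    "mitochondrial translation",
    "oxidative phosphorylation",
    "respiratory electron transport",
    "complex i biogenesis",
)


@dataclass(frozen=True)
class PathwayReference:
    """A pathway -> gene-set map with derived background pair counts.

    ``background_pos`` / ``background_neg`` count unordered annotated gene
    pairs sharing >= 1 pathway vs sharing none; they are None until
    :func:`filter_reference` has been applied.
    """

    pathways: dict[str, frozenset[str]]
    background_pos: int | None = None
    background_neg: int | None = None

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    @property
    def filtered(self) -> bool:
        return self.background_pos is not None

    def gene_pathway_map(self) -> dict[str, set[str]]:
        pmap: dict[str, set[str]] = {}
        for name, genes in self.pathways.items():
            for g in genes:
                pmap.setdefault(g, set()).add(name)
        return pmap


def load_gmt(path) -> PathwayReference:
    """Load a GMT file (name, description, tab-separated member genes).

    Lines with fewer than three fields are skipped with a warning;
    duplicate genes within a line are stored once. No size filter is
    applied and backgrounds are left unset.
    """
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: skipping line with %d fields",
                               path, lineno, len(fields))
                continue
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if name in pathways:
                logger.warning("%s:%d: duplicate pathway %r; keeping union",
                               path, lineno, name)
                genes = genes | pathways[name]
            pathways[name] = genes
    if not pathways:
        raise ValueError(f"{path}: no pathways parsed")
    return PathwayReference(pathways=pathways)


def write_gmt(ref: PathwayReference, path, description: str = "na") -> None:
    """Serialize a pathway reference in GMT format (sorted for determinism)."""
    with open(path, "w") as fh:
        for name in sorted(ref.pathways):
            genes = "\t".join(sorted(ref.pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def filter_reference(ref: PathwayReference,
                     min_size: int = 5,
                     max_size: int = 400,
                     exclude: Sequence[str] = (),
                     exact: bool = False) -> PathwayReference:
    """Apply size and name filters and compute background pair counts.

    Pathways outside [min_size, max_size] genes are removed, as are
    pathways whose names match the exclusion list (case-insensitive
    substring by default, exact match with ``exact=True``). Backgrounds
    are recomputed over the remaining annotated genes.
    """
    terms = [t.lower() for t in exclude]

    def excluded(name: str) -> bool:
        low = name.lower()
        if exact:
            return low in terms
        return any(t in low for t in terms)

    kept = {name: genes for name, genes in ref.pathways.items()
            if min_size <= len(genes) <= max_size and not excluded(name)}
    if not kept:
        raise ValueError("all pathways removed by filtering")

    pos_pairs: set[frozenset[str]] = set()
    for genes in kept.values():
        for a, b in combinations(sorted(genes), 2):
            pos_pairs.add(frozenset((a, b)))
    n_annotated = len(frozenset().union(*kept.values()))
    total = n_annotated * (n_annotated - 1) // 2
    background_pos = len(pos_pairs)
    return PathwayReference(pathways=kept,
                            background_pos=background_pos,
                            background_neg=total - background_pos)


def lls_score(pairs: Iterable[tuple[str, str]],
              ref: PathwayReference) -> tuple[float, int, int, int]:
    """Log-likelihood score of a gene-pair list against a filtered reference.

    Returns (lls, tp, fp, counted). Duplicated pairs are counted once.
    Pairs with either gene unannotated are not counted; a 0.5 pseudocount
    is added to both TP and FP only when one of them is zero.
    """
    if not ref.filtered:
        raise ValueError("reference must be filtered first (filter_reference)")
    pmap = ref.gene_pathway_map()
    seen: set[frozenset[str]] = set()
    tp = fp = 0
    for a, b in pairs:
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        pa, pb = pmap.get(a), pmap.get(b)
        if pa is None or pb is None:
            continue
        if pa & pb:
            tp += 1
        else:
            fp += 1
    counted = tp + fp
    if counted == 0:
        raise ValueError("no annotated pairs in the sample")
    tp_f, fp_f = float(tp), float(fp)
    if tp == 0 or fp == 0:
        tp_f += 0.5
        fp_f += 0.5
    lls = math.log2((tp_f / fp_f) / (ref.background_pos / ref.background_neg))
    return lls, tp, fp, counted


@dataclass(frozen=True)
class LLSProfile:
    """Per-bin cumulative and local LLS over a ranked network's top pairs."""

    bin_size: int
    cumulative_lls: np.ndarray
    local_lls: np.ndarray
    counted_pairs: np.ndarray  # per-bin pairs with both genes annotated
    cumulative_unique_genes: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.cumulative_lls)


def lls_profile(ranking, ref: PathwayReference,
                top_n: int = 50_000, bin_size: int = 1_000) -> LLSProfile:
    """Binned LLS profile of the top ``top_n`` ranked pairs.

    The top pairs are split into bins of ``bin_size``; cumulative LLS
    pools bins 1..i, local LLS scores bin i alone. Bins with no annotated
    pair get a local value of NaN (the cumulative track is unaffected).
    """
    if top_n % bin_size != 0:
        raise ValueError("top_n must be a multiple of bin_size")
    if len(ranking) < top_n:
        raise ValueError(f"ranking has {len(ranking)} pairs; {top_n} required")
    if not ref.filtered:
        raise ValueError("reference must be filtered first (filter_reference)")
    pmap = ref.gene_pathway_map()
    n_bins = top_n // bin_size
    edges = ranking.edges.iloc[:top_n]
    a_list = edges["gene_a"].tolist()
    b_list = edges["gene_b"].tolist()

    bg_odds = ref.background_pos / ref.background_neg
    cum_tp = cum_fp = 0
    genes_seen: set[str] = set()
    cumulative, local, counted, ugenes = [], [], [], []
    for i in range(n_bins):
        sl = slice(i * bin_size, (i + 1) * bin_size)
        tp = fp = 0
        for a, b in zip(a_list[sl], b_list[sl]):
            genes_seen.add(a)
            genes_seen.add(b)
            pa, pb = pmap.get(a), pmap.get(b)
            if pa is None or pb is None:
                continue
            if pa & pb:
                tp += 1
            else:
                fp += 1
        cum_tp += tp
        cum_fp += fp
        local.append(_lls_from_counts(tp, fp, bg_odds))
        cumulative.append(_lls_from_counts(cum_tp, cum_fp, bg_odds))
        counted.append(tp + fp)
        ugenes.append(len(genes_seen))
    return LLSProfile(bin_size=bin_size,
                      cumulative_lls=np.array(cumulative),
                      local_lls=np.array(local),
                      counted_pairs=np.array(counted),
                      cumulative_unique_genes=np.array(ugenes))


def _lls_from_counts(tp: int, fp: int, bg_odds: float) -> float:
    if tp + fp == 0:
        return math.nan
    tp_f, fp_f = float(tp), float(fp)
    if tp == 0 or fp == 0:
        tp_f += 0.5
        fp_f += 0.5
    return math.log2((tp_f / fp_f) / bg_odds)


def recall_at_lls(profile: LLSProfile, threshold: float) -> tuple[int, int]:
    """Network size at a functional-enrichment threshold.

    Finds the largest bin index whose cumulative LLS is at least
    ``threshold`` and returns (pooled pair count, unique gene count) at
    that bin; (0, 0) when no bin qualifies.
    """
    qualifying = np.flatnonzero(
        np.nan_to_num(profile.cumulative_lls, nan=-np.inf) >= threshold)
    if qualifying.size == 0:
        return 0, 0
    i = int(qualifying[-1])
    return (i + 1) * profile.bin_size, int(profile.cumulative_unique_genes[i])


def complex_pairs(path, gene_column: str | None = None) -> list[tuple[str, str]]:
    """Unique within-complex gene pairs from a complex-membership table.

    Expects a delimited text file (comma or tab, sniffed) with a header
    row, one complex per line, and a column of space-separated gene
    symbols (the hu.MAP 2.0 dialect; the column is located by name —
    first header containing "gene" — unless ``gene_column`` is given).
    Pairs are unordered, deduplicated across complexes; single-member
    complexes contribute nothing. Unparseable lines are skipped with a
    warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if gene_column is None:
        candidates = [c for c in df.columns if "gene" in c.lower()]
        if not candidates:
            raise ValueError(f"{path}: no column with 'gene' in its name; "
                             f"columns = {list(df.columns)}")
        gene_column = candidates[0]
    elif gene_column not in df.columns:
        raise ValueError(f"{path}: no column {gene_column!r}")
    pairs: set[tuple[str, str]] = set()
    for i, cell in enumerate(df[gene_column]):
        if not isinstance(cell, str) or not cell.strip():
            logger.warning("%s: skipping row %d with empty gene field", path, i)
            continue
        members = sorted(set(cell.split()))
        for a, b in combinations(members, 2):
            pairs.add((a, b))
    return sorted(pairs)
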