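"""Synthetic fitness matrices with planted pathway, tissue and trio structure.

The generator emulates the three statistical features the pipeline
assumes in real screen data:

* **gene modules** — groups of co-functional genes sharing a latent
  fitness factor across cell lines (pathway coessentiality);
* **sample blocks** — groups of cell lines (tissues) sharing per-gene
  latent offsets, inducing a block-structured cell-line covariance
  (tissue overrepresentation — the confounder whitening removes);
* **moonlighting trios** — a gene x tracking parent y's essentiality in
  one half of the lines and parent z's in the other, with y and z
  essential in mutually exclusive halves (hence negatively correlated).

Everything is driven by one seeded generator; the same spec and seed
reproduce the matrix bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix_io import FitnessMatrix
from .evaluation import PathwayReference


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults describe the desk-scale condition used throughout the test
    suite: 400 genes x 60 cell lines, 10 modules of 10 genes, three
    deliberately imbalanced tissue blocks (40/10/10 lines), 3 trios, and
    latent-factor loadings twice the i.i.d. noise sd.
    """

    n_genes: int = 400
    n_samples: int = 60
    n_modules: int = 10
    module_size: int = 10
    module_effect: float = 1.0
    sample_block_sizes: tuple[int, ...] = (40, 10, 10)
    sample_block_effect: float = 1.0
    n_trios: int = 3
    trio_effect: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size + 3 * self.n_trios > self.n_genes:
            raise ValueError("modules and trios need more genes than n_genes")
        if sum(self.sample_block_sizes) > self.n_samples:
            raise ValueError("sample blocks need more samples than n_samples")
        if self.noise_sd < 0 or self.module_effect < 0 or \
                self.sample_block_effect < 0 or self.trio_effect < 0:
            raise ValueError("effects and noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: module membership, trios with their active
    sample subsets, and sample block assignment."""

    module_assignments: dict[str, int]
    trio_list: list[dict]  # {"x","y","z","samples_y","samples_z"}
    block_assignments: dict[str, int]  # block -1 = unassigned

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    return [f"ACH-{i:06d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[FitnessMatrix, GroundTruth]:
    """Generate a fitness matrix and its ground truth from a spec.

    Layout: the first ``n_modules * module_size`` genes form the modules,
    the next ``3 * n_trios`` genes form trios (x, y, z per trio), the rest
    are unstructured background. Samples are assigned to blocks in order;
    leftover samples belong to no block. Trio parent y is "essential"
    (negative scores with line-to-line variation) in the first half of
    samples and silent in the second, parent z the reverse, and the
    moonlighter x copies whichever parent is active.
    """
    rng = np.random.default_rng(spec.seed)
    g, s = spec.n_genes, spec.n_samples
    genes = _gene_names(g)
    samples = _sample_names(s)

    x = rng.normal(0.0, spec.noise_sd, size=(g, s))

    module_assignments: dict[str, int] = {}
    for m in range(spec.n_modules):
        rows = range(m * spec.module_size, (m + 1) * spec.module_size)
        factor = rng.normal(0.0, 1.0, size=s)
        for r in rows:
            x[r] += spec.module_effect * factor
            module_assignments[genes[r]] = m

    block_assignments: dict[str, int] = {smp: -1 for smp in samples}
    start = 0
    for b, size in enumerate(spec.sample_block_sizes):
        idx = np.arange(start, start + size)
        start += size
        loading = rng.normal(0.0, 1.0, size=g)
        x[:, idx] += spec.sample_block_effect * loading[:, None]
        for i in idx:
            block_assignments[samples[i]] = b

    trio_list: list[dict] = []
    trio_base = spec.n_modules * spec.module_size
    half = s // 2
    h1, h2 = np.arange(half), np.arange(half, s)
    for t in range(spec.n_trios):
        ix, iy, iz = trio_base + 3 * t, trio_base + 3 * t + 1, trio_base + 3 * t + 2
        mu = spec.trio_effect
        sig_y = np.zeros(s)
        sig_z = np.zeros(s)
        sig_y[h1] = -mu + mu * rng.normal(0.0, 1.0, size=len(h1))
        sig_z[h2] = -mu + mu * rng.normal(0.0, 1.0, size=len(h2))
        x[iy] += sig_y
        x[iz] += sig_z
        x[ix] += sig_y + sig_z  # copies y where y is active, z elsewhere
        trio_list.append({
            "x": genes[ix], "y": genes[iy], "z": genes[iz],
            "samples_y": [samples[i] for i in h1],
            "samples_z": [samples[i] for i in h2]})

    fm = FitnessMatrix(pd.DataFrame(x, index=genes, columns=samples))
    truth = GroundTruth(module_assignments=module_assignments,
                        trio_list=trio_list,
                        block_assignments=block_assignments)
    return fm, truth


def generate_reference(truth: GroundTruth) -> PathwayReference:
    """One pathway per planted module, containing exactly its members.

    Backgrounds are unset; run :func:`coessnet.evaluation.filter_reference`
    before LLS scoring. Non-module genes appear in no pathway and are
    therefore excluded from LLS counting downstream.
    """
    modules: dict[str, set[str]] = {}
    for gene, mid in truth.module_assignments.items():
        modules.setdefault(f"MODULE_{mid:03d}", set()).add(gene)
    if not modules:
        raise ValueError("ground truth has no modules")
    return PathwayReference(
        pathways={k: frozenset(v) for k, v in modules.items()})
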