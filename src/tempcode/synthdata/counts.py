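"""Negative-binomial count matrices with planted stage-resolved gene programs.

Cells are laid out on a domain x developmental-stage grid (defaults: the 11
dorsal-ventral progenitor domains dp1-dp6, p0-p2, pMN, p3 and stages
e9.5-e13.5).  A chosen number of "planted" genes follow a monotone (up- or
down-regulated) geometric mean profile across stages in a fixed number of
domains and are flat elsewhere; all other genes are flat everywhere.  Counts
are negative-binomial with a shared dispersion, scaled by a per-cell
log-normal library-size factor, so the matrix resembles shallow droplet
single-cell data with known temporal ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..tempmarkers import CountMatrix

__all__ = ["CountsSpec", "generate_counts"]

DEFAULT_DOMAINS = ("dp1", "dp2", "dp3", "dp4", "dp5", "dp6", "p0", "p1", "p2", "pMN", "p3")
DEFAULT_STAGES = ("e9.5", "e10.5", "e11.5", "e12.5", "e13.5")


@dataclass(frozen=True)
class CountsSpec:
    """Parameters of a synthetic progenitor count matrix."""

    n_genes: int = 525
    n_cells: int = 2750
    domains: tuple[str, ...] = DEFAULT_DOMAINS
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_planted: int = 25
    planted_fold_change: float = 4.0
    planted_domain_count: int = 9
    #: domains eligible for planting; None = all but dp6 (the excluded domain)
    planted_domain_pool: tuple[str, ...] | None = None
    planted_base_mean: float = 1.2
    null_log_mean: float = -2.3  # ln-scale mean of null gene baseline expression
    null_log_sd: float = 0.8
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    library_size_sigma: float = 0.3  # log-normal sd of per-cell size factors
    cell_type: str = "progenitor"
    #: optional real gene symbols for the first planted genes (e.g. TF names)
    planted_gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_genes must be >= n_planted")
        if len(self.planted_gene_names) > self.n_planted:
            raise ValueError("more planted gene names than planted genes")
        if self.planted_domain_count > len(self.domain_pool):
            raise ValueError("planted_domain_count exceeds eligible domain pool")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.planted_fold_change <= 0:
            raise ValueError("planted_fold_change must be positive")

    @property
    def domain_pool(self) -> tuple[str, ...]:
        if self.planted_domain_pool is not None:
            return self.planted_domain_pool
        return tuple(d for d in self.domains if d != "dp6")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean mu and var mu + dispersion*mu^2 (Poisson when dispersion=0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts(spec: CountsSpec, seed: int) -> CountMatrix:
    """Sample a genes x cells sparse count matrix with planted temporal genes.

    The returned :class:`CountMatrix` carries a ``truth`` table with one row
    per gene: ``gene, temporal, direction, n_domains, domains`` (semicolon
    joined).  Deterministic per ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    n_dom, n_stage = len(spec.domains), len(spec.stages)
    per_group = spec.n_cells // (n_dom * n_stage)
    if per_group < 1:
        raise ValueError("n_cells too small for the domain x stage grid")

    dom_col, stage_col = [], []
    for d in spec.domains:
        for s in spec.stages:
            dom_col += [d] * per_group
            stage_col += [s] * per_group
    n_cells = len(dom_col)

    genes = [f"tg{i:04d}" for i in range(spec.n_planted)] + [
        f"ng{i:04d}" for i in range(spec.n_genes - spec.n_planted)
    ]
    for i, sym in enumerate(spec.planted_gene_names):
        genes[i] = sym

    base = np.exp(rng.normal(spec.null_log_mean, spec.null_log_sd, size=spec.n_genes))
    base[: spec.n_planted] = spec.planted_base_mean

    directions = np.where(rng.random(spec.n_planted) < 0.5, "up", "down")
    pool_idx = np.array([spec.domains.index(d) for d in spec.domain_pool])
    planted_domains = [
        sorted(pool_idx[rng.choice(len(pool_idx), size=spec.planted_domain_count, replace=False)])
        for _ in range(spec.n_planted)
    ]

    # per-gene per-(domain, stage) mean multiplier
    ramp = spec.planted_fold_change ** (np.arange(n_stage) / (n_stage - 1))
    mu = np.empty((spec.n_genes, n_cells))
    dom_idx = np.array([spec.domains.index(d) for d in dom_col])
    stage_idx = np.array([spec.stages.index(s) for s in stage_col])
    mu[:] = base[:, None]
    for g in range(spec.n_planted):
        prof = ramp if directions[g] == "up" else ramp[::-1]
        in_dom = np.isin(dom_idx, planted_domains[g])
        mu[g, in_dom] = spec.planted_base_mean * prof[stage_idx[in_dom]]

    size_factors = np.exp(rng.normal(0.0, spec.library_size_sigma, size=n_cells))
    mu *= size_factors[None, :]

    counts = sp.csr_matrix(_nb_sample(rng, mu, spec.nb_dispersion))

    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "domain": dom_col,
            "stage": stage_col,
            "cell_type": spec.cell_type,
        }
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "temporal": [i < spec.n_planted for i in range(spec.n_genes)],
            "direction": list(directions) + [""] * (spec.n_genes - spec.n_planted),
            "n_domains": [spec.planted_domain_count] * spec.n_planted
            + [0] * (spec.n_genes - spec.n_planted),
            "domains": [
                ";".join(spec.domains[j] for j in planted_domains[i])
                for i in range(spec.n_planted)
            ]
            + [""] * (spec.n_genes - spec.n_planted),
        }
    )
    return CountMatrix(counts=counts, gene_ids=genes, cell_meta=cell_meta, truth=truth)
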