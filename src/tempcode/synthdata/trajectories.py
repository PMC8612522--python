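"""Synthetic differentiation trajectories for pseudotime reconstruction.

Cells are placed along a smooth curve in a 2D embedding according to a latent
maturation coordinate in [0, 1], partitioned into ordered clusters, and given
log-scale expression profiles that are Gaussian bumps of maturation.  Default
gene peaks plant the early -> intermediate -> late TF wave (Onecut2 early,
Pou2f2/Zfhx3 intermediate, Nfia/Nfib/Neurod2 late) so that binned expression
should peak near bins 5, 15, and 25 of 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["TrajectorySpec", "generate_trajectory", "DEFAULT_GENE_PEAKS"]

#: maturation positions of the planted expression peaks (early / mid / late)
DEFAULT_GENE_PEAKS: dict[str, float] = {
    "Onecut2": 0.12,
    "Pou2f2": 0.50,
    "Zfhx3": 0.50,
    "Nfia": 0.88,
    "Nfib": 0.88,
    "Neurod2": 0.88,
}


@dataclass(frozen=True)
class TrajectorySpec:
    n_cells: int = 600
    n_clusters: int = 6
    curve: str = "arc"  # "arc" or "line"
    scale: float = 10.0
    embedding_noise_sd: float = 0.35
    gene_peaks: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_PEAKS))
    peak_width: float = 0.15
    amplitude: float = 2.0
    expression_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need >= 2 clusters")
        if self.curve not in ("arc", "line"):
            raise ValueError("curve must be 'arc' or 'line'")


def _curve_xy(t: np.ndarray, kind: str, scale: float) -> np.ndarray:
    if kind == "line":
        return np.column_stack([scale * t, np.zeros_like(t)])
    ang = 0.5 * np.pi * t  # quarter circle
    return np.column_stack([scale * np.cos(ang), scale * np.sin(ang)])


def generate_trajectory(
    spec: TrajectorySpec, seed: int
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Return (embedding, clusters, expression, maturation).

    * ``embedding`` — DataFrame indexed by cell_id with columns x, y;
    * ``clusters`` — Series of ordered integer cluster ids (0 = start);
    * ``expression`` — genes x cells DataFrame of noisy log-scale bumps;
    * ``maturation`` — the latent coordinate in [0, 1] (ground truth).
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(spec.n_cells))
    cell_ids = [f"cell{i:05d}" for i in range(spec.n_cells)]
    xy = _curve_xy(t, spec.curve, spec.scale)
    xy = xy + rng.normal(0.0, spec.embedding_noise_sd, size=xy.shape)
    clusters = np.minimum((t * spec.n_clusters).astype(int), spec.n_clusters - 1)

    genes = list(spec.gene_peaks)
    expr = np.empty((len(genes), spec.n_cells))
    for i, g in enumerate(genes):
        peak = spec.gene_peaks[g]
        expr[i] = spec.amplitude * np.exp(-0.5 * ((t - peak) / spec.peak_width) ** 2)
    expr += rng.normal(0.0, spec.expression_noise_sd, size=expr.shape)
    expr = np.clip(expr, 0.0, None)

    embedding = pd.DataFrame(xy, index=cell_ids, columns=["x", "y"])
    return (
        embedding,
        pd.Series(clusters, index=cell_ids, name="cluster"),
        pd.DataFrame(expr, index=genes, columns=cell_ids),
        pd.Series(t, index=cell_ids, name="maturation"),
    )
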