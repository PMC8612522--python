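"""Correlation-structure analyses of temporal gene expression.

Spearman TF-TF correlation matrices across cells, genome-wide correlation
rank tables against a reference gene (Nfib- or Zfhx3-style rank plots),
stage-profile construction (log-scaled per-stage means, z-scored across
stages), and the in-vivo/in-vitro Pearson partition that classifies each gene
as correlated (r > 0.5), anticorrelated (r < -0.5) or uncorrelated between
paired embryonic stages and differentiation days.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "correlation_rank",
    "stage_profiles",
    "partition_by_correlation",
    "DEFAULT_STAGE_PAIRS",
]

#: positional pairing of embryonic stages with in vitro differentiation days
DEFAULT_STAGE_PAIRS = (
    ("e9.5", "D5"),
    ("e10.5", "D6"),
    ("e11.5", "D7"),
    ("e12.5", "D8"),
    ("e13.5", "D9"),
)

CORRELATED = "correlated"
UNCORRELATED = "uncorrelated"
ANTICORRELATED = "anticorrelated"


def spearman_matrix(expr: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlation between gene rows over cells.

    ``expr`` is genes x cells.  The diagonal is set to exactly 1; constant
    rows yield NaN off-diagonals (logged).
    """
    if genes is not None:
        expr = expr.loc[genes]
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 cells")
    mat = expr.to_numpy(dtype=float)
    rho = spearmanr(mat, axis=1).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # two genes: spearmanr returns a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    if np.isnan(rho).any():
        logger.warning("spearman_matrix: constant gene rows give NaN correlations")
    return pd.DataFrame(rho, index=expr.index, columns=expr.index)


def correlation_rank(
    expr: pd.DataFrame, reference_gene: str, highlight: set[str] = frozenset()
) -> pd.DataFrame:
    """Rank all genes by descending Spearman correlation to a reference gene.

    The reference itself correlates perfectly with itself and takes rank 1
    (ties broken in its favor, then alphabetically).  ``highlight`` membership
    is flagged for plotting.
    """
    if reference_gene not in expr.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression table")
    ref = expr.loc[reference_gene].to_numpy(dtype=float)
    if (expr.loc[reference_gene] != 0).sum() < 3:
        raise ValueError("reference gene expressed in fewer than 3 cells")
    rows = []
    for gene in expr.index:
        r = spearmanr(ref, expr.loc[gene].to_numpy(dtype=float)).statistic
        rows.append({"gene": gene, "r": float(r)})
    out = pd.DataFrame(rows)
    out["is_reference"] = out["gene"] == reference_gene
    out = out.sort_values(
        ["r", "is_reference", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["highlighted"] = out["gene"].isin(set(highlight))
    return out.drop(columns="is_reference")


def stage_profiles(
    expr: pd.DataFrame,
    stages: pd.Series | list[str],
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene stage profiles: per-stage means on log scale, z-scored across stages.

    ``expr`` is genes x samples (cells or bulk replicates); ``stages`` assigns
    each sample column to an ordered stage.  Constant genes become zero rows
    (logged), matching the heatmap convention.
    """
    stages = pd.Series(np.asarray(stages), index=expr.columns)
    ordered = list(dict.fromkeys(stages))
    mat = expr.to_numpy(dtype=float)
    if log_transform:
        mat = np.log1p(mat)
    means = np.column_stack(
        [mat[:, (stages == s).to_numpy()].mean(axis=1) for s in ordered]
    )
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    flat = (sd.ravel() <= 1e-12 * np.maximum(1.0, np.abs(mu.ravel())))
    if flat.any():
        logger.warning("stage_profiles: %d constant genes set to zero", int(flat.sum()))
    sd[flat, :] = 1.0
    z = (means - mu) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=ordered)


def partition_by_correlation(
    in_vivo: pd.DataFrame,
    in_vitro: pd.DataFrame,
    stage_pairs: tuple[tuple[str, str], ...] = DEFAULT_STAGE_PAIRS,
    tf_list: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pearson-partition genes by in-vivo vs in-vitro stage-profile agreement.

    Profiles are restricted to the paired stages, the gene universe is
    intersected, and per-gene Pearson r over the paired values assigns the
    class: correlated iff r > 0.5, anticorrelated iff r < -0.5, uncorrelated
    otherwise.  A constant profile on either side leaves r undefined; such
    genes are classed uncorrelated with ``flagged=True``.

    Returns the per-gene table and a summary dict with class counts (plus TF
    counts when a TF list is given).
    """
    vivo_stages = [p[0] for p in stage_pairs]
    vitro_stages = [p[1] for p in stage_pairs]
    missing = [s for s in vivo_stages if s not in in_vivo.columns] + [
        s for s in vitro_stages if s not in in_vitro.columns
    ]
    if missing:
        raise KeyError(f"stages missing from profiles: {missing}")
    genes = [g for g in in_vivo.index if g in set(in_vitro.index)]
    a = in_vivo.loc[genes, vivo_stages].to_numpy(dtype=float)
    b = in_vitro.loc[genes, vitro_stages].to_numpy(dtype=float)

    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a_c**2).sum(axis=1))
    sb = np.sqrt((b_c**2).sum(axis=1))
    flagged = (sa == 0) | (sb == 0)
    denom = np.where(flagged, 1.0, sa * sb)
    r = (a_c * b_c).sum(axis=1) / denom
    r[flagged] = np.nan

    cls = np.full(len(genes), UNCORRELATED, dtype=object)
    cls[np.nan_to_num(r) > 0.5] = CORRELATED
    cls[np.nan_to_num(r) < -0.5] = ANTICORRELATED
    cls[flagged] = UNCORRELATED

    table = pd.DataFrame({"gene": genes, "r": r, "class": cls, "flagged": flagged})
    summary = {
        "n_genes": len(genes),
        "n_correlated": int((cls == CORRELATED).sum()),
        "n_uncorrelated": int((cls == UNCORRELATED).sum()),
        "n_anticorrelated": int((cls == ANTICORRELATED).sum()),
    }
    if tf_list is not None:
        tfs = set(tf_list)
        is_tf = table["gene"].isin(tfs)
        for name in (CORRELATED, UNCORRELATED, ANTICORRELATED):
            summary[f"n_tf_{name}"] = int((is_tf & (table["class"] == name)).sum())
    return table, summary
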