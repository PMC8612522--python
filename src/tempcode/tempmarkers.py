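"""Temporal marker discovery in neural progenitors.

Re-implements the marker workflow used for stage-resolved single-cell data:
depth normalization to 10,000 counts per cell followed by log1p; per-domain,
per-stage one-vs-rest differential expression with detection-fraction
(min.pct) and log-fold-change pre-filters and a Wilcoxon rank-sum test with
Bonferroni adjustment; a cross-domain consistency filter that keeps genes
recurring as stage markers in more than ``min_domains`` progenitor domains;
TF subsetting against a symbol list; and z-scored log-expression matrices for
heatmaps.

The rank-sum test uses exact enumeration (mid-ranks, all label assignments)
when both groups have at most 8 cells, and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedExpression",
    "TemporalGeneSet",
    "read_counts",
    "write_counts",
    "normalize_counts",
    "rank_sum_test",
    "stage_markers",
    "cross_domain_filter",
    "subset_tfs",
    "load_tf_list",
    "zscore_matrix",
]

NORM_TOTAL = 10_000.0
EXACT_MAX_N = 8


@dataclass
class CountMatrix:
    """Sparse genes x cells integer counts with per-cell annotations.

    ``cell_meta`` must carry columns ``cell_id``, ``domain``, ``stage``,
    ``cell_type`` (one row per cell, aligned to count columns).
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    truth: pd.DataFrame | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length must match count rows")
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValueError("cell_meta length must match count columns")
        missing = {"cell_id", "domain", "stage", "cell_type"} - set(self.cell_meta)
        if missing:
            raise ValueError(f"cell_meta missing columns: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedExpression:
    """Depth-normalized expression: per-cell totals rescaled to 10,000, plus log1p."""

    norm: sp.csr_matrix
    lognorm: sp.csr_matrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class TemporalGeneSet:
    """Genes recurrently temporal across progenitor domains."""

    genes: list[str]
    domain_hit_counts: dict[str, int]
    tf_subset: list[str] = field(default_factory=list)


def read_counts(path: Path | str) -> CountMatrix:
    """Read MatrixMarket counts + genes.tsv + cells.tsv from a directory."""
    path = Path(path)
    counts = sp.csr_matrix(mmread(path / "counts.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    truth_file = path / "truth.csv"
    truth = pd.read_csv(truth_file) if truth_file.exists() else None
    return CountMatrix(counts=counts, gene_ids=genes, cell_meta=cells, truth=truth)


def write_counts(cm: CountMatrix, path: Path | str) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "counts.mtx", sp.coo_matrix(cm.counts))
    pd.Series(cm.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    cm.cell_meta.to_csv(path / "cells.tsv", sep="\t", index=False)
    if cm.truth is not None:
        cm.truth.to_csv(path / "truth.csv", index=False)


def normalize_counts(cm: CountMatrix) -> NormalizedExpression:
    """Scale every cell to 10,000 total counts; store log1p alongside.

    Raises if any cell has zero total counts (its scaling is undefined),
    listing the offending cell ids.
    """
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = cm.cell_meta["cell_id"].iloc[zero].tolist()
        raise ValueError(f"cells with zero total counts: {ids}")
    scale = sp.diags(NORM_TOTAL / totals)
    norm = sp.csr_matrix(cm.counts @ scale)
    lognorm = norm.copy()
    lognorm.data = np.log1p(lognorm.data)
    return NormalizedExpression(
        norm=norm, lognorm=lognorm, gene_ids=list(cm.gene_ids), cell_meta=cm.cell_meta
    )


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Mid-ranks handle ties; the two-sided p doubles the smaller tail
    probability of the rank-sum of ``x``, capped at 1.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    total = comb(n1 + n2, n1)
    n_le = n_ge = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        s = ranks[list(idx)].sum()
        if s <= w_obs + 1e-9:
            n_le += 1
        if s >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Exact enumeration when both groups have <= 8 observations, otherwise the
    tie-corrected normal approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return _exact_ranksum_p(x, y)
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def stage_markers(
    norm: NormalizedExpression,
    domain: str,
    min_pct: float = 0.25,
    lfc_threshold: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Stage-wise one-vs-rest markers within one progenitor domain.

    For each stage present in the domain (with at least ``min_cells`` cells)
    and each gene: detection fractions ``pct_in``/``pct_out`` are computed on
    nonzero counts; genes pass only if ``max(pct_in, pct_out) >= min_pct``;
    the natural-log fold change of group means of ``expm1(lognorm)`` with
    pseudocount 1 must satisfy ``|lnFC| >= lfc_threshold``; surviving genes
    get a two-sided rank-sum p on log-normalized values, Bonferroni-adjusted
    over the genes tested in that comparison.  Only significant rows
    (``p_adj < alpha``) are returned.
    """
    meta = norm.cell_meta
    in_domain = np.where((meta["domain"] == domain).to_numpy())[0]
    if in_domain.size == 0:
        raise ValueError(f"no cells in domain {domain!r}")
    stages = meta["stage"].iloc[in_domain]
    counts_per_stage = stages.value_counts()
    usable = [s for s in sorted(counts_per_stage.index) if counts_per_stage[s] >= min_cells]
    skipped = sorted(set(counts_per_stage.index) - set(usable))
    if skipped:
        logger.warning("domain %s: skipping stages with < %d cells: %s", domain, min_cells, skipped)
    if len(usable) < 2:
        raise ValueError(f"domain {domain!r} needs >= 2 stages with >= {min_cells} cells")

    sub_log = np.asarray(norm.lognorm[:, in_domain].todense())
    expr = np.expm1(sub_log)  # back to depth-normalized scale
    detected = expr > 0
    stage_arr = stages.to_numpy()
    genes = np.asarray(norm.gene_ids)

    rows: list[dict] = []
    for stage in usable:
        grp = stage_arr == stage
        n_in, n_out = int(grp.sum()), int((~grp).sum())
        pct_in = detected[:, grp].sum(axis=1) / n_in
        pct_out = detected[:, ~grp].sum(axis=1) / n_out
        keep = np.maximum(pct_in, pct_out) >= min_pct
        mean_in = expr[:, grp].mean(axis=1)
        mean_out = expr[:, ~grp].mean(axis=1)
        lnfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        keep &= np.abs(lnfc) >= lfc_threshold
        tested = np.where(keep)[0]
        if tested.size == 0:
            continue
        n_tests = tested.size
        if n_in > EXACT_MAX_N or n_out > EXACT_MAX_N:
            res = mannwhitneyu(
                sub_log[tested][:, grp],
                sub_log[tested][:, ~grp],
                alternative="two-sided",
                method="asymptotic",
                axis=1,
            )
            pvals = np.atleast_1d(res.pvalue)
        else:
            pvals = np.array(
                [_exact_ranksum_p(sub_log[g, grp], sub_log[g, ~grp]) for g in tested]
            )
        padj = np.minimum(pvals * n_tests, 1.0)
        for k, g in enumerate(tested):
            if padj[k] < alpha:
                rows.append(
                    {
                        "gene": genes[g],
                        "domain": domain,
                        "stage": stage,
                        "ln_fold_change": float(lnfc[g]),
                        "pct_in": float(pct_in[g]),
                        "pct_out": float(pct_out[g]),
                        "p": float(pvals[k]),
                        "p_adj": float(padj[k]),
                    }
                )
    cols = ["gene", "domain", "stage", "ln_fold_change", "pct_in", "pct_out", "p", "p_adj"]
    return pd.DataFrame(rows, columns=cols)


def cross_domain_filter(
    per_domain_marker_sets: dict[str, set[str]],
    min_domains: int = 7,
    excluded_domains: set[str] = frozenset({"dp6"}),
) -> TemporalGeneSet:
    """Keep genes appearing as stage markers in strictly more than ``min_domains`` domains.

    ``excluded_domains`` (dp6 by default, a sparsely sampled domain) are
    dropped before counting.
    """
    counts: dict[str, int] = {}
    for dom, genes in per_domain_marker_sets.items():
        if dom in excluded_domains:
            continue
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    kept = sorted((g for g, c in counts.items() if c > min_domains),
                  key=lambda g: (-counts[g], g))
    return TemporalGeneSet(genes=kept, domain_hit_counts={g: counts[g] for g in kept})


def load_tf_list(path: Path | str | None = None) -> list[str]:
    """Load a TF symbol list (one symbol per line, '#' comments allowed).

    Without a path, a bundled miniature synthetic list of mouse TF symbols is
    used; real analyses should point this at a genome-wide TF catalog.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "tf_list.txt"
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def subset_tfs(genes: list[str], tf_list: list[str]) -> list[str]:
    """Intersect ``genes`` with a TF symbol list, preserving input order."""
    tfs = set(tf_list)
    return [g for g in genes if g in tfs]


def zscore_matrix(
    norm: NormalizedExpression,
    genes: list[str],
    group_by: list[str] | str = ("domain", "stage"),
) -> pd.DataFrame:
    """Mean log-normalized expression per group, z-scored across groups per gene.

    Zero-variance rows become all zeros (logged) rather than NaN.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    group_by = list(group_by)
    meta = norm.cell_meta
    idx = [norm.gene_index(g) for g in genes]
    dense = np.asarray(norm.lognorm[idx, :].todense())
    keys = meta[group_by].astype(str).agg("|".join, axis=1).to_numpy()
    groups = sorted(set(keys))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to z-score across")
    means = np.column_stack([dense[:, keys == g].mean(axis=1) for g in groups])
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    flat = (sd.ravel() <= 1e-12 * np.maximum(1.0, np.abs(mu.ravel())))
    if flat.any():
        logger.warning("zscore_matrix: %d constant gene rows set to zero", int(flat.sum()))
    sd[flat, :] = 1.0
    z = (means - mu) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=genes, columns=groups)
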