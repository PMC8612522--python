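"""Flow-cytometry gating and group comparison.

Implements the quantification used for stem-cell-derived neural cultures:
live/single-cell gating on a viability stain and forward/side scatter, a
Sox2/Tubb3 rectangular split into progenitors and neurons, a per-sample
dynamic positivity threshold calibrated so that 1-2% of Sox2-positive
progenitors score positive (default target 1.5%), an alternative global
threshold mode for markers expressed in both compartments (Nfia), and
unpaired t tests (pooled-variance and Welch) with the conventional
significance stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "GateResult",
    "gate_live_single",
    "split_progenitor_neuron",
    "dynamic_threshold",
    "global_threshold",
    "percent_positive",
    "welch_t_test",
    "student_t_test",
    "significance_stars",
    "gate_sample",
]

REQUIRED_CHANNELS = ("viability", "fsc", "ssc", "sox2", "tubb3", "marker")
MIN_PROGENITORS = 50


@dataclass(frozen=True)
class GateConfig:
    """Gating parameters (linear intensity units).

    Defaults match the synthetic flow model: live cells sit below the
    viability cutoff, scatter selects the main cell population, and the
    Sox2/Tubb3 thresholds split the two well-separated marker modes.
    """

    viability_max: float = 10**2.75
    scatter_box: tuple[tuple[float, float], tuple[float, float]] = (
        (10**2.6, 10**3.4),
        (10**2.6, 10**3.4),
    )
    sox2_threshold: float = 10**2.4
    tubb3_threshold: float = 10**2.4
    target_progenitor_fraction: float = 0.015
    mode: str = "dynamic"  # or "global"
    global_threshold: float | None = None
    global_quantile: float = 0.975

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic", "global"):
            raise ValueError("mode must be 'dynamic' or 'global'")
        if not 0.0 <= self.target_progenitor_fraction <= 1.0:
            raise ValueError("target_progenitor_fraction must be in [0, 1]")


@dataclass
class GateResult:
    """Per-sample positivity summary."""

    threshold_used: float
    pct_pos_neurons: float
    pct_pos_progenitors: float
    n_neurons: int
    n_progenitors: int
    mode: str = "dynamic"


def _require(events: pd.DataFrame, channels=REQUIRED_CHANNELS) -> None:
    for ch in channels:
        if ch not in events.columns:
            raise KeyError(f"missing flow channel {ch!r}")


def gate_live_single(events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Keep live singlets: viability below cutoff and scatter inside the box."""
    _require(events, ("viability", "fsc", "ssc"))
    (f_lo, f_hi), (s_lo, s_hi) = cfg.scatter_box
    keep = (
        (events["viability"] < cfg.viability_max)
        & events["fsc"].between(f_lo, f_hi)
        & events["ssc"].between(s_lo, s_hi)
    )
    return events[keep].reset_index(drop=True)


def split_progenitor_neuron(events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Rectangular Sox2/Tubb3 split; double-positive/negative events stay unassigned."""
    _require(events, ("sox2", "tubb3"))
    out = events.copy()
    sox_hi = out["sox2"] > cfg.sox2_threshold
    tub_hi = out["tubb3"] > cfg.tubb3_threshold
    out["gated_class"] = "unassigned"
    out.loc[sox_hi & ~tub_hi, "gated_class"] = "progenitor"
    out.loc[tub_hi & ~sox_hi, "gated_class"] = "neuron"
    return out


def dynamic_threshold(
    progenitor_marker_intensities: np.ndarray, target_fraction: float = 0.015
) -> float:
    """Per-sample threshold: the (1 - target) empirical quantile of progenitors.

    Linear interpolation between order statistics, so for continuous data the
    fraction of progenitors strictly above the threshold matches the target
    (1-2% band for the default 1.5%).
    """
    x = np.asarray(progenitor_marker_intensities, dtype=float)
    if x.size < MIN_PROGENITORS:
        raise ValueError(
            f"only {x.size} progenitor events (< {MIN_PROGENITORS}); "
            "use a global threshold instead"
        )
    return float(np.quantile(x, 1.0 - target_fraction))


def global_threshold(
    pooled_intensities: np.ndarray, quantile: float = 0.975
) -> float:
    """Run-wide threshold: a high quantile of pooled progenitor+neuron intensities."""
    return float(np.quantile(np.asarray(pooled_intensities, dtype=float), quantile))


def percent_positive(intensities: np.ndarray, threshold: float) -> float:
    """100 x fraction of events strictly above the threshold (0 for empty input)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        logger.warning("percent_positive on empty input; reporting 0")
        return 0.0
    return float(100.0 * (x > threshold).mean())


def gate_sample(events: pd.DataFrame, cfg: GateConfig) -> GateResult:
    """Full per-sample gating: live gate, Sox2/Tubb3 split, threshold, percentages."""
    gated = split_progenitor_neuron(gate_live_single(events, cfg), cfg)
    prog = gated.loc[gated["gated_class"] == "progenitor", "marker"].to_numpy()
    neur = gated.loc[gated["gated_class"] == "neuron", "marker"].to_numpy()
    if cfg.mode == "dynamic":
        thr = dynamic_threshold(prog, cfg.target_progenitor_fraction)
    else:
        thr = (
            cfg.global_threshold
            if cfg.global_threshold is not None
            else global_threshold(np.concatenate([prog, neur]), cfg.global_quantile)
        )
    return GateResult(
        threshold_used=thr,
        pct_pos_neurons=percent_positive(neur, thr),
        pct_pos_progenitors=percent_positive(prog, thr),
        n_neurons=len(neur),
        n_progenitors=len(prog),
        mode=cfg.mode,
    )


def _describe(a: np.ndarray) -> tuple[int, float, float]:
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("each group needs n >= 2")
    return a.size, a.mean(), a.var(ddof=1)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Unpaired t test with Welch's correction: (t, df, two-sided p).

    t = (ma - mb) / sqrt(va/na + vb/nb); df by Welch-Satterthwaite.  When both
    groups have zero variance and equal means the comparison is vacuous and
    (0, n-2, 1) is returned (logged).
    """
    na, ma, va = _describe(a)
    nb, mb, vb = _describe(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        logger.warning("welch_t_test: zero variance in both groups")
        if ma == mb:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.inf) if ma > mb else float(-np.inf), float(na + nb - 2), 0.0
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def student_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Unpaired pooled-variance t test: (t, df, two-sided p)."""
    na, ma, va = _describe(a)
    nb, mb, vb = _describe(b)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if denom == 0:
        logger.warning("student_t_test: zero pooled variance")
        return (0.0, float(df), 1.0) if ma == mb else (np.inf, float(df), 0.0)
    t = (ma - mb) / denom
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def significance_stars(p: float) -> str:
    """Conventional star coding: p<0.001 -> ***, p<0.01 -> **, p<0.05 -> *, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
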