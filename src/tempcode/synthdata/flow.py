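"""Synthetic flow-cytometry event tables for progenitor/neuron gating.

Events come from per-subpopulation Gaussians on the log10-intensity scale for
six channels (viability, fsc, ssc, Sox2, Tubb3, marker).  Progenitors are
Sox2-high/Tubb3-low, neurons the reverse; a configurable fraction of each
class carries the queried marker (a separate high-intensity mode).  A small
fraction of dead cells with a bright viability stain exercises the live gate.
Ground-truth columns (``true_class``, ``marker_true``) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FlowSpec", "generate_flow_events", "DEFAULT_CHANNEL_MODEL"]

CHANNELS = ("viability", "fsc", "ssc", "sox2", "tubb3", "marker")

#: (log10 mean, log10 sd) per channel for each subpopulation.
DEFAULT_CHANNEL_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "progenitor": {
        "viability": (2.0, 0.2),
        "fsc": (3.0, 0.10),
        "ssc": (3.0, 0.10),
        "sox2": (3.0, 0.15),
        "tubb3": (1.8, 0.15),
        "marker": (1.5, 0.15),
    },
    "neuron": {
        "viability": (2.0, 0.2),
        "fsc": (3.0, 0.10),
        "ssc": (3.0, 0.10),
        "sox2": (1.8, 0.15),
        "tubb3": (3.0, 0.15),
        "marker": (1.5, 0.15),
    },
    "dead": {
        "viability": (3.5, 0.15),
        "fsc": (2.6, 0.2),
        "ssc": (3.2, 0.2),
        "sox2": (2.0, 0.4),
        "tubb3": (2.0, 0.4),
        "marker": (1.5, 0.3),
    },
}

#: log10 (mean, sd) of the marker channel for marker-positive cells.
DEFAULT_MARKER_POSITIVE_MODE = (3.0, 0.15)


@dataclass(frozen=True)
class FlowSpec:
    """Parameters of one synthetic flow sample."""

    n_events: int = 20_000
    progenitor_fraction: float = 0.4
    dead_fraction: float = 0.05
    marker_positive_fraction_neurons: float = 0.5
    marker_positive_fraction_progenitors: float = 0.0
    channel_model: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_CHANNEL_MODEL
    )
    marker_positive_mode: tuple[float, float] = DEFAULT_MARKER_POSITIVE_MODE

    def __post_init__(self) -> None:
        for f in (
            self.progenitor_fraction,
            self.dead_fraction,
            self.marker_positive_fraction_neurons,
            self.marker_positive_fraction_progenitors,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for pop, chans in self.channel_model.items():
            for ch, (_, sd) in chans.items():
                if sd <= 0:
                    raise ValueError(f"sd must be positive ({pop}/{ch})")


def generate_flow_events(spec: FlowSpec, seed: int) -> pd.DataFrame:
    """Sample one event table.

    Returns a DataFrame with linear-scale intensity columns ``viability, fsc,
    ssc, sox2, tubb3, marker`` plus truth columns ``true_class`` (progenitor /
    neuron / dead) and ``marker_true``.  Deterministic per ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_events
    u = rng.random(n)
    cls = np.where(
        u < spec.dead_fraction,
        "dead",
        np.where(
            u < spec.dead_fraction + (1 - spec.dead_fraction) * spec.progenitor_fraction,
            "progenitor",
            "neuron",
        ),
    )
    marker_true = np.zeros(n, dtype=bool)
    for pop, frac in (
        ("neuron", spec.marker_positive_fraction_neurons),
        ("progenitor", spec.marker_positive_fraction_progenitors),
    ):
        mask = cls == pop
        marker_true[mask] = rng.random(int(mask.sum())) < frac

    data: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        vals = np.empty(n)
        for pop in ("progenitor", "neuron", "dead"):
            mask = cls == pop
            mean, sd = spec.channel_model[pop][ch]
            vals[mask] = rng.normal(mean, sd, int(mask.sum()))
        if ch == "marker":
            mean, sd = spec.marker_positive_mode
            vals[marker_true] = rng.normal(mean, sd, int(marker_true.sum()))
        data[ch] = 10.0 ** vals

    out = pd.DataFrame(data)
    out.insert(0, "event_id", np.arange(n))
    out["true_class"] = cls
    out["marker_true"] = marker_true
    return out
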