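"""Temporal transcription-factor program: birthdate windows and progenitor onsets.

The central nervous system stratifies neurons by the embryonic day on which
they are born.  Neurons born early express Onecut-family TFs, neurons born at
intermediate stages express Pou2f2 and Zfhx3, and late-born neurons express
Nfia/Nfib and Neurod2.  A :class:`TemporalProgram` encodes this as a map from
TF symbol to a half-open birthdate window ``[on, off)`` in embryonic days:
a neuron born at day ``b`` expresses the TF iff ``on <= b < off``.  Cycling
progenitors are handled separately: late progenitor genes (Sox9, Nfia, Nfib)
switch on in all progenitors once the embryo reaches the gene's onset day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["TemporalProgram", "temporal_tf_state", "NEURON", "PROGENITOR"]

NEURON = "neuron"
PROGENITOR = "progenitor"

#: Default neuronal birthdate windows (embryonic days, half-open [on, off)).
DEFAULT_TF_WINDOWS: dict[str, tuple[float, float]] = {
    "Onecut2": (9.0, 10.5),
    "Zfhx3": (9.0, 11.5),
    "Pou2f2": (10.5, 11.5),
    "Nfia": (11.5, 13.5),
    "Nfib": (11.5, 13.5),
    "Neurod2": (11.5, 13.5),
}

#: Default onset days for late progenitor genes (gliogenic switch markers).
DEFAULT_PROGENITOR_ONSETS: dict[str, float] = {
    "Sox9": 11.0,
    "Nfia": 11.5,
    "Nfib": 11.5,
}


def _midpoint(w: tuple[float, float]) -> float:
    return 0.5 * (w[0] + w[1])


@dataclass(frozen=True)
class TemporalProgram:
    """Birthdate windows for neuronal TFs plus onset days for progenitor genes.

    Parameters
    ----------
    tf_windows
        Map TF symbol -> half-open interval ``[on, off)`` in embryonic days
        during which a neuron born then expresses the TF.
    progenitor_onsets
        Map late-progenitor gene symbol -> embryonic day from which the gene
        is expressed in all cycling progenitors.
    """

    tf_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TF_WINDOWS)
    )
    progenitor_onsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROGENITOR_ONSETS)
    )

    def __post_init__(self) -> None:
        for tf, (on, off) in self.tf_windows.items():
            if not on < off:
                raise ValueError(f"empty birthdate window for {tf}: [{on}, {off})")
        zf = self.tf_windows.get("Zfhx3")
        nfib = self.tf_windows.get("Nfib")
        oc = self.tf_windows.get("Onecut2")
        if oc and zf and nfib:
            if not (_midpoint(oc) < _midpoint(zf) < _midpoint(nfib)):
                raise ValueError(
                    "temporal order violated: Onecut2, Zfhx3, Nfib window "
                    "midpoints must be increasing"
                )
        if zf and nfib and zf[1] > nfib[0] and nfib[1] > zf[0]:
            raise ValueError("Zfhx3 and Nfib windows must be disjoint")

    @property
    def genes(self) -> list[str]:
        """All genes the program speaks about (neuronal TFs + progenitor genes)."""
        out = list(self.tf_windows)
        out += [g for g in self.progenitor_onsets if g not in self.tf_windows]
        return out

    def window(self, tf: str) -> tuple[float, float]:
        try:
            return self.tf_windows[tf]
        except KeyError:
            raise KeyError(
                f"unknown TF {tf!r}; program knows {sorted(self.tf_windows)}"
            ) from None


def temporal_tf_state(
    birthdate: float,
    cell_class: str,
    program: TemporalProgram,
    collection_day: float | None = None,
) -> dict[str, bool]:
    """Expression state of every program gene for one cell.

    For a neuron, each TF is on iff ``birthdate`` falls inside its half-open
    window.  For a progenitor, neuronal windows do not apply (all off) and each
    late progenitor gene is on iff ``collection_day`` has reached its onset.

    Parameters
    ----------
    birthdate
        Embryonic day of birth.  May be NaN for progenitors (which are still
        cycling and have no birthdate).
    cell_class
        ``"neuron"`` or ``"progenitor"``.
    collection_day
        Embryonic day at which the tissue is examined; required to evaluate
        progenitor onsets (defaults to ``birthdate``).
    """
    if cell_class not in (NEURON, PROGENITOR):
        raise ValueError(f"unknown cell class {cell_class!r}")
    if collection_day is None:
        collection_day = birthdate
    state: dict[str, bool] = {}
    if cell_class == NEURON:
        if not math.isfinite(birthdate):
            raise ValueError("neurons require a finite birthdate")
        for tf, (on, off) in program.tf_windows.items():
            state[tf] = on <= birthdate < off
        for gene in program.progenitor_onsets:
            state.setdefault(gene, False)
    else:
        for tf in program.tf_windows:
            state[tf] = False
        if not math.isfinite(collection_day):
            raise ValueError("progenitors require a finite collection day")
        for gene, onset in program.progenitor_onsets.items():
            state[gene] = collection_day >= onset
    return state
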