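"""Synthetic multi-channel cryosection images with per-nucleus ground truth.

Each section emulates a transverse neural-tube cryosection imaged in four
channels (DAPI, a class marker, one temporal TF, EdU).  Nuclei are rendered as
flat-top ellipses with a 1-pixel Gaussian edge blur; a nucleus is bright in a
channel according to its ground-truth state:

* DAPI — every nucleus;
* class marker — neurons if the marker is HuC, progenitors if Sox2;
* TF channel — nuclei whose temporal program state for that TF is on;
* EdU — neurons born within ``edu_window_halfwidth`` days of the pulse, and
  progenitors with an independent Bernoulli S-phase label.

Noise is additive Gaussian with standard deviation ``amplitude / snr``.
Generation is a pure function of (spec, program, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .program import NEURON, PROGENITOR, TemporalProgram, temporal_tf_state

__all__ = [
    "SectionSpec",
    "SectionImage",
    "PlacementError",
    "generate_section",
    "write_section",
    "read_section",
]

#: nominal signal unit in float units (images are scaled to 16 bit on write);
#: noise sd is SIGNAL_AMPLITUDE / snr
SIGNAL_AMPLITUDE = 1.0
#: stained nuclei are rendered this factor above the nominal unit so that the
#: class separation meets the nominal snr bound strictly despite edge
#: softening, zero-clipping, and 16-bit quantization
RENDER_BOOST = 1.15
#: 16-bit scale factor applied when quantizing float intensities
INT_SCALE = 10_000.0

DEFAULT_BIRTHDATE_GRID = tuple(np.round(np.arange(9.0, 13.01, 0.25), 3))


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic section.

    Distances are pixels, times embryonic days.  ``birthdate_distribution``
    maps embryonic days to (unnormalized) mixture weights for neuronal
    birthdates; the default is uniform over a 0.25-day grid e9.0–e13.0.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 120
    nucleus_radius_range: tuple[float, float] = (5.0, 9.0)
    progenitor_fraction: float = 0.3
    birthdate_distribution: dict[float, float] = field(
        default_factory=lambda: {d: 1.0 for d in DEFAULT_BIRTHDATE_GRID}
    )
    edu_pulse_day: float = 12.5
    edu_window_halfwidth: float = 0.25
    edu_progenitor_rate: float = 0.3
    collection_day: float = 13.5
    tf_channel: str = "Nfib"
    class_marker: str = "HuC"
    snr: float = 8.0
    background_level: float = 0.1

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus radii must be positive and ordered")
        if self.edu_pulse_day > self.collection_day:
            raise ValueError("edu_pulse_day must not exceed collection_day")
        if self.class_marker not in ("HuC", "Sox2"):
            raise ValueError("class_marker must be 'HuC' or 'Sox2'")
        if not 0.0 <= self.progenitor_fraction <= 1.0:
            raise ValueError("progenitor_fraction must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SectionImage:
    """A multi-channel 2D image with named channels and a pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails within the retry budget."""


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_dist: float,
    margin: float,
    retry_budget: int,
) -> np.ndarray:
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= retry_budget:
            achievable = len(centers)
            usable = (shape[0] - 2 * margin) * (shape[1] - 2 * margin)
            density_hint = int(usable / (math.pi * min_dist**2))
            raise PlacementError(
                f"placed only {achievable}/{n} nuclei after {retry_budget} "
                f"attempts; at min spacing {min_dist:.1f}px roughly "
                f"{density_hint} nuclei fit this field"
            )
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        ok = all((r - rr) ** 2 + (c - cc) ** 2 >= min_dist**2 for rr, cc in centers)
        if ok:
            centers.append((r, c))
    return np.asarray(centers, dtype=float)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
) -> tuple[slice, slice, np.ndarray]:
    """Flat-top ellipse with a 1-px Gaussian edge, on a local bounding box."""
    r0, c0 = center
    pad = int(math.ceil(max(a, b))) + 4
    rs = slice(max(0, int(r0) - pad), min(shape[0], int(r0) + pad + 1))
    cs = slice(max(0, int(c0) - pad), min(shape[1], int(c0) + pad + 1))
    rr, cc = np.mgrid[rs, cs]
    dr, dc = rr - r0, cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    hard = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
    # flat-top profile: interior stays at 1, the Gaussian skirt only decays outward
    soft = np.maximum(hard, gaussian_filter(hard, sigma=1.0))
    return rs, cs, soft


def generate_section(
    spec: SectionSpec, program: TemporalProgram, seed: int
) -> tuple[SectionImage, pd.DataFrame]:
    """Render one section and its ground-truth table.

    Returns the image (channels ordered DAPI, class marker, TF, EdU) and a
    DataFrame with one row per nucleus: ``nucleus_id, center_row, center_col,
    radius, cell_class, birthdate, edu_true`` plus one ``tf_<gene>`` boolean
    column per program gene.  Identical ``(spec, seed)`` give bit-identical
    outputs.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.image_shape)
    lo, hi = spec.nucleus_radius_range
    min_dist = 1.5 * hi
    margin = hi + 2.0

    centers = (
        _place_centers(rng, shape, spec.n_nuclei, min_dist, margin, 200 * max(spec.n_nuclei, 1))
        if spec.n_nuclei
        else np.empty((0, 2))
    )
    n = len(centers)
    major = rng.uniform(lo, hi, size=n)
    ratio = rng.uniform(0.7, 1.0, size=n)
    minor = major * ratio
    theta = rng.uniform(0.0, math.pi, size=n)
    is_prog = rng.random(n) < spec.progenitor_fraction

    days = np.array(sorted(spec.birthdate_distribution), dtype=float)
    w = np.array([spec.birthdate_distribution[d] for d in days], dtype=float)
    w = w / w.sum()
    birth = days[rng.choice(len(days), size=n, p=w)] if n else np.empty(0)
    birth = birth.astype(float)
    birth[is_prog] = np.nan

    edu = np.zeros(n, dtype=bool)
    neuron_mask = ~is_prog
    edu[neuron_mask] = (
        np.abs(birth[neuron_mask] - spec.edu_pulse_day) <= spec.edu_window_halfwidth
    )
    edu[is_prog] = rng.random(int(is_prog.sum())) < spec.edu_progenitor_rate

    genes = program.genes
    tf_true = {g: np.zeros(n, dtype=bool) for g in genes}
    for i in range(n):
        cls = PROGENITOR if is_prog[i] else NEURON
        state = temporal_tf_state(birth[i], cls, program, spec.collection_day)
        for g in genes:
            tf_true[g][i] = state[g]

    if spec.tf_channel not in genes:
        raise KeyError(
            f"unknown TF channel {spec.tf_channel!r}; program knows {sorted(genes)}"
        )

    # which nuclei are bright per channel
    bright = {
        "DAPI": np.ones(n, dtype=bool),
        spec.class_marker: is_prog if spec.class_marker == "Sox2" else neuron_mask,
        spec.tf_channel: tf_true[spec.tf_channel],
        "EdU": edu,
    }

    canvases = {name: np.full(shape, spec.background_level) for name in bright}
    for i in range(n):
        rs, cs, soft = _ellipse_mask(shape, tuple(centers[i]), major[i], minor[i], theta[i])
        for name, mask in bright.items():
            if mask[i]:
                canvases[name][rs, cs] += RENDER_BOOST * SIGNAL_AMPLITUDE * soft

    noise_sd = 0.0 if math.isinf(spec.snr) else SIGNAL_AMPLITUDE / spec.snr
    channels: dict[str, np.ndarray] = {}
    for name in ("DAPI", spec.class_marker, spec.tf_channel, "EdU"):
        img = canvases[name]
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        channels[name] = np.clip(img * INT_SCALE, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(n, dtype=int),
            "center_row": centers[:, 0] if n else np.empty(0),
            "center_col": centers[:, 1] if n else np.empty(0),
            "radius": major,
            "cell_class": np.where(is_prog, PROGENITOR, NEURON),
            "birthdate": birth,
            "edu_true": edu,
        }
    )
    for g in genes:
        truth[f"tf_{g}"] = tf_true[g]

    meta = {
        "seed": int(seed),
        "channel_names": list(channels),
        "pixel_size_um": 1.0,
        "spec": _spec_to_jsonable(spec),
        "noise_sd": noise_sd,
        "signal_amplitude": SIGNAL_AMPLITUDE,
    }
    return SectionImage(channels=channels, pixel_size_um=1.0, meta=meta), truth


def _spec_to_jsonable(spec: SectionSpec) -> dict:
    d = asdict(spec)
    d["birthdate_distribution"] = {str(k): v for k, v in spec.birthdate_distribution.items()}
    d["image_shape"] = list(spec.image_shape)
    d["nucleus_radius_range"] = list(spec.nucleus_radius_range)
    d["snr"] = "inf" if math.isinf(spec.snr) else spec.snr
    return d


def write_section(
    image: SectionImage, truth: pd.DataFrame, path: Path | str, stem: str
) -> dict[str, Path]:
    """Write a section as multi-page 16-bit TIFF + JSON sidecar + truth CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tif = path / f"{stem}.tif"
    sidecar = path / f"{stem}.json"
    truth_csv = path / f"{stem}_truth.csv"
    stack = np.stack([image.channels[c] for c in image.channel_names])
    tifffile.imwrite(tif, stack, photometric="minisblack")
    with open(sidecar, "w") as fh:
        json.dump(image.meta, fh, indent=1, sort_keys=True)
    truth.to_csv(truth_csv, index=False, float_format="%.6g")
    return {"tiff": tif, "sidecar": sidecar, "truth": truth_csv}


def read_section(tif_path: Path | str) -> SectionImage:
    """Read a TIFF written by :func:`write_section` using its JSON sidecar."""
    tif_path = Path(tif_path)
    sidecar = tif_path.with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    names = meta["channel_names"]
    channels = {name: stack[i] for i, name in enumerate(names)}
    return SectionImage(
        channels=channels, pixel_size_um=meta.get("pixel_size_um", 1.0), meta=meta
    )
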