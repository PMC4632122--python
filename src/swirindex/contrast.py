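"""ROI-based contrast metrics and the exhaustive band-pair contrast space.

Three classical metrics compare a monitoring intensity I1 against a
normalizing intensity I2:

    SRC (simple ratio contrast)   I1 / I2
    WC  (Weber contrast)          (I1 − I2) / I2
    MC  (Michelson contrast)      (I1 − I2) / (I1 + I2)

The contrast space evaluates the chosen metric for every ordered pair of
spectral bands using the ROI-mean intensity of a single region at the two
wavelengths — a B×B matrix (262,144 entries on the 512-band grid).  A
two-ROI variant (same band, two regions) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hsi_core import HyperspectralCube, ROI, ScalarImage, SpectralAxis

__all__ = [
    "ContrastSpace",
    "roi_mean",
    "src",
    "weber",
    "michelson",
    "contrast_space",
    "two_roi_contrast",
    "top_pairs",
    "CONTRAST_METRICS",
]

CONTRAST_METRICS = ("SRC", "WC", "MC")


@dataclass
class ContrastSpace:
    """B×B matrix of a contrast metric over ordered band pairs.

    Entry (i, j) uses band i as the monitoring and band j as the
    normalizing intensity.  Entries whose denominator is numerically zero
    are NaN in ``values`` and flagged in ``undefined``, never silently
    zeroed.
    """

    metric: str
    values: np.ndarray
    undefined: np.ndarray
    axis: SpectralAxis

    def __post_init__(self):
        b = len(self.axis)
        if self.values.shape != (b, b) or self.undefined.shape != (b, b):
            raise ValueError("contrast space must be B×B")
        if self.metric not in CONTRAST_METRICS:
            raise ValueError(f"metric must be one of {CONTRAST_METRICS}")

    @property
    def n_entries(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: lambda_monitor, lambda_norm, value (NaN if undefined)."""
        wl = self.axis.wavelengths_nm
        mon, norm = np.meshgrid(wl, wl, indexing="ij")
        return pd.DataFrame({
            "lambda_monitor_nm": mon.ravel(),
            "lambda_norm_nm": norm.ravel(),
            "value": np.where(self.undefined, np.nan, self.values).ravel(),
        })

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def roi_mean(image_or_band: ScalarImage | np.ndarray, roi: ROI) -> float:
    """Arithmetic mean of the valid ROI pixels of an image or raw band array."""
    if isinstance(image_or_band, ScalarImage):
        values, mask = image_or_band.values, image_or_band.mask
    else:
        values = np.asarray(image_or_band, float)
        mask = np.ones(values.shape, bool)
    roi.check_bounds(*values.shape)
    sel = mask[roi.rows, roi.cols]
    if not sel.any():
        raise ValueError("ROI contains no valid pixels")
    return float(values[roi.rows, roi.cols][sel].mean())


def src(I1: float, I2: float) -> float:
    """Simple ratio contrast I1/I2."""
    if I2 == 0:
        raise ZeroDivisionError("normalizing intensity is zero")
    return I1 / I2


def weber(I1: float, I2: float) -> float:
    """Weber contrast (I1 − I2)/I2 = SRC − 1."""
    if I2 == 0:
        raise ZeroDivisionError("normalizing intensity is zero")
    return (I1 - I2) / I2


def michelson(I1: float, I2: float) -> float:
    """Michelson contrast (I1 − I2)/(I1 + I2), in [−1, 1] for non-negative inputs."""
    if I1 + I2 == 0:
        raise ZeroDivisionError("intensity sum is zero")
    return (I1 - I2) / (I1 + I2)


_METRIC_FUNCS = {"SRC": src, "WC": weber, "MC": michelson}


def contrast_space(
    cube: HyperspectralCube,
    roi: ROI,
    metric: str = "SRC",
    epsilon_rel: float = 1e-12,
) -> ContrastSpace:
    """Metric value for every ordered band pair, from one ROI's per-band means.

    Per-band ROI means are computed once (O(HWB)), then combined for all
    B² pairs.  Denominators with magnitude below ``epsilon_rel`` times the
    largest band mean are flagged undefined.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"metric must be one of {CONTRAST_METRICS}")
    roi.check_bounds(*cube.shape[:2])
    means = cube.intensities[roi.rows, roi.cols, :].mean(axis=0)  # (B,)
    return _space_from_means(means, means, metric, cube.axis, epsilon_rel)


def _space_from_means(mon, norm, metric, axis, epsilon_rel):
    eps = epsilon_rel * max(np.abs(mon).max(), np.abs(norm).max(), 1e-300)
    i1 = mon[:, None]
    i2 = norm[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "SRC":
            denom = np.broadcast_to(i2, (mon.size, norm.size))
            values = i1 / i2
        elif metric == "WC":
            denom = np.broadcast_to(i2, (mon.size, norm.size))
            values = (i1 - i2) / i2
        else:  # MC
            denom = i1 + i2
            values = (i1 - i2) / denom
    undefined = np.abs(denom) < eps
    values = np.where(undefined, np.nan, values)
    return ContrastSpace(metric=metric, values=values, undefined=undefined, axis=axis)


def two_roi_contrast(
    cube: HyperspectralCube, roi1: ROI, roi2: ROI, metric: str = "SRC"
) -> pd.DataFrame:
    """Per-band metric comparing two regions at the same wavelength.

    The variant reading of the ROI contrast formulas: I1 and I2 are the
    means of two different regions (e.g. leaf A vs leaf B) in the same
    band image.  Returns one row per band.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"metric must be one of {CONTRAST_METRICS}")
    for roi in (roi1, roi2):
        roi.check_bounds(*cube.shape[:2])
    m1 = cube.intensities[roi1.rows, roi1.cols, :].mean(axis=0)
    m2 = cube.intensities[roi2.rows, roi2.cols, :].mean(axis=0)
    func = _METRIC_FUNCS[metric]
    vals = []
    for a, b in zip(m1, m2):
        try:
            vals.append(func(float(a), float(b)))
        except ZeroDivisionError:
            vals.append(np.nan)
    return pd.DataFrame({
        "wavelength_nm": cube.axis.wavelengths_nm,
        "metric": metric,
        "value": vals,
    })


def top_pairs(space: ContrastSpace, k: int = 10) -> list[tuple[float, float, float]]:
    """The k largest finite entries as (monitoring λ, normalizing λ, value).

    Descending by value; ties break toward the lower monitoring then
    lower normalizing wavelength.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    finite = np.isfinite(space.values) & ~space.undefined
    n_ok = int(finite.sum())
    if k > n_ok:
        raise ValueError(f"k={k} exceeds the {n_ok} defined entries")
    vals = space.values.copy()
    vals[~finite] = -np.inf
    flat = vals.ravel()
    # stable tie-break: lexsort on (-value, i, j); flat order is already (i, j)
    order = np.lexsort((np.arange(flat.size), -flat))[:k]
    wl = space.axis.wavelengths_nm
    b = len(space.axis)
    return [
        (float(wl[idx // b]), float(wl[idx % b]), float(flat[idx])) for idx in order
    ]
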