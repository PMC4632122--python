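"""Reference computations for plant water status and leaf optics.

Relative water content (RWC) from gravimetric records, spectral ratios
(transmittance/reflectance), replicate averaging, and absorbed fraction
from the T/R energy balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RWCRecord",
    "rwc",
    "transmittance",
    "average_spectra",
    "absorbance_from_TR",
    "log_absorbance",
    "rwc_table",
]


@dataclass(frozen=True)
class RWCRecord:
    """Gravimetric leaf record: sample weight W, turgid weight TW, dry weight DW."""

    W: float
    TW: float
    DW: float

    def __post_init__(self):
        if self.DW <= 0:
            raise ValueError("dry weight must be positive")
        if self.TW <= self.DW:
            raise ValueError("turgid weight must exceed dry weight")


def rwc(record: RWCRecord) -> float:
    """Relative water content in percent: 100·(W − DW)/(TW − DW).

    100% at full turgor, 0% oven dry.  A sample weight slightly outside
    [DW, TW] (surface-moisture artifacts) yields a value outside [0, 100]
    with a warning rather than an error.
    """
    value = 100.0 * (record.W - record.DW) / (record.TW - record.DW)
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"RWC {value:.2f}% outside [0, 100]: sample weight {record.W} "
            f"falls outside [DW={record.DW}, TW={record.TW}]",
            stacklevel=2,
        )
    return value


def rwc_table(csv_path: str | Path) -> pd.DataFrame:
    """Batch RWC from a CSV with columns sample_id, W, TW, DW."""
    df = pd.read_csv(csv_path)
    required = {"sample_id", "W", "TW", "DW"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV missing columns: {sorted(missing)}")
    df = df.copy()
    df["RWC_percent"] = [
        rwc(RWCRecord(W=row.W, TW=row.TW, DW=row.DW)) for row in df.itertuples()
    ]
    return df


def transmittance(transmitted_power: np.ndarray, incident_power: np.ndarray) -> np.ndarray:
    """Elementwise ratio of transmitted to incident radiant power.

    The same contract serves reflectance (reflected over incident).
    """
    t = np.asarray(transmitted_power, float)
    i = np.asarray(incident_power, float)
    if t.shape != i.shape:
        raise ValueError("spectra must have equal lengths")
    if np.any(i <= 0):
        raise ValueError("incident power must be strictly positive")
    if np.any(t < 0):
        raise ValueError("transmitted power must be non-negative")
    return t / i


def average_spectra(spectra) -> np.ndarray:
    """Elementwise arithmetic mean of replicate spectra (noise averaging)."""
    arr = np.asarray(list(spectra), dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one spectrum; all must share a length")
    return arr.mean(axis=0)


def absorbance_from_TR(T: np.ndarray, R: np.ndarray, tolerance: float = 1e-6) -> np.ndarray:
    """Absorbed fraction from the energy balance A = 1 − T − R, clipped to [0, 1].

    T and R must lie in [0, 1] and satisfy T + R ≤ 1 + tolerance.  This
    is the default notion of "absorption" here; see :func:`log_absorbance`
    for the Beer-Lambert log form.
    """
    T = np.asarray(T, float)
    R = np.asarray(R, float)
    if T.shape != R.shape:
        raise ValueError("T and R must have equal lengths")
    for name, s in (("T", T), ("R", R)):
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    if np.any(T + R > 1 + tolerance):
        raise ValueError("T + R exceeds 1 beyond tolerance")
    return np.clip(1.0 - T - R, 0.0, 1.0)


def log_absorbance(T: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical depth −ln(T); the log-form alternative to A = 1−T−R."""
    T = np.asarray(T, float)
    if np.any(T <= 0) or np.any(T > 1):
        raise ValueError("T must lie in (0, 1]")
    return -np.log(T)
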