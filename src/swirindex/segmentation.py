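"""Bimodality-guided histogram thresholding.

Once an index image shows two well-separated histogram modes (fresh vs
stressed leaf pixels), a threshold placed between the modes partitions
the image.  The default threshold is the equal-density point of the two
fitted Gaussian components — the intensity between the centers where the
two curves intersect — which minimizes misassignment for well-separated
modes; the midpoint of the centers and a manual value are alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .bimodality import BimodalFit
from .hsi_core import ScalarImage

__all__ = ["ThresholdDecision", "threshold_between_modes", "apply_threshold"]

THRESHOLD_METHODS = ("component_intersection", "mode_midpoint", "manual")


@dataclass(frozen=True)
class ThresholdDecision:
    """A chosen intensity threshold and how it was derived."""

    threshold: float
    method: str
    fit: BimodalFit | None = None

    def __post_init__(self):
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"method must be one of {THRESHOLD_METHODS}")
        if self.fit is not None and self.method != "manual":
            lo, hi = self.fit.components
            if not (lo.b < self.threshold < hi.b):
                raise ValueError(
                    "fit-derived threshold must lie strictly between the mode centers"
                )


def threshold_between_modes(
    fit: BimodalFit, method: str = "component_intersection"
) -> ThresholdDecision:
    """Place a threshold between the two fitted modes.

    ``component_intersection`` solves a1·exp(−((x−b1)/c1)²) =
    a2·exp(−((x−b2)/c2)²) for x between the centers (falling back to the
    midpoint when no interior intersection exists); ``mode_midpoint`` uses
    (b1+b2)/2.  Refuses degenerate fits: non-converged, or centers closer
    than one pooled sigma.
    """
    if not fit.converged:
        raise ValueError("refusing to threshold a non-converged fit")
    lo, hi = fit.components
    if hi.b == lo.b:
        raise ValueError("mode centers coincide; no between-mode threshold exists")
    pooled_sigma = np.sqrt((lo.sigma**2 + hi.sigma**2) / 2.0)
    if hi.b - lo.b < pooled_sigma:
        raise ValueError(
            f"modes too close to separate: center gap {hi.b - lo.b:.4g} "
            f"is below the pooled sigma {pooled_sigma:.4g}"
        )
    midpoint = 0.5 * (lo.b + hi.b)
    if method == "mode_midpoint":
        return ThresholdDecision(midpoint, "mode_midpoint", fit)
    if method != "component_intersection":
        raise ValueError("method must be component_intersection or mode_midpoint")

    # log-difference of the two component curves; a root between the
    # centers is the equal-density point
    def logdiff(x):
        return (np.log(max(lo.a, 1e-300)) - ((x - lo.b) / lo.c) ** 2) - (
            np.log(max(hi.a, 1e-300)) - ((x - hi.b) / hi.c) ** 2
        )

    a, b = lo.b, hi.b
    fa, fb = logdiff(a), logdiff(b)
    if fa == 0.0:
        return ThresholdDecision(_nudge_interior(a, lo.b, hi.b), "component_intersection", fit)
    if fa * fb >= 0 or lo.a == 0 or hi.a == 0:
        # no interior sign change (e.g. one amplitude ~0): fall back
        return ThresholdDecision(midpoint, "component_intersection", fit)
    x0 = brentq(logdiff, a, b, xtol=1e-12 * max(abs(a), abs(b), 1.0))
    return ThresholdDecision(_nudge_interior(x0, lo.b, hi.b), "component_intersection", fit)


def _nudge_interior(x: float, lo_b: float, hi_b: float) -> float:
    """Keep a root strictly inside (lo_b, hi_b) against float rounding."""
    eps = 1e-12 * max(abs(lo_b), abs(hi_b), 1.0)
    return float(min(max(x, lo_b + eps), hi_b - eps))


def apply_threshold(
    image: ScalarImage,
    mask: np.ndarray | None,
    decision: ThresholdDecision,
    keep: str = "below",
) -> np.ndarray:
    """Boolean mask of valid pixels on the kept side of the threshold.

    Pixels exactly at the threshold count as "below", so the two calls
    with ``keep="below"`` and ``keep="above"`` partition the valid pixels
    exactly.
    """
    if keep not in ("below", "above"):
        raise ValueError('keep must be "below" or "above"')
    valid = image.mask if mask is None else (image.mask & np.asarray(mask, bool))
    below = valid & (image.values <= decision.threshold)
    return below if keep == "below" else (valid & ~below)
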