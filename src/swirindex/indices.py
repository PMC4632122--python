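"""Vegetation index images and the bimodality-driven band-pair search.

Index kinds: single band, broadband mean, band ratio I(λn)/I(λd), and
normalized difference (I1 − I2)/(I1 + I2).  The classical water indices
are provided under their usual names:

    WBI   900 nm / 970 nm
    MSI   1599 nm / 819 nm
    NDWI  (857 nm − 1241 nm) / (857 nm + 1241 nm)

``search_indices`` automates index discovery: every ordered band pair on a
strided grid is rendered as a ratio image, scored with the histogram
bimodality pipeline, filtered for fit validity, and ranked by descending
Bhattacharyya distance.  The manual step this replaces — screening band
ratios frame by frame for visual contrast — becomes an unsupervised
exhaustive ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bimodality import BimodalityConfig, BimodalityResult, bimodality_report
from .hsi_core import (
    HyperspectralCube,
    ScalarImage,
    band_image,
    band_index_for_wavelength,
    broadband_image,
)

__all__ = [
    "IndexDefinition",
    "RankedIndexTable",
    "ratio_image",
    "normalized_difference_image",
    "wbi",
    "msi",
    "ndwi",
    "evaluate_index",
    "search_indices",
    "parse_index_definition",
]

INDEX_KINDS = ("single_band", "broadband", "ratio", "normalized_difference")


@dataclass(frozen=True)
class IndexDefinition:
    """Recipe for an index image: kind plus one or two wavelengths (nm).

    ``wavelengths`` holds one value for ``single_band``, the [lo, hi]
    window for ``broadband``, (numerator, denominator) for ``ratio`` and
    (λ1, λ2) for ``normalized_difference``.  ``tol_nm`` widens the
    wavelength-to-band matching window beyond the default half grid step
    (needed e.g. for MSI, whose 1599 nm reference sits just past the last
    band center of the 800-1600 nm grid).
    """

    kind: str
    wavelengths: tuple[float, ...]
    label: str = ""
    tol_nm: float | None = None

    def __post_init__(self):
        if self.kind not in INDEX_KINDS:
            raise ValueError(f"kind must be one of {INDEX_KINDS}")
        n = len(self.wavelengths)
        if self.kind == "single_band" and n != 1:
            raise ValueError("single_band takes exactly one wavelength")
        if self.kind != "single_band":
            if n != 2:
                raise ValueError(f"{self.kind} takes exactly two wavelengths")
            if self.kind in ("ratio", "normalized_difference") and \
                    self.wavelengths[0] == self.wavelengths[1]:
                raise ValueError(f"{self.kind} wavelengths must be distinct")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        w = self.wavelengths
        return {
            "single_band": lambda: f"band:{w[0]:g}",
            "broadband": lambda: f"broadband:{w[0]:g}-{w[1]:g}",
            "ratio": lambda: f"ratio:{w[0]:g}/{w[1]:g}",
            "normalized_difference": lambda: f"nd:{w[0]:g}/{w[1]:g}",
        }[self.kind]()


def parse_index_definition(text: str) -> IndexDefinition:
    """Parse the compact grammar: ``band:1416``, ``broadband:800-1600``,
    ``ratio:1529/1416``, ``nd:857/1241``, plus the names WBI/MSI/NDWI."""
    named = {
        "wbi": IndexDefinition("ratio", (900.0, 970.0), "WBI"),
        "msi": IndexDefinition("ratio", (1599.0, 819.0), "MSI", tol_nm=2.5),
        "ndwi": IndexDefinition("normalized_difference", (857.0, 1241.0), "NDWI"),
    }
    key = text.strip().lower()
    if key in named:
        return named[key]
    if ":" not in text:
        raise ValueError(f"cannot parse index definition {text!r}")
    kind_key, args = text.split(":", 1)
    kind_key = kind_key.strip().lower()
    try:
        if kind_key == "band":
            return IndexDefinition("single_band", (float(args),))
        if kind_key == "broadband":
            lo, hi = args.split("-")
            return IndexDefinition("broadband", (float(lo), float(hi)))
        if kind_key in ("ratio", "nd"):
            num, den = args.split("/")
            kind = "ratio" if kind_key == "ratio" else "normalized_difference"
            return IndexDefinition(kind, (float(num), float(den)))
    except ValueError as exc:
        raise ValueError(f"cannot parse index definition {text!r}: {exc}") from exc
    raise ValueError(f"unknown index kind in {text!r}")


# ---------------------------------------------------------------------------
# index images

def _resolve_mask(cube: HyperspectralCube, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(cube.shape[:2], bool)
    mask = np.asarray(mask, bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial shape")
    return mask


def ratio_image(
    cube: HyperspectralCube,
    numerator_nm: float,
    denominator_nm: float,
    mask: np.ndarray | None = None,
    epsilon_rel: float = 1e-9,
    tol_nm: float | None = None,
) -> ScalarImage:
    """Per-pixel I(λ_num)/I(λ_den); near-zero-denominator pixels are masked out."""
    mask = _resolve_mask(cube, mask)
    ki = band_index_for_wavelength(cube.axis, numerator_nm, tol_nm)
    kj = band_index_for_wavelength(cube.axis, denominator_nm, tol_nm)
    num = cube.intensities[:, :, ki]
    den = cube.intensities[:, :, kj]
    eps = epsilon_rel * max(den.max(), 1e-300)
    valid = mask & (np.abs(den) > eps)
    if not valid.any():
        raise ValueError("no valid pixels (denominator ~0 everywhere in mask)")
    values = np.zeros_like(num)
    values[valid] = num[valid] / den[valid]
    wl = cube.axis.wavelengths_nm
    return ScalarImage(
        values=values, mask=valid,
        label=f"ratio {numerator_nm:g}/{denominator_nm:g} nm "
              f"(centers {wl[ki]:.2f}/{wl[kj]:.2f}, "
              f"{'normalized' if cube.normalized else 'raw'})",
    )


def normalized_difference_image(
    cube: HyperspectralCube,
    lambda1_nm: float,
    lambda2_nm: float,
    mask: np.ndarray | None = None,
    epsilon_rel: float = 1e-9,
    tol_nm: float | None = None,
) -> ScalarImage:
    """Per-pixel (I1 − I2)/(I1 + I2); zero-sum pixels are masked out."""
    mask = _resolve_mask(cube, mask)
    k1 = band_index_for_wavelength(cube.axis, lambda1_nm, tol_nm)
    k2 = band_index_for_wavelength(cube.axis, lambda2_nm, tol_nm)
    i1 = cube.intensities[:, :, k1]
    i2 = cube.intensities[:, :, k2]
    total = i1 + i2
    eps = epsilon_rel * max(total.max(), 1e-300)
    valid = mask & (np.abs(total) > eps)
    if not valid.any():
        raise ValueError("no valid pixels (band sum ~0 everywhere in mask)")
    values = np.zeros_like(i1)
    values[valid] = (i1[valid] - i2[valid]) / total[valid]
    wl = cube.axis.wavelengths_nm
    return ScalarImage(
        values=values, mask=valid,
        label=f"nd ({lambda1_nm:g}-{lambda2_nm:g})/({lambda1_nm:g}+{lambda2_nm:g}) nm "
              f"(centers {wl[k1]:.2f}/{wl[k2]:.2f})",
    )


def wbi(cube: HyperspectralCube, mask: np.ndarray | None = None) -> ScalarImage:
    """Water Band Index: 900 nm / 970 nm."""
    img = ratio_image(cube, 900.0, 970.0, mask)
    img.label = "WBI " + img.label
    return img


def msi(cube: HyperspectralCube, mask: np.ndarray | None = None) -> ScalarImage:
    """Moisture Stress Index: 1599 nm / 819 nm.

    On the 800-1600 nm instrument grid the last band center is 1597.16 nm,
    so the 1599 nm reference resolves (with a widened 2.5 nm tolerance) to
    that edge band; the label records the actual centers.
    """
    img = ratio_image(cube, 1599.0, 819.0, mask, tol_nm=2.5)
    img.label = "MSI " + img.label
    return img


def ndwi(cube: HyperspectralCube, mask: np.ndarray | None = None) -> ScalarImage:
    """Normalized Difference Water Index: (857 − 1241)/(857 + 1241) nm."""
    img = normalized_difference_image(cube, 857.0, 1241.0, mask)
    img.label = "NDWI " + img.label
    return img


def build_index_image(
    cube: HyperspectralCube,
    definition: IndexDefinition,
    mask: np.ndarray | None = None,
) -> ScalarImage:
    """Render the index image for any definition kind."""
    w = definition.wavelengths
    if definition.kind == "single_band":
        img = band_image(cube, w[0])
    elif definition.kind == "broadband":
        img = broadband_image(cube, w[0], w[1])
    elif definition.kind == "ratio":
        return ratio_image(cube, w[0], w[1], mask, tol_nm=definition.tol_nm)
    else:
        return normalized_difference_image(cube, w[0], w[1], mask,
                                           tol_nm=definition.tol_nm)
    if mask is not None:
        valid = img.mask & _resolve_mask(cube, mask)
        img = ScalarImage(values=img.values, mask=valid, label=img.label)
    return img


def evaluate_index(
    cube: HyperspectralCube,
    definition: IndexDefinition,
    mask: np.ndarray | None = None,
    config: BimodalityConfig | None = None,
) -> tuple[ScalarImage, BimodalityResult]:
    """Render the index image and score it with the bimodality pipeline."""
    img = build_index_image(cube, definition, mask)
    report = bimodality_report(img, config=config)
    return img, report


# ---------------------------------------------------------------------------
# search

@dataclass
class RankedIndexTable:
    """D_B-ranked candidates from an index search, plus the excluded ones.

    ``rows``: (definition, result) sorted by descending D_B, restricted to
    converged fits that pass the validity filter.  ``excluded``: every
    other evaluated candidate with its exclusion reason, so no candidate
    is silently dropped.  ``metadata`` records the grid and configuration.
    """

    rows: list[tuple[IndexDefinition, BimodalityResult]]
    excluded: list[tuple[IndexDefinition, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        dbs = [r.d_b for _, r in self.rows]
        if any(b > a + 1e-12 for a, b in zip(dbs, dbs[1:])):
            raise ValueError("rows must be sorted by descending D_B")

    @property
    def best(self) -> tuple[IndexDefinition, BimodalityResult]:
        if not self.rows:
            raise ValueError("no accepted candidates")
        return self.rows[0]

    def to_frame(self) -> pd.DataFrame:
        """Table with the standard report columns: label, wavelengths, D_B, C_B, R², class."""
        records = []
        for d, r in self.rows:
            records.append({
                "index": d.label,
                "wavelengths": "/".join(f"{w:g} nm" for w in d.wavelengths),
                "D_B": r.d_b,
                "C_B": r.c_b,
                "R2": r.fit.r_squared,
                "class": r.contrast_class,
            })
        return pd.DataFrame.from_records(
            records,
            columns=["index", "wavelengths", "D_B", "C_B", "R2", "class"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def search_indices(
    cube: HyperspectralCube,
    mask: np.ndarray | None = None,
    numerator_range: tuple[float, float] | None = None,
    denominator_range: tuple[float, float] | None = None,
    stride: int = 4,
    config: BimodalityConfig | None = None,
) -> RankedIndexTable:
    """Rank every strided ordered band pair (numerator, denominator) by D_B.

    Ratios are not symmetric, so both orientations of each pair are
    evaluated.  Candidates whose fit fails to converge, scores
    R² < ``config.r2_min`` or collapses to one effective mode are moved
    to ``excluded`` with the reason.  Ties in D_B break toward the lower
    numerator then lower denominator wavelength.
    """
    if stride < 1:
        raise ValueError("stride must be at least 1")
    config = config or BimodalityConfig()
    wl = cube.axis.wavelengths_nm
    full = (float(wl[0]), float(wl[-1]))
    numerator_range = numerator_range or full
    denominator_range = denominator_range or full

    def grid(lo, hi):
        sel = np.nonzero((wl >= lo) & (wl <= hi))[0]
        if sel.size == 0:
            raise ValueError(f"no bands in range [{lo}, {hi}] nm")
        return sel[::stride]

    num_bands = grid(*numerator_range)
    den_bands = grid(*denominator_range)

    accepted, excluded = [], []
    for ki in num_bands:
        for kj in den_bands:
            if ki == kj:
                continue
            definition = IndexDefinition("ratio", (float(wl[ki]), float(wl[kj])))
            try:
                _, result = evaluate_index(cube, definition, mask, config)
            except (ValueError, RuntimeError) as exc:
                excluded.append((definition, f"evaluation failed: {exc}"))
                continue
            if result.usable:
                accepted.append((definition, result))
            else:
                excluded.append((definition, result.note))
    if not accepted and not excluded:
        raise ValueError("empty candidate set")

    accepted.sort(key=lambda item: (-item[1].d_b,
                                    item[0].wavelengths[0],
                                    item[0].wavelengths[1]))
    return RankedIndexTable(
        rows=accepted,
        excluded=excluded,
        metadata={
            "numerator_range_nm": list(numerator_range),
            "denominator_range_nm": list(denominator_range),
            "stride": stride,
            "n_candidates": len(accepted) + len(excluded),
            "r2_min": config.r2_min,
            "min_component_fraction": config.min_component_fraction,
            "bins": config.bins,
        },
    )
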