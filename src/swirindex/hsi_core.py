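"""Hyperspectral datacube model, wavelength-indexed band access, and file I/O.

Conventions
-----------
* Cubes are ``(rows, cols, bands)`` arrays of non-negative real intensities
  (detector counts, arbitrary units); pixel ``(0, 0)`` is top-left,
  row-major, 0-based.
* The spectral axis holds strictly increasing band-center wavelengths in
  nanometres.  The instrument grid this package targets is 800-1600 nm in
  1.56 nm steps, 512 bands (the last band center lands at 1597.16 nm).
* Two on-disk formats are supported: ENVI (text ``.hdr`` + flat binary;
  BSQ/BIL/BIP read, BSQ write) and a self-describing NumPy ``.npz``
  container holding the array, axis and optional light-reference spectrum.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpectralAxis",
    "HyperspectralCube",
    "ScalarImage",
    "ROI",
    "load_cube",
    "save_cube",
    "band_index_for_wavelength",
    "normalize_to_light_source",
    "band_image",
    "broadband_image",
]

#: Default instrument grid: 800 nm start, 1.56 nm step, 512 bands.
DEFAULT_START_NM = 800.0
DEFAULT_STEP_NM = 1.56
DEFAULT_N_BANDS = 512


@dataclass(frozen=True)
class SpectralAxis:
    """Ordered band-center wavelengths in nanometres.

    Wavelengths must be finite and strictly increasing.  The default
    construction reproduces the 800-1600 nm, 1.56 nm, 512-band grid.
    """

    wavelengths_nm: np.ndarray

    def __init__(self, wavelengths_nm: Sequence[float] | None = None):
        if wavelengths_nm is None:
            wl = DEFAULT_START_NM + DEFAULT_STEP_NM * np.arange(DEFAULT_N_BANDS)
        else:
            wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("spectral axis must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(wl)):
            raise ValueError("spectral axis wavelengths must be finite")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("spectral axis wavelengths must be strictly increasing")
        wl.flags.writeable = False
        object.__setattr__(self, "wavelengths_nm", wl)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def __hash__(self):
        return hash(self.wavelengths_nm.tobytes())

    @property
    def step_nm(self) -> float:
        """Median grid spacing (exact for uniform grids)."""
        if len(self) < 2:
            return 0.0
        return float(np.median(np.diff(self.wavelengths_nm)))


@dataclass
class HyperspectralCube:
    """A (rows, cols, bands) stack of band images with a wavelength axis.

    Parameters
    ----------
    intensities
        Non-negative, finite intensity array, shape ``(H, W, B)``.
    axis
        Spectral axis of length ``B``.
    light_reference
        Optional strictly positive length-``B`` source spectrum used for
        normalization.
    normalized
        True once intensities have been divided by a light reference.
    """

    intensities: np.ndarray
    axis: SpectralAxis
    light_reference: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D (rows, cols, bands) array")
        if arr.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {arr.shape[2]} disagrees with axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        self.intensities = arr
        if self.light_reference is not None:
            ref = np.asarray(self.light_reference, dtype=float)
            _check_reference(ref, arr.shape[2])
            self.light_reference = ref

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[2]


@dataclass
class ScalarImage:
    """A single-channel image plus validity mask and provenance label."""

    values: np.ndarray
    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if vals.ndim != 2:
            raise ValueError("values must be 2-D")
        if mask.shape != vals.shape:
            raise ValueError("mask shape must match values shape")
        if not mask.any():
            raise ValueError("mask must contain at least one valid pixel")
        if not np.all(np.isfinite(vals[mask])):
            raise ValueError("values must be finite wherever mask is true")
        self.values = vals
        self.mask = mask

    def valid_values(self) -> np.ndarray:
        """Flat array of the masked-in pixel values."""
        return self.values[self.mask]


class ROI:
    """A non-empty set of in-bounds pixels.

    Construct from an axis-aligned rectangle (``ROI.rect``) or explicit
    ``(row, col)`` coordinates (``ROI.from_pixels``); 0-based, top-left
    origin.  Rectangle bounds are half-open: ``rows [r0, r1), cols [c0, c1)``.
    """

    def __init__(self, rows: np.ndarray, cols: np.ndarray):
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        if rows.size == 0 or rows.shape != cols.shape:
            raise ValueError("ROI must contain at least one pixel")
        if np.any(rows < 0) or np.any(cols < 0):
            raise ValueError("ROI coordinates must be non-negative")
        self.rows = rows
        self.cols = cols

    @classmethod
    def rect(cls, r0: int, c0: int, r1: int, c1: int) -> "ROI":
        if r1 <= r0 or c1 <= c0:
            raise ValueError("rectangle must have positive extent")
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        return cls(rr.ravel(), cc.ravel())

    @classmethod
    def from_pixels(cls, pixels: Iterable[tuple[int, int]]) -> "ROI":
        pts = np.atleast_2d(np.asarray(list(pixels), dtype=int))
        if pts.size == 0:
            raise ValueError("ROI must contain at least one pixel")
        return cls(pts[:, 0], pts[:, 1])

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "ROI":
        rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
        if rows.size == 0:
            raise ValueError("ROI mask is empty")
        return cls(rows, cols)

    def __len__(self) -> int:
        return int(self.rows.size)

    def check_bounds(self, height: int, width: int) -> None:
        if np.any(self.rows >= height) or np.any(self.cols >= width):
            raise ValueError("ROI exceeds image bounds")


# ---------------------------------------------------------------------------
# band access

def band_index_for_wavelength(
    axis: SpectralAxis, target_nm: float, tol_nm: float | None = None
) -> int:
    """Index of the band center nearest ``target_nm``; ties go to the lower index.

    The target must lie within ``tol_nm`` of the axis span (default: half
    a grid step), else a ``ValueError`` is raised.  A wider tolerance lets
    literature index wavelengths that sit just past the last band center
    (e.g. a 1599 nm reference on a grid ending at 1597.16 nm) map to the
    edge band.
    """
    wl = axis.wavelengths_nm
    if tol_nm is None:
        tol_nm = axis.step_nm / 2.0 if len(axis) > 1 else 0.0
    if target_nm < wl[0] - tol_nm or target_nm > wl[-1] + tol_nm:
        raise ValueError(
            f"wavelength {target_nm} nm outside axis span "
            f"[{wl[0]:.2f}, {wl[-1]:.2f}] nm (±{tol_nm:.2f} nm)"
        )
    dist = np.abs(wl - target_nm)
    # argmin returns the first (lowest) index on exact ties
    return int(np.argmin(dist))


def normalize_to_light_source(
    cube: HyperspectralCube, reference: np.ndarray | None = None
) -> HyperspectralCube:
    """Divide every band image by the light-source spectrum.

    Uses ``cube.light_reference`` when ``reference`` is omitted.  Returns a
    new cube with the ``normalized`` flag set; input is untouched.
    """
    if reference is None:
        reference = cube.light_reference
    if reference is None:
        raise ValueError("no light reference supplied or attached to the cube")
    ref = np.asarray(reference, dtype=float)
    _check_reference(ref, cube.n_bands)
    return HyperspectralCube(
        intensities=cube.intensities / ref[None, None, :],
        axis=cube.axis,
        light_reference=ref,
        normalized=True,
    )


def band_image(cube: HyperspectralCube, wavelength_nm: float) -> ScalarImage:
    """The single-band image at the grid band nearest ``wavelength_nm``.

    The label records both the requested and the actual band-center
    wavelength, since named index wavelengths rarely fall exactly on the
    1.56 nm grid.
    """
    k = band_index_for_wavelength(cube.axis, wavelength_nm)
    actual = cube.axis.wavelengths_nm[k]
    return ScalarImage(
        values=cube.intensities[:, :, k].copy(),
        mask=np.ones(cube.shape[:2], dtype=bool),
        label=f"band {wavelength_nm:g} nm (center {actual:.2f} nm, index {k})",
    )


def broadband_image(cube: HyperspectralCube, lo_nm: float, hi_nm: float) -> ScalarImage:
    """Per-pixel mean over all bands with centers in the closed [lo, hi] window."""
    if hi_nm < lo_nm:
        raise ValueError("require lo_nm <= hi_nm")
    wl = cube.axis.wavelengths_nm
    sel = (wl >= lo_nm) & (wl <= hi_nm)
    if not sel.any():
        raise ValueError(f"no bands with centers in [{lo_nm}, {hi_nm}] nm")
    return ScalarImage(
        values=cube.intensities[:, :, sel].mean(axis=2),
        mask=np.ones(cube.shape[:2], dtype=bool),
        label=f"broadband {lo_nm:g}-{hi_nm:g} nm ({int(sel.sum())} bands)",
    )


# ---------------------------------------------------------------------------
# file I/O

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def save_cube(cube: HyperspectralCube, path: str | Path, format: str = "envi") -> Path:
    """Write a cube to disk; ``format`` is ``"envi"`` (BSQ) or ``"array_container"``.

    ENVI output is a float32 little-endian BSQ binary with a text ``.hdr``
    beside it; the array container is a NumPy ``.npz`` archive holding the
    full-precision array, axis and optional light reference.  Both
    round-trip with :func:`load_cube` (ENVI at float32 precision).
    """
    path = Path(path)
    if format == "envi":
        return _save_envi(cube, path)
    if format == "array_container":
        return _save_container(cube, path)
    raise ValueError(f"unknown format {format!r}")


def load_cube(path: str | Path, format: str | None = None) -> HyperspectralCube:
    """Read a cube written by :func:`save_cube` (or any plain ENVI BSQ/BIL/BIP file).

    When ``format`` is omitted it is inferred from the file suffix
    (``.npz`` → array container, anything else → ENVI).
    """
    path = Path(path)
    if format is None:
        format = "array_container" if path.suffix == ".npz" else "envi"
    if format == "envi":
        return _load_envi(path)
    if format == "array_container":
        return _load_container(path)
    raise ValueError(f"unknown format {format!r}")


def _save_container(cube: HyperspectralCube, path: Path) -> Path:
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    payload = {
        "intensities": cube.intensities,
        "wavelengths_nm": cube.axis.wavelengths_nm,
        "normalized": np.array(cube.normalized),
    }
    if cube.light_reference is not None:
        payload["light_reference"] = cube.light_reference
    np.savez_compressed(path, **payload)
    return path


def _load_container(path: Path) -> HyperspectralCube:
    with np.load(path) as z:
        ref = z["light_reference"] if "light_reference" in z.files else None
        return HyperspectralCube(
            intensities=z["intensities"],
            axis=SpectralAxis(z["wavelengths_nm"]),
            light_reference=ref,
            normalized=bool(z["normalized"]),
        )


def _save_envi(cube: HyperspectralCube, path: Path) -> Path:
    if path.suffix == ".hdr":
        raise ValueError("pass the binary path; the .hdr is written alongside")
    h, w, b = cube.shape
    data = np.ascontiguousarray(
        cube.intensities.transpose(2, 0, 1), dtype="<f4"
    )  # BSQ: band, line, sample
    data.tofile(path)
    wl = ", ".join(f"{x:.6f}" for x in cube.axis.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {swirindex cube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_DTYPE_CODES[np.dtype('float32')]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
    ]
    if cube.light_reference is not None:
        ref = ", ".join(f"{x:.6f}" for x in cube.light_reference)
        lines.append("; light reference (swirindex extension)")
        lines.append("light reference = { " + ref + " }")
    lines.append(f"normalized = {int(cube.normalized)}")
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(lines) + "\n")
    return path


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs, including brace-delimited lists."""
    fields: dict[str, str] = {}
    # strip comment lines
    text = "\n".join(
        ln for ln in text.splitlines() if not ln.strip().startswith(";")
    )
    for m in re.finditer(
        r"^\s*([a-zA-Z][a-zA-Z0-9 _]*?)\s*=\s*(\{[^}]*\}|[^\n]*)",
        text,
        flags=re.MULTILINE | re.DOTALL,
    ):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def _load_envi(path: Path) -> HyperspectralCube:
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    w = int(fields["samples"])
    h = int(fields["lines"])
    b = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    else:
        dtype = dtype.newbyteorder("<")
    interleave = fields["interleave"].lower()
    offset = int(fields.get("header offset", "0"))

    raw = np.fromfile(path, dtype=dtype, offset=offset)
    if raw.size != h * w * b:
        raise ValueError(
            f"data size {raw.size} disagrees with header "
            f"lines×samples×bands = {h}×{w}×{b} = {h * w * b}"
        )
    if interleave == "bsq":
        arr = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(h, w, b)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    if "wavelength" in fields:
        wl = np.array([float(x) for x in fields["wavelength"].split(",")])
        if wl.size != b:
            raise ValueError(
                f"header lists {wl.size} wavelengths but declares {b} bands"
            )
        axis = SpectralAxis(wl)
    else:
        warnings.warn("ENVI header has no wavelength list; using band indices")
        axis = SpectralAxis(np.arange(b, dtype=float))

    ref = None
    if "light reference" in fields:
        ref = np.array([float(x) for x in fields["light reference"].split(",")])
    normalized = bool(int(fields.get("normalized", "0")))
    return HyperspectralCube(
        intensities=arr.astype(float),
        axis=axis,
        light_reference=ref,
        normalized=normalized,
    )


def _check_reference(ref: np.ndarray, n_bands: int) -> None:
    if ref.ndim != 1 or ref.size != n_bands:
        raise ValueError(
            f"light reference length {ref.size} must equal band count {n_bands}"
        )
    if not np.all(np.isfinite(ref)) or np.any(ref <= 0):
        raise ValueError("light reference must be strictly positive and finite")
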