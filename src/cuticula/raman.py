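"""Raman hyperspectral chemometrics for leaf-cuticle cross-sections.

A confocal Raman map of a cuticle cross-section is a cube: a regular 2-D
spatial grid of spectra sharing one wavenumber axis.  The processing chain
mirrors standard practice for such data:

1. crop the spectra to the informative fingerprint range (120-1810 cm^-1),
2. remove cosmic-ray spikes (isolated 1-2 channel outliers),
3. subtract a smooth per-pixel baseline (asymmetric penalised least
   squares), then
4. image the cuticle by integrating the 1452 cm^-1 CH-deformation band,
   unmix the cube into chemically distinct component spectra with
   non-negative abundance maps, measure layer thicknesses from those maps,
   and score band assignments against a reference table of cuticle
   compound classes (cutin, triterpenoids, flavonoids, phenolic acids,
   crystalline waxes).

The preprocessing order crop -> despike -> baseline is enforced; each cube
records the stages already applied to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from scipy.linalg import solveh_banded
from scipy.ndimage import median_filter
from scipy.signal import find_peaks
from sklearn.decomposition import NMF

__all__ = [
    "RamanCube",
    "ComponentSet",
    "BandAssignment",
    "LayerMeasurement",
    "BAND_ASSIGNMENTS",
    "PreprocessingOrderError",
    "crop_spectra",
    "remove_cosmic_rays",
    "baseline_correct",
    "band_integral_image",
    "average_spectrum",
    "unmix_components",
    "measure_layer_thickness",
    "assign_bands",
    "write_cube",
    "read_cube",
]


class PreprocessingOrderError(RuntimeError):
    """Raised when preprocessing stages are applied out of order."""


@dataclass
class BandAssignment:
    """Reference peak positions for one compound class."""

    label: str
    peaks: tuple[float, ...]  # cm^-1
    window: float = 8.0  # half-width for matching, cm^-1


#: Band-assignment table for alpine ericaceous cuticles (positions in cm^-1).
BAND_ASSIGNMENTS: tuple[BandAssignment, ...] = (
    BandAssignment("flavonoids", (1570.0, 1250.0)),
    BandAssignment("aromatic_ring", (1607.0,)),
    BandAssignment("anthocyanins", (631.0, 1630.0)),
    BandAssignment("triterpenoids", (463.0, 532.0, 564.0, 683.0, 729.0, 746.0)),
    BandAssignment("ursolic_oleanolic_acid", (746.0,)),
    BandAssignment("cutin", (1443.0, 1306.0)),
    BandAssignment("cinnamic_acid", (1630.0, 1170.0)),
    BandAssignment("crystalline_alkanes", (1064.0, 1133.0, 1297.0)),
)


@dataclass
class RamanCube:
    """Wavenumber axis plus per-pixel spectra on a regular 2-D grid.

    ``intensities`` has shape (n_rows, n_cols, n_wavenumbers); ``stages``
    records which preprocessing steps have been applied, in order.
    """

    wavenumbers: np.ndarray  # cm^-1, strictly increasing
    intensities: np.ndarray  # (ny, nx, n_wn)
    pixel_size: float  # um
    metadata: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumber axis must be 1-D")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (rows, cols, wavenumbers)")
        if self.intensities.shape[-1] != len(self.wavenumbers):
            raise ValueError("spectral dimension mismatch")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def flat(self) -> np.ndarray:
        """Pixel-by-channel matrix view, shape (ny*nx, n_wn)."""
        ny, nx, nw = self.intensities.shape
        return self.intensities.reshape(ny * nx, nw)


def _require_stages(cube: RamanCube, expected: tuple[str, ...], op: str) -> None:
    if cube.stages != expected:
        raise PreprocessingOrderError(
            f"{op} expects stages {expected}, cube has {cube.stages}; "
            "order is crop -> despike -> baseline"
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def crop_spectra(cube: RamanCube, low: float = 120.0, high: float = 1810.0) -> RamanCube:
    """Restrict the wavenumber axis to the closed range [low, high].

    Idempotent; pixels are otherwise untouched.
    """
    if cube.stages not in ((), ("crop",)):
        raise PreprocessingOrderError("crop must come before despike/baseline")
    mask = (cube.wavenumbers >= low) & (cube.wavenumbers <= high)
    if not mask.any():
        raise ValueError(f"crop range [{low}, {high}] does not overlap the axis")
    return replace(
        cube,
        wavenumbers=cube.wavenumbers[mask],
        intensities=cube.intensities[..., mask],
        stages=("crop",),
    )


def remove_cosmic_rays(
    cube: RamanCube,
    mad_factor: float = 8.0,
    max_width: int = 2,
    median_window: int = 5,
    min_relative: float = 0.04,
) -> RamanCube:
    """Replace isolated spike channels by linear interpolation.

    Channels deviating more than ``mad_factor`` robust standard deviations
    (1.4826 x MAD of the running-median residual) from a running median, in
    contiguous groups no wider than ``max_width`` channels, are treated as
    cosmic rays.  Broader excursions (real bands) are left bit-identical.
    The threshold is floored at ``min_relative`` times each spectrum's
    dynamic range so that, on near-noiseless spectra, residual band
    curvature never masquerades as a spike (genuine cosmic rays exceed the
    floor by an order of magnitude).
    """
    _require_stages(cube, ("crop",), "remove_cosmic_rays")
    if len(cube.wavenumbers) < 16:
        raise ValueError("need at least 16 channels")
    spectra = cube.flat().copy()
    med = median_filter(spectra, size=(1, median_window), mode="nearest")
    resid = spectra - med
    mad = np.median(np.abs(resid), axis=1, keepdims=True) * 1.4826
    floor = min_relative * np.ptp(spectra, axis=1, keepdims=True)
    threshold = np.maximum(mad_factor * mad, floor)
    flagged = resid > threshold  # cosmic rays are positive spikes

    nw = spectra.shape[1]
    for p in np.nonzero(flagged.any(axis=1))[0]:
        row = flagged[p]
        i = 0
        while i < nw:
            if row[i]:
                j = i
                while j < nw and row[j]:
                    j += 1
                if j - i <= max_width:
                    lo = i - 1
                    hi = j
                    left = spectra[p, lo] if lo >= 0 else spectra[p, hi] if hi < nw else 0.0
                    right = spectra[p, hi] if hi < nw else left
                    for k in range(i, j):
                        frac = (k - lo) / (hi - lo) if hi > lo else 0.5
                        spectra[p, k] = left + frac * (right - left)
                i = j
            else:
                i += 1
    ny, nx, _ = cube.shape
    return replace(
        cube, intensities=spectra.reshape(ny, nx, nw), stages=("crop", "despike")
    )


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int = 10) -> np.ndarray:
    """Asymmetric penalised least-squares baseline for one spectrum."""
    n = len(y)
    # Pentadiagonal lam * D2'D2 (D2 = second differences), upper banded form.
    main = np.full(n, 6.0)
    main[0] = main[-1] = 1.0
    main[1] = main[-2] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[0] = off1[-1] = -2.0
    off2 = np.full(n - 2, 1.0)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = np.zeros((3, n))
        ab[0, 2:] = lam * off2
        ab[1, 1:] = lam * off1
        ab[2, :] = lam * main + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(
    cube: RamanCube, smoothness: float = 1e5, asymmetry: float = 0.01
) -> RamanCube:
    """Subtract a smooth per-pixel baseline (asymmetric least squares).

    ``smoothness`` is the roughness penalty on the baseline's second
    differences; ``asymmetry`` is the weight given to points above the
    baseline (small values let peaks float above it).
    """
    _require_stages(cube, ("crop", "despike"), "baseline_correct")
    spectra = cube.flat()
    corrected = np.empty_like(spectra)
    for i in range(spectra.shape[0]):
        corrected[i] = spectra[i] - _als_baseline(spectra[i], smoothness, asymmetry)
    ny, nx, nw = cube.shape
    return replace(
        cube,
        intensities=corrected.reshape(ny, nx, nw),
        stages=("crop", "despike", "baseline"),
    )


# ---------------------------------------------------------------------------
# Imaging and spectra
# ---------------------------------------------------------------------------

def band_integral_image(
    cube: RamanCube, center: float = 1452.0, half_width: float = 30.0
) -> np.ndarray:
    """Trapezoidal integral of intensity over [center +- half_width] per pixel."""
    lo, hi = center - half_width, center + half_width
    wn = cube.wavenumbers
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(f"integration window [{lo}, {hi}] outside axis")
    mask = (wn >= lo) & (wn <= hi)
    return np.trapezoid(cube.intensities[..., mask], wn[mask], axis=-1)


def average_spectrum(cube: RamanCube, mask: np.ndarray) -> np.ndarray:
    """Channel-wise mean spectrum over the pixels selected by a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape must match the spatial grid")
    if not mask.any():
        raise ValueError("empty mask")
    return cube.intensities[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# Component unmixing
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """Endmember spectra with abundance maps and noise/relevance flags.

    All components of the selected model order are kept; ``is_true`` marks
    those accepted as chemical components (spectrally autocorrelated) versus
    noise.  ``selected`` lists the indices of the requested number of
    relevant components, ordered by total abundance.
    """

    endmember_spectra: np.ndarray  # (k, n_wn)
    abundance_maps: np.ndarray  # (k, ny, nx)
    is_true: np.ndarray  # (k,) bool
    selected: tuple[int, ...]
    reconstruction_errors: dict[int, float]

    @property
    def selected_spectra(self) -> np.ndarray:
        return self.endmember_spectra[list(self.selected)]

    @property
    def selected_maps(self) -> np.ndarray:
        return self.abundance_maps[list(self.selected)]

    def classify_pixels(self) -> np.ndarray:
        """Hard assignment of each pixel to the selected component with the
        largest abundance."""
        return np.argmax(self.selected_maps, axis=0)


def _lag1_autocorrelation(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    return float(np.dot(x[:-1], x[1:]) / denom)


def unmix_components(
    cube: RamanCube,
    k_max: int = 6,
    k_select: int = 3,
    noise_autocorr_threshold: float = 0.5,
    elbow_tol: float = 0.01,
    random_state: int = 0,
) -> ComponentSet:
    """Non-negative spectral unmixing with automatic model-order selection.

    The pixel-by-channel matrix is factorised by NMF for k = 1..k_max.  The
    model order is the smallest k whose further relative reduction in
    reconstruction error falls below ``elbow_tol`` (error elbow).  Components
    whose spectra have lag-1 autocorrelation below
    ``noise_autocorr_threshold`` are flagged as noise; the ``k_select``
    remaining components with the largest total abundance are selected.
    """
    _require_stages(cube, ("crop", "despike", "baseline"), "unmix_components")
    x = np.clip(cube.flat(), 0.0, None)
    if not x.any():
        raise ValueError("cube is identically zero")

    models: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    errors: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for k in range(1, k_max + 1):
            nmf = NMF(
                n_components=k,
                init="nndsvda",
                max_iter=1000,
                tol=1e-5,
                random_state=random_state,
            )
            w = nmf.fit_transform(x)  # (pixels, k) abundances
            h = nmf.components_  # (k, n_wn) spectra
            models[k] = (w, h, nmf.reconstruction_err_)
            errors[k] = float(nmf.reconstruction_err_)

    base = max(errors[1], 1e-30)
    k_star = k_max
    for k in range(1, k_max):
        if (errors[k] - errors[k + 1]) / base < elbow_tol:
            k_star = k
            break

    w, h, _ = models[k_star]
    # Normalise spectra to unit maximum, fold scale into abundances.
    scale = h.max(axis=1)
    scale[scale == 0] = 1.0
    h_n = h / scale[:, None]
    w_n = w * scale[None, :]

    is_true = np.array([
        _lag1_autocorrelation(h_n[i]) >= noise_autocorr_threshold
        for i in range(k_star)
    ])
    true_idx = np.nonzero(is_true)[0]
    if len(true_idx) < k_select:
        raise ValueError(
            f"only {len(true_idx)} non-noise components discoverable, "
            f"{k_select} requested"
        )
    totals = w_n[:, true_idx].sum(axis=0)
    order = true_idx[np.argsort(totals)[::-1]][:k_select]

    ny, nx, _ = cube.shape
    return ComponentSet(
        endmember_spectra=h_n,
        abundance_maps=w_n.T.reshape(k_star, ny, nx),
        is_true=is_true,
        selected=tuple(int(i) for i in order),
        reconstruction_errors=errors,
    )


# ---------------------------------------------------------------------------
# Layer thickness and band assignment
# ---------------------------------------------------------------------------

@dataclass
class LayerMeasurement:
    label: str
    thickness_um: np.ndarray  # per transect
    mean: float
    sd: float


def measure_layer_thickness(
    abundance_map: np.ndarray,
    pixel_size: float,
    threshold_fraction: float = 0.5,
    transect_axis: int = 0,
    label: str = "",
) -> LayerMeasurement:
    """Layer thickness from an abundance map, per transect.

    Each transect is a line of pixels along ``transect_axis`` (the direction
    perpendicular to the cuticle surface).  Per transect, thickness is the
    longest contiguous run of pixels with abundance at or above
    ``threshold_fraction`` times the map maximum, times ``pixel_size``.
    """
    amap = np.asarray(abundance_map, dtype=float)
    if np.any(amap < 0):
        raise ValueError("abundance map must be non-negative")
    peak = amap.max()
    if peak <= 0:
        raise ValueError("no pixel above threshold (empty abundance map)")
    mask = amap >= threshold_fraction * peak
    if transect_axis == 1:
        mask = mask.T
    runs = []
    for j in range(mask.shape[1]):
        col = mask[:, j]
        best = cur = 0
        for v in col:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        if best > 0:
            runs.append(best * pixel_size)
    if not runs:
        raise ValueError("no pixel above threshold on any transect")
    th = np.asarray(runs, dtype=float)
    return LayerMeasurement(
        label=label,
        thickness_um=th,
        mean=float(th.mean()),
        sd=float(th.std(ddof=1)) if len(th) > 1 else 0.0,
    )


def assign_bands(
    wavenumbers: np.ndarray,
    spectrum: np.ndarray,
    table: tuple[BandAssignment, ...] = BAND_ASSIGNMENTS,
    min_prominence_fraction: float = 0.02,
) -> dict[str, dict]:
    """Score compound classes by how many of their reference peaks appear.

    Local maxima of the (baseline-corrected) spectrum are detected with a
    prominence floor of ``min_prominence_fraction`` times the spectrum
    maximum; a reference peak is matched when a detected maximum lies within
    the class's matching window.  Returns, per class, the matched fraction
    and the matched peak positions.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if y.max() <= 0:
        detected = np.array([])
    else:
        idx, _ = find_peaks(y, prominence=min_prominence_fraction * y.max())
        detected = wn[idx]
    out: dict[str, dict] = {}
    for entry in table:
        matched = [
            p for p in entry.peaks
            if detected.size and np.min(np.abs(detected - p)) <= entry.window
        ]
        out[entry.label] = {
            "fraction_matched": len(matched) / len(entry.peaks),
            "matched_peaks": matched,
        }
    return out


# ---------------------------------------------------------------------------
# IO: portable array container + JSON sidecar
# ---------------------------------------------------------------------------

def write_cube(cube: RamanCube, path) -> None:
    """Write a cube as .npz with a JSON sidecar for axes and metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, wavenumbers=cube.wavenumbers, intensities=cube.intensities)
    meta = {}
    for k, v in cube.metadata.items():
        try:
            json.dumps(v)
        except TypeError:
            continue  # ground-truth arrays live only in memory
        meta[k] = v
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": cube.pixel_size,
                "stages": list(cube.stages),
                "metadata": meta,
            },
            indent=2,
        )
    )


def read_cube(path) -> RamanCube:
    import json
    from pathlib import Path

    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    side = json.loads(path.with_suffix(".json").read_text())
    return RamanCube(
        wavenumbers=data["wavenumbers"],
        intensities=data["intensities"],
        pixel_size=side["pixel_size_um"],
        metadata=side.get("metadata", {}),
        stages=tuple(side.get("stages", ())),
    )
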