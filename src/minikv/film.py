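"""Synthetic radiochromic-film forward model and the film analysis chain.

The forward model maps a dose plane to a 16-bit RGB scan: dose -> net
optical density through the standard radiochromic calibration form
``D = a * netOD + b * netOD^n`` (inverted numerically; strictly monotone on
the calibrated range), then ``PV = PV_unexposed * 10^-netOD`` on the red
channel (the dosimetry channel; green/blue respond with reduced
sensitivity), plus per-pixel Gaussian scanner noise.  The inverse analysis
mirrors the measurement procedure: red channel, average of the central five
pixel rows along the beam axis, a 1-D median filter, calibration inversion
and normalisation -- yielding a PDD with per-depth uncertainty from the
five-row spread.

This synthetic response stands in for real film calibration; it represents
the stabilised (24 h) post-irradiation state and models no scanner lateral
artefacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import medfilt

from .analysis import IsodoseMap, PDDCurve, isodose_from_plane

DPI_DEFAULT = 300
CALIBRATED_DOSE_RANGE_GY = (0.0, 16.0)  # irradiated levels span 0.25-16 Gy


@dataclass
class FilmResponseModel:
    """Dose -> netOD -> red-channel pixel value calibration (synthetic)."""

    a_gy: float = 10.0
    b_gy: float = 40.0
    n: float = 2.5
    pv_unexposed: float = 42000.0
    noise_sigma_pv: float = 0.0
    dpi: float = DPI_DEFAULT
    dose_range_gy: tuple[float, float] = CALIBRATED_DOSE_RANGE_GY
    # reduced sensitivity of the non-dosimetry channels
    channel_sensitivity: tuple[float, float, float] = (1.0, 0.45, 0.2)

    _netod_grid: np.ndarray = field(default=None, repr=False)
    _dose_grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.a_gy <= 0 or self.b_gy < 0 or self.n <= 1:
            raise ValueError("calibration requires a > 0, b >= 0, n > 1")
        # netOD upper bound: solve D(netOD) = dose max (monotone)
        x = np.linspace(0.0, 2.0, 4001)
        d = self.a_gy * x + self.b_gy * x**self.n
        self._netod_grid = x
        self._dose_grid = d

    @property
    def pixel_pitch_cm(self) -> float:
        return 2.54 / self.dpi

    def netod_from_dose(self, dose_gy) -> np.ndarray:
        dose_gy = np.asarray(dose_gy, float)
        lo, hi = self.dose_range_gy
        if np.any(dose_gy < lo - 1e-12) or np.any(dose_gy > hi + 1e-12):
            raise ValueError(
                f"dose outside the calibrated range [{lo}, {hi}] Gy"
            )
        return np.interp(dose_gy, self._dose_grid, self._netod_grid)

    def dose_from_netod(self, netod) -> np.ndarray:
        return np.interp(np.asarray(netod, float), self._netod_grid, self._dose_grid)

    def pv_from_dose(self, dose_gy, channel: int = 0) -> np.ndarray:
        s = self.channel_sensitivity[channel]
        return self.pv_unexposed * 10.0 ** (-s * self.netod_from_dose(dose_gy))

    def dose_from_pv(self, pv) -> np.ndarray:
        """Invert the red-channel response (channel 0)."""
        pv = np.clip(np.asarray(pv, float), 1.0, self.pv_unexposed)
        netod = np.log10(self.pv_unexposed / pv)
        return self.dose_from_netod(netod)


@dataclass
class FilmScan:
    """16-bit RGB scan with spatial metadata and cut-out mask."""

    image: np.ndarray  # (ny, nx, 3) uint16
    pixel_pitch_cm: float
    device_center_px: tuple[float, float]  # (col, row) of the device axis
    device_radius_cm: float
    cutout: str = "circle"  # "circle" (bare probe) or "hemisphere"
    mask: np.ndarray | None = None  # True where there is no film

    def __post_init__(self):
        if self.image.dtype != np.uint16 or self.image.ndim != 3:
            raise ValueError("image must be a (ny, nx, 3) uint16 array")
        if self.mask is None:
            self.mask = self._build_mask()

    def _build_mask(self) -> np.ndarray:
        ny, nx = self.image.shape[:2]
        cx, cy = self.device_center_px
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        r_px = self.device_radius_cm / self.pixel_pitch_cm
        inside = (jj - cx) ** 2 + (ii - cy) ** 2 < r_px**2
        if self.cutout == "hemisphere":
            inside &= jj <= cx
        return inside

    @property
    def x_cm(self) -> np.ndarray:
        return (np.arange(self.image.shape[1]) - self.device_center_px[0]) * self.pixel_pitch_cm

    @property
    def y_cm(self) -> np.ndarray:
        return (np.arange(self.image.shape[0]) - self.device_center_px[1]) * self.pixel_pitch_cm

    def write(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.image)
        meta = {
            "pixel_pitch_cm": self.pixel_pitch_cm,
            "device_center_px": list(self.device_center_px),
            "device_radius_cm": self.device_radius_cm,
            "cutout": self.cutout,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "FilmScan":
        import tifffile

        path = Path(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"missing registration sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        return cls(
            tifffile.imread(path),
            pixel_pitch_cm=meta["pixel_pitch_cm"],
            device_center_px=tuple(meta["device_center_px"]),
            device_radius_cm=meta["device_radius_cm"],
            cutout=meta["cutout"],
        )


def synthesize_film(dose_plane, response: FilmResponseModel, *,
                    film_size_cm: tuple[float, float] = (9.0, 6.0),
                    device_radius_cm: float = 0.16075,
                    cutout: str = "circle",
                    device_position: str = "edge",
                    seed: int = 0) -> FilmScan:
    """Forward-generate a film scan from a dose plane.

    ``dose_plane`` is a callable ``dose_gy = f(x_cm, y_cm)`` evaluated on
    pixel centres, with the device axis at the coordinate origin.  The
    device sits at the film's left edge midline (``device_position='edge'``,
    the applicator-against-film geometry) or at the film centre
    (``'center'``, the bare-probe cut-out geometry).
    """
    wx, wy = film_size_cm
    pitch = response.pixel_pitch_cm
    nx, ny = int(round(wx / pitch)), int(round(wy / pitch))
    if device_position == "edge":
        cx, cy = 0.0, (ny - 1) / 2.0
    else:
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx) - cx) * pitch
    y = (np.arange(ny) - cy) * pitch
    xx, yy = np.meshgrid(x, y)
    dose = np.asarray(dose_plane(xx, yy), float)
    rng = np.random.default_rng(seed)
    img = np.zeros((ny, nx, 3), dtype=np.uint16)
    r_px = device_radius_cm / pitch
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    mask = (jj - cx) ** 2 + (ii - cy) ** 2 < r_px**2
    if cutout == "hemisphere":
        mask &= jj <= cx
    dose_safe = np.where(mask, 0.0, np.clip(dose, *response.dose_range_gy))
    if np.any(~mask & ((dose < response.dose_range_gy[0] - 1e-12)
                       | (dose > response.dose_range_gy[1] + 1e-12))):
        raise ValueError("dose plane exceeds the calibrated range")
    for ch in range(3):
        pv = response.pv_from_dose(dose_safe, channel=ch)
        if response.noise_sigma_pv > 0:
            pv = pv + rng.normal(0.0, response.noise_sigma_pv, pv.shape)
        pv[mask] = 65535.0  # cut-out: scanner sees open aperture
        img[:, :, ch] = np.clip(np.round(pv), 0, 65535).astype(np.uint16)
    return FilmScan(img, pixel_pitch_cm=pitch, device_center_px=(cx, cy),
                    device_radius_cm=device_radius_cm, cutout=cutout, mask=mask)


def _axis_rows(scan: FilmScan, n_rows: int = 5) -> np.ndarray:
    cy = int(round(scan.device_center_px[1]))
    half = n_rows // 2
    rows = np.arange(cy - half, cy + half + 1)
    if rows[0] < 0 or rows[-1] >= scan.image.shape[0]:
        raise ValueError("fewer than five rows available at the device axis")
    return rows


def film_pdd(scan: FilmScan, response: FilmResponseModel, *,
             norm_depth_cm: float = 1.0, median_window: int = 5,
             n_rows: int = 5) -> PDDCurve:
    """PDD along +x from the device surface, with five-row uncertainty.

    Red channel -> average of the central five rows -> 1-D median filter ->
    calibration inversion -> normalisation at ``norm_depth_cm``.
    """
    if scan.device_center_px is None:
        raise ValueError("scan is missing axis registration metadata")
    rows = _axis_rows(scan, n_rows)
    red = scan.image[:, :, 0].astype(float)
    cols_x = scan.x_cm
    depth = cols_x - scan.device_radius_cm
    usable = depth > 0.5 * scan.pixel_pitch_cm
    band = red[np.ix_(rows, np.flatnonzero(usable))]
    mask_band = scan.mask[np.ix_(rows, np.flatnonzero(usable))]
    if np.any(mask_band):
        raise ValueError("cut-out mask intrudes into the analysis band")
    avg_pv = band.mean(axis=0)
    avg_pv = medfilt(avg_pv, kernel_size=median_window)
    dose = response.dose_from_pv(avg_pv)
    # per-depth spread over the individual rows (measurement uncertainty)
    row_doses = np.stack([response.dose_from_pv(band[i]) for i in range(len(rows))])
    sigma = row_doses.std(axis=0, ddof=1)
    depths = depth[usable]
    rel = np.divide(sigma, dose, out=np.zeros_like(sigma), where=dose > 0)
    curve = PDDCurve(depths, dose, rel, axis="x",
                     origin_offset_cm=scan.device_radius_cm)
    return curve.normalised(norm_depth_cm)


def film_dose_plane(scan: FilmScan, response: FilmResponseModel) -> np.ndarray:
    """Reconstruct the dose plane (Gy) from the red channel; masked pixels 0."""
    dose = response.dose_from_pv(scan.image[:, :, 0].astype(float))
    dose[scan.mask] = 0.0
    return dose


def film_isodose(scan: FilmScan, response: FilmResponseModel,
                 normalisation_point=(1.0, 0.0),
                 levels=tuple(range(10, 101, 10))) -> IsodoseMap:
    """Isodose map of the reconstructed film dose plane (10 % steps)."""
    dose = film_dose_plane(scan, response)
    # plane indexed (x, y): transpose from image (row=y, col=x)
    return isodose_from_plane(scan.x_cm, scan.y_cm, dose.T,
                              normalisation_point, levels)


def slice_sigma(scan: FilmScan, response: FilmResponseModel,
                n_rows: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """(depths, per-depth standard deviation across the five axis rows)."""
    rows = _axis_rows(scan, n_rows)
    red = scan.image[:, :, 0].astype(float)
    depth = scan.x_cm - scan.device_radius_cm
    usable = depth > 0.5 * scan.pixel_pitch_cm
    band = red[np.ix_(rows, np.flatnonzero(usable))]
    row_doses = np.stack([response.dose_from_pv(band[i]) for i in range(len(rows))])
    return depth[usable], row_doses.std(axis=0, ddof=1)


def film_set_uncertainty(scans, response: FilmResponseModel,
                         n_rows: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth film-set uncertainty from repeat slices of one device.

    Step 1: per-slice standard deviation across the five axis rows
    (sigma_slice_i); step 2: the standard deviation over the slices at each
    depth gives sigma_film.
    """
    if len(scans) < 2:
        raise ValueError("need at least two film slices")
    depths_ref = None
    sigmas = []
    for scan in scans:
        d, s = slice_sigma(scan, response, n_rows)
        if depths_ref is None:
            depths_ref = d
        elif len(d) != len(depths_ref) or not np.allclose(d, depths_ref):
            raise ValueError("film slices have mismatched depth grids")
        sigmas.append(s)
    arr = np.stack(sigmas)
    return depths_ref, arr.std(axis=0, ddof=1)
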