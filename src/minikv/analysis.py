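"""Spectrum statistics, PDD extraction and fitting, isodose maps, comparisons.

Depth-dose curves are normalised to 100 % at a reference depth (probe:
0.1992 cm from the isocentre, i.e. 0.03845 cm from the tip surface;
applicators: 0.2 cm from the applicator surface by default).  Two fit
models are provided:

``eq2`` (bare probe)   y = 100 A exp(-Bx) + 100 C exp(-Dx)
``eq3`` (applicators)  y = 100 A exp(-Bx - 2 ln x + C)
                         = 100 A e^C exp(-Bx) / x^2

where x is the distance from the device isocentre, so the 1/x^2 factor in
``eq3`` carries the inverse-square fall-off and the exponential the water
attenuation.  In ``eq3`` the parameters A and C enter only through the
product A e^C and are not individually identifiable; the fit reports the
amplitude in A and sets C = 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .dosegrid import DoseGrid

PROBE_SURFACE_RADIUS = 0.16075
PROBE_NORM_FROM_ISOCENTRE = 0.1992  # closest ionisation-chamber depth
APPLICATOR_NORM_FROM_SURFACE = 0.2


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Binned photon fluence vs energy (uniform bins)."""

    bin_edges_kev: np.ndarray
    fluence: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.bin_edges_kev = np.asarray(self.bin_edges_kev, float)
        self.fluence = np.asarray(self.fluence, float)
        if np.any(np.diff(self.bin_edges_kev) <= 0):
            raise ValueError("bin edges must be ascending")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")

    @classmethod
    def from_energies(cls, energies, weights=None, bin_kev: float = 0.2,
                      e_max: float | None = None, provenance: str = "") -> "Spectrum":
        energies = np.asarray(energies, float)
        if e_max is None:
            e_max = math.ceil(float(energies.max()) / bin_kev) * bin_kev
        edges = np.arange(0.0, e_max + bin_kev / 2, bin_kev)
        fl, _ = np.histogram(energies, bins=edges, weights=weights)
        return cls(edges, fl, provenance)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_kev[:-1] + self.bin_edges_kev[1:])

    def mean_energy(self) -> float:
        """Fluence-weighted mean of bin centres, keV."""
        total = self.fluence.sum()
        if total <= 0:
            raise ValueError("empty spectrum")
        return float((self.centers * self.fluence).sum() / total)

    def find_peaks(self, window: int = 3, min_fluence: float = 0.0) -> list[float]:
        """Bin centres that are strict local maxima over +/- ``window`` bins."""
        f, c = self.fluence, self.centers
        peaks = []
        for i in range(len(f)):
            if f[i] <= min_fluence:
                continue
            lo, hi = max(0, i - window), min(len(f), i + window + 1)
            neighbours = np.delete(f[lo:hi], i - lo)
            if neighbours.size and f[i] > neighbours.max():
                peaks.append(float(c[i]))
        return peaks

    def to_csv(self, path) -> None:
        rows = ["bin_lo_keV,bin_hi_keV,fluence"]
        for lo, hi, fl in zip(self.bin_edges_kev[:-1], self.bin_edges_kev[1:],
                              self.fluence):
            rows.append(f"{lo:.6g},{hi:.6g},{fl:.10g}")
        from pathlib import Path

        Path(path).write_text("\n".join(rows) + "\n")


def mean_energy(spectrum: Spectrum) -> float:
    return spectrum.mean_energy()


# ---------------------------------------------------------------------------
# PDD
# ---------------------------------------------------------------------------

@dataclass
class PDDCurve:
    """Percent depth dose vs depth from the device surface along one axis.

    ``origin_offset_cm`` is the distance from the device isocentre to the
    surface (probe tip or ball radius); fits are performed against
    ``depth + origin_offset`` so the inverse-square term is anchored at the
    isocentre.
    """

    depths_cm: np.ndarray
    percent_dose: np.ndarray
    rel_unc: np.ndarray | None = None
    axis: str = "z"
    origin_offset_cm: float = 0.0
    norm_depth_cm: float | None = None

    def __post_init__(self):
        self.depths_cm = np.asarray(self.depths_cm, float)
        self.percent_dose = np.asarray(self.percent_dose, float)
        if np.any(np.diff(self.depths_cm) <= 0):
            raise ValueError("depths must be strictly ascending")

    def value_at(self, depth_cm: float) -> float:
        d = self.depths_cm
        if not (d[0] <= depth_cm <= d[-1]):
            raise ValueError(f"depth {depth_cm} outside sampled range "
                             f"[{d[0]:.4g}, {d[-1]:.4g}]")
        return float(np.interp(depth_cm, d, self.percent_dose))

    def normalised(self, norm_depth_cm: float) -> "PDDCurve":
        scale = 100.0 / self.value_at(norm_depth_cm)
        return PDDCurve(self.depths_cm, self.percent_dose * scale, self.rel_unc,
                        self.axis, self.origin_offset_cm, norm_depth_cm)


def extract_pdd(grid: DoseGrid, axis: str = "z", *,
                surface_offset_cm: float = PROBE_SURFACE_RADIUS,
                norm_depth_cm: float | None = None) -> PDDCurve:
    """Central-axis dose vs distance from the device surface, normalised to
    100 % at ``norm_depth_cm`` (linear interpolation between voxel centres).

    ``surface_offset_cm`` is the device-surface coordinate along the axis
    (probe tip z or applicator ball radius); it also becomes the curve's
    isocentre offset.
    """
    ax = {"x": 0, "z": 2}[axis]
    other = [i for i in range(3) if i != ax]
    idx = [0, 0, 0]
    for o in other:
        idx[o] = int(np.argmin(np.abs(grid.centers(o))))
    sl = tuple(slice(None) if i == ax else idx[i] for i in range(3))
    dose = grid.dose[sl]
    unc = grid.rel_unc[sl] if grid.rel_unc is not None else None
    coord = grid.centers(ax)
    depths = coord - surface_offset_cm
    keep = depths > 0
    curve = PDDCurve(depths[keep], dose[keep],
                     unc[keep] if unc is not None else None,
                     axis=axis, origin_offset_cm=surface_offset_cm)
    if norm_depth_cm is None:
        norm_depth_cm = float(curve.depths_cm[0])
    return curve.normalised(norm_depth_cm)


def pdd_from_shell(result, surface_offset_cm: float,
                   norm_depth_cm: float = APPLICATOR_NORM_FROM_SURFACE) -> PDDCurve:
    """PDD from a forward-cone shell-tally run (see transport.ShellTally).

    Radii are converted to depths from the device surface; normalisation as
    for the voxel-extracted PDD.
    """
    tally, dose = result.shell_tally, result.shell_dose
    depths = tally.r_centers - surface_offset_cm
    keep = (depths > 0) & (dose > 0)
    curve = PDDCurve(depths[keep], dose[keep],
                     result.shell_rel_unc[keep] if result.shell_rel_unc is not None else None,
                     axis="z", origin_offset_cm=surface_offset_cm)
    return curve.normalised(norm_depth_cm)


# ---------------------------------------------------------------------------
# Fit models
# ---------------------------------------------------------------------------

@dataclass
class PDDFit:
    model: str  # "eq2" or "eq3"
    A: float
    B: float
    C: float
    D: float = 0.0
    r2: float = float("nan")
    covariance: np.ndarray | None = None
    origin_offset_cm: float = 0.0

    def __post_init__(self):
        if self.model not in ("eq2", "eq3"):
            raise ValueError("model must be 'eq2' or 'eq3'")
        if self.B < 0 or self.D < 0:
            raise ValueError("decay rates B, D must be non-negative")


def evaluate_model(fit: PDDFit, x) -> np.ndarray | float:
    """Percent dose at isocentre distance(s) x (cm)."""
    x_arr = np.asarray(x, float)
    if fit.model == "eq2":
        y = 100.0 * fit.A * np.exp(-fit.B * x_arr) + 100.0 * fit.C * np.exp(-fit.D * x_arr)
    else:
        if np.any(x_arr <= 0):
            raise ValueError("eq3 requires x > 0 (logarithmic term)")
        y = 100.0 * fit.A * np.exp(-fit.B * x_arr - 2.0 * np.log(x_arr) + fit.C)
    return y if y.ndim else float(y)


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_model(curve: PDDCurve, model: str = "eq3",
              weighting: str = "relative") -> PDDFit:
    """Least-squares fit of ``eq2`` or ``eq3`` to a PDD curve.

    x is depth + isocentre offset.  Initialisation: log-linear regression on
    the tail for the slow component, residual fit for the fast one (eq2);
    log-linear regression of ln(y x^2) for eq3.  B, D are bounded >= 0.

    ``weighting`` selects the residual scale: ``"relative"`` (default,
    sigma ~ y -- the right treatment for the multiplicative noise of
    Monte-Carlo and film data, without which the steep near-surface points
    dominate and the decay rates are ill-determined), ``"uncertainty"``
    (sigma from the curve's per-point relative uncertainties) or ``"none"``
    (plain unweighted least squares, the convention of the published fit
    tables).  R^2 is always reported on unweighted residuals.
    """
    x = curve.depths_cm + curve.origin_offset_cm
    y = curve.percent_dose
    if len(x) < 5:
        raise ValueError("need at least 5 points to fit")
    if weighting == "relative":
        sigma = np.maximum(y, 1e-12)
    elif weighting == "uncertainty":
        if curve.rel_unc is None:
            raise ValueError("curve carries no uncertainties")
        sigma = np.maximum(curve.rel_unc, 1e-3) * np.maximum(y, 1e-12)
    elif weighting == "none":
        sigma = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if model == "eq3":
        if np.any(x <= 0):
            raise ValueError("eq3 requires positive isocentre distances")
        pos = y > 0
        lny = np.log(y[pos] * x[pos] ** 2 / 100.0)
        slope, intercept = np.polyfit(x[pos], lny, 1)
        g0, b0 = math.exp(intercept), max(-slope, 1e-6)

        def f(xv, g, b):
            return 100.0 * g * np.exp(-b * xv) / xv**2

        try:
            popt, pcov = curve_fit(f, x, y, p0=[g0, b0], sigma=sigma,
                                   bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(f"eq3 fit failed to converge: {err}") from err
        fit = PDDFit("eq3", A=float(popt[0]), B=float(popt[1]), C=0.0,
                     covariance=pcov, origin_offset_cm=curve.origin_offset_cm)
    elif model == "eq2":
        n = len(x)
        tail = slice(max(n // 2, n - 10), n)
        pos = y[tail] > 0
        slope, intercept = np.polyfit(x[tail][pos], np.log(y[tail][pos] / 100.0), 1)
        c0, d0 = math.exp(intercept), max(-slope, 1e-6)
        resid = y - 100.0 * c0 * np.exp(-d0 * x)
        head = resid[: max(3, n // 3)] > 0
        if head.sum() >= 2:
            xs = x[: max(3, n // 3)][head]
            slope2, intercept2 = np.polyfit(
                xs, np.log(resid[: max(3, n // 3)][head] / 100.0), 1
            )
            a0, b0 = math.exp(intercept2), max(-slope2, d0 * 2)
        else:
            a0, b0 = c0, d0 * 4
        def f(xv, a, b, c, d):
            return 100.0 * a * np.exp(-b * xv) + 100.0 * c * np.exp(-d * xv)

        try:
            popt, pcov = curve_fit(f, x, y, p0=[a0, b0, c0, d0], sigma=sigma,
                                   bounds=([0, 0, 0, 0], [np.inf] * 4), maxfev=40000)
        except RuntimeError as err:
            raise RuntimeError(f"eq2 fit failed to converge: {err}") from err
        a, b, c, d = (float(v) for v in popt)
        if b < d:  # report the fast component first
            a, b, c, d = c, d, a, b
        fit = PDDFit("eq2", A=a, B=b, C=c, D=d, covariance=pcov,
                     origin_offset_cm=curve.origin_offset_cm)
    else:
        raise ValueError("model must be 'eq2' or 'eq3'")
    fit.r2 = _r2(y, evaluate_model(fit, x))
    return fit


# ---------------------------------------------------------------------------
# Curve comparison with horizontal shift alignment
# ---------------------------------------------------------------------------

def compare_curves(reference: PDDFit, test_points, shift_cm: float = 0.0) -> np.ndarray:
    """Per-point percent differences 100 (test - model)/model.

    ``test_points`` is an iterable of (depth, value[, uncertainty]) tuples in
    the reference curve's depth coordinate; depths are shifted by
    ``shift_cm`` before evaluating the reference's fitted model.
    """
    pts = [tuple(p) for p in test_points]
    if not pts:
        raise ValueError("no test points")
    depths = np.asarray([p[0] for p in pts], float) + shift_cm
    vals = np.asarray([p[1] for p in pts], float)
    x = depths + reference.origin_offset_cm
    if reference.model == "eq3" and np.any(x <= 0):
        raise ValueError("shifted points fall outside the fitted range")
    model = evaluate_model(reference, x)
    return 100.0 * (vals - model) / model


def best_shift(reference: PDDFit, test_points, shifts,
               allow_rescale: bool = False) -> float:
    """Grid-search the shift minimising the RMS percent difference.

    With ``allow_rescale`` a free multiplicative factor is fitted per shift:
    appropriate when the test curve was normalised at its own (possibly
    misregistered) reference depth, which turns a pure spatial shift into a
    shift plus a constant scale.
    """
    pts = [tuple(p) for p in test_points]
    vals = np.asarray([p[1] for p in pts], float)
    best, best_rms = 0.0, math.inf
    for s in shifts:
        try:
            d = compare_curves(reference, pts, shift_cm=float(s))
        except ValueError:
            continue
        if allow_rescale:
            model = vals / (1.0 + d / 100.0)
            scale = float(np.mean(vals / model))
            d = 100.0 * (vals - scale * model) / (scale * model)
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms:
            best, best_rms = float(s), rms
    return best


# ---------------------------------------------------------------------------
# Isodose maps
# ---------------------------------------------------------------------------

@dataclass
class IsodoseMap:
    """Relative dose in an xy-plane with 10 %-step contour polylines."""

    x_cm: np.ndarray
    y_cm: np.ndarray
    dose_percent: np.ndarray  # shape (nx, ny)
    levels: tuple = tuple(range(10, 101, 10))
    contours: dict = field(default_factory=dict)  # level -> list of (N,2) xy arrays

    def area(self, level: int) -> float:
        """Total area (cm^2) enclosed by the contours of one level."""
        total = 0.0
        for poly in self.contours.get(level, []):
            xs, ys = poly[:, 0], poly[:, 1]
            total += 0.5 * abs(
                float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1)))
            )
        return total


def isodose_from_plane(x_cm, y_cm, plane, normalisation_point=(0.0, 0.0),
                       levels=tuple(range(10, 101, 10))) -> IsodoseMap:
    """Normalise a dose plane (indexed [x, y]) to 100 % at a point and
    extract contour polylines at the requested levels."""
    from skimage import measure

    xc, yc = np.asarray(x_cm, float), np.asarray(y_cm, float)
    plane = np.asarray(plane, float)
    if not (xc[0] <= normalisation_point[0] <= xc[-1]
            and yc[0] <= normalisation_point[1] <= yc[-1]):
        raise ValueError("normalisation point outside the plane")
    ix = int(np.argmin(np.abs(xc - normalisation_point[0])))
    iy = int(np.argmin(np.abs(yc - normalisation_point[1])))
    ref = plane[ix, iy]
    if ref <= 0:
        raise ValueError("zero dose at the normalisation point")
    rel = 100.0 * plane / ref
    contours: dict = {}
    for lev in levels:
        polys = measure.find_contours(rel, lev)
        out = []
        for p in polys:
            xs = np.interp(p[:, 0], np.arange(len(xc)), xc)
            ys = np.interp(p[:, 1], np.arange(len(yc)), yc)
            out.append(np.column_stack([xs, ys]))
        contours[lev] = out
    return IsodoseMap(xc, yc, rel, tuple(levels), contours)


def isodose_map(grid: DoseGrid, plane_z_cm: float, normalisation_point=(0.0, 0.0),
                levels=tuple(range(10, 101, 10))) -> IsodoseMap:
    """Dose plane at ``plane_z_cm`` normalised to 100 % at a point, with
    contours at the requested levels (default 10 %...100 % in 10 % steps)."""
    zc = grid.centers(2)
    if not (zc[0] <= plane_z_cm <= zc[-1]):
        raise ValueError("plane outside the grid")
    iz = int(np.argmin(np.abs(zc - plane_z_cm)))
    plane = grid.dose[:, :, iz]
    return isodose_from_plane(grid.centers(0), grid.centers(1), plane,
                              normalisation_point, levels)
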