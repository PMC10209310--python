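"""Photon interaction data: attenuation tables, emission lines, bremsstrahlung.

The shipped table ``data/attenuation.csv`` holds per-material mass
coefficients (cm^2/g) for photoelectric, incoherent, coherent, total and
energy absorption on a 1-200 keV grid with points straddling every
absorption edge.  Lookups are log-log interpolated, which is exact at grid
nodes and monotone between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .materials import Material, get_material

E_MIN_KEV = 1.0
E_MAX_KEV = 200.0

_COLUMNS = ("pe", "incoh", "coh", "total", "mu_en")


class AttenuationTable:
    """Log-log interpolated mass-attenuation coefficients for one material."""

    def __init__(self, energy_kev: np.ndarray, coeffs: dict[str, np.ndarray]):
        energy_kev = np.asarray(energy_kev, dtype=float)
        if energy_kev.ndim != 1 or np.any(np.diff(energy_kev) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if energy_kev[0] > E_MIN_KEV or energy_kev[-1] < E_MAX_KEV:
            raise ValueError("energy grid must span at least 1-200 keV")
        self.energy_kev = energy_kev
        self._log_e = np.log(energy_kev)
        self._log_c = {}
        for name in _COLUMNS:
            c = np.asarray(coeffs[name], dtype=float)
            if np.any(c <= 0):
                raise ValueError(f"{name} coefficients must be > 0 on the grid")
            self._log_c[name] = np.log(c)
        total = np.exp(self._log_c["total"])
        parts = sum(np.exp(self._log_c[k]) for k in ("pe", "incoh", "coh"))
        if np.any(np.abs(total - parts) > 0.01 * total):
            raise ValueError("total differs from sum of components by > 1%")

    def __call__(self, energy_kev: float, column: str = "total") -> float:
        if not (E_MIN_KEV <= energy_kev <= E_MAX_KEV):
            raise ValueError(
                f"energy {energy_kev} keV outside table range "
                f"[{E_MIN_KEV}, {E_MAX_KEV}]"
            )
        x = math.log(energy_kev)
        return math.exp(float(np.interp(x, self._log_e, self._log_c[column])))

    def components(self, energy_kev: float) -> tuple[float, float, float]:
        """(pe, incoherent, coherent) mass coefficients at one energy."""
        return (
            self(energy_kev, "pe"),
            self(energy_kev, "incoh"),
            self(energy_kev, "coh"),
        )


class PhysicsData:
    """Bundle of attenuation tables and emission-line data.

    ``mu_scale`` uniformly rescales all linear attenuation coefficients; it
    exists for limit checks (e.g. the vacuum limit ``mu_scale=0`` in which
    photons stream freely).
    """

    def __init__(self, tables: dict[str, AttenuationTable] | None = None,
                 mu_scale: float = 1.0):
        self.tables = dict(_load_shipped_tables()) if tables is None else tables
        self.mu_scale = mu_scale

    def table(self, material: str | Material) -> AttenuationTable:
        name = material.name if isinstance(material, Material) else material
        if name == "vacuum":
            raise KeyError("vacuum has no attenuation table")
        try:
            return self.tables[name]
        except KeyError:
            raise KeyError(f"no attenuation table for material {name!r}") from None

    def mu_linear(self, material: str | Material, energy_kev: float,
                  column: str = "total") -> float:
        """Linear attenuation coefficient in cm^-1 (density x mu/rho)."""
        mat = material if isinstance(material, Material) else get_material(material)
        if mat.name == "vacuum":
            return 0.0
        return self.mu_scale * mat.density * self.table(mat.name)(energy_kev, column)

    def mu_components(self, material: str | Material,
                      energy_kev: float) -> tuple[float, float, float]:
        """Linear (pe, incoherent, coherent) coefficients in cm^-1."""
        mat = material if isinstance(material, Material) else get_material(material)
        if mat.name == "vacuum":
            return (0.0, 0.0, 0.0)
        pe, inc, coh = self.table(mat.name).components(energy_kev)
        s = self.mu_scale * mat.density
        return (s * pe, s * inc, s * coh)

    def mu_en_over_rho(self, material: str | Material, energy_kev: float) -> float:
        mat = material if isinstance(material, Material) else get_material(material)
        if mat.name == "vacuum":
            return 0.0
        return self.table(mat.name)(energy_kev, "mu_en")


_DEFAULT: PhysicsData | None = None


def default_physics() -> PhysicsData:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = PhysicsData()
    return _DEFAULT


def _load_shipped_tables() -> dict[str, AttenuationTable]:
    path = resources.files("minikv").joinpath("data/attenuation.csv")
    raw = path.read_text().strip().splitlines()
    header = raw[0].split(",")
    assert header == ["material", "energy_keV", *list(_COLUMNS)]
    per_mat: dict[str, list[list[float]]] = {}
    for line in raw[1:]:
        parts = line.split(",")
        per_mat.setdefault(parts[0], []).append([float(v) for v in parts[1:]])
    tables = {}
    for name, rows in per_mat.items():
        arr = np.asarray(rows)
        tables[name] = AttenuationTable(
            arr[:, 0], {col: arr[:, i + 1] for i, col in enumerate(_COLUMNS)}
        )
    return tables


def mu_linear(material: str | Material, energy_kev: float) -> float:
    """Module-level convenience using the shipped tables."""
    return default_physics().mu_linear(material, energy_kev)


# ---------------------------------------------------------------------------
# Characteristic emission lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionLine:
    element: str
    shell: str  # Kalpha, Kbeta, Lalpha, Lbeta, Lgamma
    energy_kev: float
    fluorescence_yield: float
    relative_intensity: float

    def __post_init__(self) -> None:
        if not (0 < self.energy_kev < 100):
            raise ValueError("line energy must be in (0, 100) keV")
        if not (0 <= self.fluorescence_yield <= 1):
            raise ValueError("fluorescence yield must be in [0, 1]")


# (shell, energy keV, relative intensity within the element), K yield, L yield
_LINE_DB: dict[str, dict] = {
    "Be": {"lines": [("Kalpha", 0.108, 1.0)], "omega_K": 3e-4, "omega_L": 0.0},
    "Al": {"lines": [("Kalpha", 1.487, 1.0)], "omega_K": 0.039, "omega_L": 0.0},
    "Cr": {
        "lines": [("Kalpha", 5.415, 0.88), ("Kbeta", 5.947, 0.12)],
        "omega_K": 0.275,
        "omega_L": 0.0,
    },
    "Fe": {
        "lines": [("Kalpha", 6.404, 0.88), ("Kbeta", 7.058, 0.12)],
        "omega_K": 0.340,
        "omega_L": 0.0,
    },
    "Ni": {
        "lines": [("Kalpha", 7.472, 0.875), ("Kbeta", 8.265, 0.125)],
        "omega_K": 0.406,
        "omega_L": 0.0,
    },
    "Cu": {
        "lines": [("Kalpha", 8.041, 0.88), ("Kbeta", 8.905, 0.12)],
        "omega_K": 0.440,
        "omega_L": 0.0,
    },
    "Mo": {
        "lines": [("Kalpha", 17.443, 0.84), ("Kbeta", 19.633, 0.16)],
        "omega_K": 0.765,
        "omega_L": 0.0,
    },
    # Au: standard line energies; Z >= 70, so the L series is included
    "Au": {
        "lines": [
            ("Lalpha", 9.713, 0.38),
            ("Lbeta", 11.442, 0.33),
            ("Lgamma", 13.382, 0.09),
            ("Kalpha", 68.804, 0.14),
            ("Kbeta", 77.985, 0.06),
        ],
        "omega_K": 0.960,
        "omega_L": 0.32,
    },
}

_Z_OF = {"Be": 4, "Al": 13, "Cr": 24, "Fe": 26, "Ni": 28, "Cu": 29, "Mo": 42, "Au": 79}

# K absorption edges (keV) for the fluorescing elements
K_EDGE_KEV = {"Cr": 5.989, "Fe": 7.112, "Ni": 8.333, "Cu": 8.979, "Mo": 20.0, "Au": 80.725}


def characteristic_lines(element: str) -> list[EmissionLine]:
    """All K lines (plus L lines for Z >= 70) above 1 keV for ``element``."""
    try:
        entry = _LINE_DB[element]
    except KeyError:
        raise KeyError(f"no emission-line data for element {element!r}") from None
    z = _Z_OF[element]
    out = []
    for shell, e, ri in entry["lines"]:
        if e < E_MIN_KEV:
            continue
        if shell.startswith("L") and z < 70:
            continue
        omega = entry["omega_K"] if shell.startswith("K") else entry["omega_L"]
        out.append(EmissionLine(element, shell, e, omega, ri))
    return out


def lines_for_shell(element: str, shell_family: str) -> list[EmissionLine]:
    """Lines of one shell family ('K' or 'L'), intensities renormalised."""
    lines = [
        ln for ln in characteristic_lines(element) if ln.shell.startswith(shell_family)
    ]
    total = sum(ln.relative_intensity for ln in lines)
    return [
        EmissionLine(ln.element, ln.shell, ln.energy_kev, ln.fluorescence_yield,
                     ln.relative_intensity / total)
        for ln in lines
    ]


def fluorescence_yield_K(element: str) -> float:
    return _LINE_DB[element]["omega_K"]


# ---------------------------------------------------------------------------
# Bremsstrahlung continuum (Kramers thick-target shape)
# ---------------------------------------------------------------------------

def bremsstrahlung_pdf(electron_energy_kev: float):
    """Normalised Kramers spectral density N(E) ~ (E0 - E)/E on [1, E0].

    Target self-absorption is applied downstream by the transport through
    the sampled emission depth in the gold target, so the emission density
    itself is the bare thick-target shape.
    """
    e0 = float(electron_energy_kev)
    if e0 <= E_MIN_KEV:
        raise ValueError("electron energy must exceed 1 keV")
    if e0 > E_MAX_KEV:
        raise ValueError("electron energy above the 200 keV table bound")
    norm = e0 * math.log(e0 / E_MIN_KEV) - (e0 - E_MIN_KEV)

    def pdf(e_kev):
        e = np.asarray(e_kev, dtype=float)
        out = np.where(
            (e >= E_MIN_KEV) & (e <= e0), np.maximum(e0 - e, 0.0) / np.maximum(e, E_MIN_KEV) / norm, 0.0
        )
        return out if out.ndim else float(out)

    return pdf


def sample_bremsstrahlung(electron_energy_kev: float, rng: np.random.Generator) -> float:
    """Draw one photon energy from the Kramers shape by rejection.

    Envelope ~ 1/E on [1, E0]; acceptance probability 1 - E/E0.
    """
    e0 = float(electron_energy_kev)
    if e0 <= E_MIN_KEV:
        raise ValueError("electron energy must exceed 1 keV")
    log_e0 = math.log(e0 / E_MIN_KEV)
    while True:
        e = E_MIN_KEV * math.exp(rng.random() * log_e0)
        if rng.random() < 1.0 - e / e0:
            return e
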