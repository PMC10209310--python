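"""Analog photon transport with voxel dose scoring and batch uncertainty.

Photons are transported interaction-to-interaction through the scene
returned by :mod:`minikv.geometry`.  Electrons are not transported: the CSDA
range of sub-50 keV electrons in water (< 0.005 cm) is below the voxel size,
so every electron's energy is deposited at its creation point.  Under that
assumption collision kerma equals absorbed dose, which licenses the two
scoring estimators:

``collision``
    Energy deposited at each interaction point (photoelectric: all of it,
    less any fluorescence photon; incoherent: the Compton-electron share).
    Energy is conserved exactly: entering = deposited + escaped.
``tracklength``
    Collision-kerma track-length estimator: every water path segment adds
    ``E * (mu_en/rho) * ds / V`` to the voxels it crosses.  Unbiased for the
    same quantity, far lower variance; used for PDD-quality runs.

Interactions: photoelectric (with K-fluorescence re-emission in the high-Z
probe layers), incoherent (Klein-Nishina kinematics, free electrons) and
coherent (direction change only, Thomson-like angular law).  Photons below
the 1 keV cutoff are absorbed locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dosegrid import DoseGrid
from .geometry import Scene
from .phasespace import PhaseSpaceFile
from .physics import (
    K_EDGE_KEV,
    PhysicsData,
    default_physics,
    fluorescence_yield_K,
    lines_for_shell,
)

MEC2_KEV = 511.0
WATER_RHO = 0.998

# which element fluoresces after a photoelectric absorption, per material
FLUOR_ELEMENT = {"Ni": "Ni", "NiO": "Ni", "CrN": "Cr", "Au": "Au", "mu-metal": "Ni"}

DEVICE_MATERIALS = {"vacuum", "Au", "Be", "NiO", "Ni", "CrN", "mu-metal", "Al", "ULTEM", "air"}


@dataclass
class TransportConfig:
    cutoff_kev: float = 1.0
    interactions: tuple[str, ...] = ("pe", "incoh", "coh")
    n_batches: int = 10
    coverage_k: float = 1.0
    scoring: str = "collision"  # or "tracklength"
    fluorescence: bool = True

    def __post_init__(self):
        if self.cutoff_kev < 1.0:
            raise ValueError("photon cutoff below the 1 keV table threshold")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for uncertainty")
        if self.scoring not in ("collision", "tracklength"):
            raise ValueError(f"unknown scoring mode {self.scoring!r}")
        bad = set(self.interactions) - {"pe", "incoh", "coh"}
        if bad:
            raise ValueError(f"unknown interaction channels {bad}")

    @property
    def coherent_enabled(self) -> bool:
        return "coh" in self.interactions


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_free_path(mu: float, rng: np.random.Generator) -> float:
    """Exponential free path s = -ln(U)/mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    u = rng.random()
    while u <= 0.0:
        u = rng.random()
    return -math.log(u) / mu


def sample_interaction(material: str, energy_kev: float, physics: PhysicsData,
                       rng: np.random.Generator,
                       interactions: tuple[str, ...] = ("pe", "incoh", "coh")) -> str:
    """Choose an interaction branch with probability ~ its mass coefficient."""
    pe, inc, coh = physics.mu_components(material, energy_kev)
    probs = {"pe": pe, "incoh": inc, "coh": coh}
    chans = [c for c in ("pe", "incoh", "coh") if c in interactions]
    tot = sum(probs[c] for c in chans)
    r = rng.random() * tot
    acc = 0.0
    for c in chans:
        acc += probs[c]
        if r <= acc:
            return c
    return chans[-1]


def sample_klein_nishina_mu(energy_kev: float, rng: np.random.Generator) -> float:
    """cos(theta) from the Klein-Nishina angular distribution (rejection)."""
    a = energy_kev / MEC2_KEV
    # KN density in mu is maximal at mu = 1 where f = 2
    fmax = 2.0
    while True:
        mu = 2.0 * rng.random() - 1.0
        k = 1.0 / (1.0 + a * (1.0 - mu))
        f = k * k * (k + 1.0 / k - (1.0 - mu * mu))
        if rng.random() * fmax <= f:
            return mu


def compton_scatter(energy_kev: float, rng: np.random.Generator) -> tuple[float, float, float]:
    """(scattered energy, polar angle, deposited energy) for a Compton event."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    mu = sample_klein_nishina_mu(energy_kev, rng)
    e_out = compton_energy(energy_kev, math.acos(max(-1.0, min(1.0, mu))))
    return e_out, math.acos(max(-1.0, min(1.0, mu))), energy_kev - e_out


def compton_energy(energy_kev: float, theta: float) -> float:
    """Compton formula E' = E / (1 + (E/mc^2)(1 - cos theta))."""
    return energy_kev / (1.0 + (energy_kev / MEC2_KEV) * (1.0 - math.cos(theta)))


def sample_thomson_mu(rng: np.random.Generator) -> float:
    """cos(theta) ~ (1 + mu^2) (coherent-scatter angular law, unscreened)."""
    while True:
        mu = 2.0 * rng.random() - 1.0
        if rng.random() * 2.0 <= 1.0 + mu * mu:
            return mu


def rotate_direction(u: float, v: float, w: float, mu: float,
                     phi: float) -> tuple[float, float, float]:
    """New unit vector at polar angle acos(mu), azimuth phi, about (u,v,w)."""
    st = math.sqrt(max(0.0, 1.0 - mu * mu))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(w) > 0.999999:
        sgn = 1.0 if w > 0 else -1.0
        return st * cp, sgn * st * sp, sgn * mu
    s = math.sqrt(1.0 - w * w)
    nu = u * mu + st * (u * w * cp - v * sp) / s
    nv = v * mu + st * (v * w * cp + u * sp) / s
    nw = w * mu - st * s * cp
    n = math.sqrt(nu * nu + nv * nv + nw * nw)
    return nu / n, nv / n, nw / n


# ---------------------------------------------------------------------------
# Core single-photon tracker
# ---------------------------------------------------------------------------

@dataclass
class Balance:
    entered: float = 0.0
    deposited: float = 0.0
    escaped: float = 0.0


def transport_photon(scene: Scene, physics: PhysicsData, cfg: TransportConfig,
                     rng: np.random.Generator,
                     x: float, y: float, z: float,
                     u: float, v: float, w: float,
                     energy: float, weight: float,
                     balance: Balance,
                     dose_arr: np.ndarray | None = None,
                     grid: DoseGrid | None = None,
                     exit_records: list | None = None,
                     stop_on_water_entry: bool = False,
                     shell: "ShellTally | None" = None,
                     shell_arr: np.ndarray | None = None) -> None:
    """Track one photon (and its fluorescence descendants) to completion.

    ``exit_records`` collects (x, y, z, u, v, w, E, weight) at the photon's
    first transition from a device material into water (the scoring
    surface); with ``stop_on_water_entry`` tracking stops there.
    """
    stack = [(x, y, z, u, v, w, energy)]
    scored_exit = False
    tracklength = cfg.scoring == "tracklength" and dose_arr is not None
    all_channels = set(cfg.interactions) == {"pe", "incoh", "coh"}

    while stack:
        px, py, pz, du, dv, dw, e = stack.pop()
        alive = True
        while alive:
            segs = scene.trace((px, py, pz), (du, dv, dw))
            tau = -math.log(max(rng.random(), 1e-300))
            interacted = False
            prev_device = False
            for mat, t0, t1 in segs:
                if mat == "water" and prev_device and not scored_exit and exit_records is not None:
                    exit_records.append(
                        (px + t0 * du, py + t0 * dv, pz + t0 * dw, du, dv, dw, e, weight)
                    )
                    scored_exit = True
                    if stop_on_water_entry:
                        # the photon leaves the tracked system at the surface
                        balance.escaped += weight * e
                        alive = False
                        interacted = True
                        break
                prev_device = mat in DEVICE_MATERIALS
                if all_channels:
                    mu_lin = physics.mu_linear(mat, e)
                else:
                    pe_c, inc_c, coh_c = physics.mu_components(mat, e)
                    mu_lin = ((pe_c if "pe" in cfg.interactions else 0.0)
                              + (inc_c if "incoh" in cfg.interactions else 0.0)
                              + (coh_c if "coh" in cfg.interactions else 0.0))
                seg_len = t1 - t0
                if mu_lin <= 0.0:
                    continue
                s = tau / mu_lin
                travel = min(s, seg_len)
                if mat == "water" and (tracklength or shell is not None):
                    p0 = (px + t0 * du, py + t0 * dv, pz + t0 * dw)
                    p1 = (px + (t0 + travel) * du, py + (t0 + travel) * dv,
                          pz + (t0 + travel) * dw)
                    muen = physics.mu_en_over_rho("water", e)
                    if tracklength:
                        grid.score_track(dose_arr, p0, p1,
                                         weight * e * muen / grid.voxel_volume)
                    if shell is not None:
                        shell.score(shell_arr, p0, p1, weight * e * muen)
                if s >= seg_len:
                    tau -= mu_lin * seg_len
                    continue
                # interaction inside this segment
                t_int = t0 + s
                ix, iy, iz = px + t_int * du, py + t_int * dv, pz + t_int * dw
                interacted = True
                branch = sample_interaction(mat, e, physics, rng, cfg.interactions)
                if branch == "pe":
                    e_dep = e
                    if cfg.fluorescence and mat in FLUOR_ELEMENT:
                        el = FLUOR_ELEMENT[mat]
                        edge = K_EDGE_KEV[el]
                        if e > edge and rng.random() < fluorescence_yield_K(el):
                            lines = lines_for_shell(el, "K")
                            r = rng.random()
                            acc = 0.0
                            for ln in lines:
                                acc += ln.relative_intensity
                                if r <= acc:
                                    break
                            if ln.energy_kev >= cfg.cutoff_kev:
                                mu_iso = 2.0 * rng.random() - 1.0
                                phi = 2.0 * math.pi * rng.random()
                                st = math.sqrt(1.0 - mu_iso * mu_iso)
                                stack.append((ix, iy, iz, st * math.cos(phi),
                                              st * math.sin(phi), mu_iso,
                                              ln.energy_kev))
                                e_dep = e - ln.energy_kev
                    balance.deposited += weight * e_dep
                    if dose_arr is not None and not tracklength:
                        grid.deposit(dose_arr, ix, iy, iz,
                                     weight * e_dep / (WATER_RHO * grid.voxel_volume))
                    alive = False
                elif branch == "incoh":
                    mu_s = sample_klein_nishina_mu(e, rng)
                    e_new = e / (1.0 + (e / MEC2_KEV) * (1.0 - mu_s))
                    e_dep = e - e_new
                    phi = 2.0 * math.pi * rng.random()
                    du, dv, dw = rotate_direction(du, dv, dw, mu_s, phi)
                    if e_new < cfg.cutoff_kev:
                        e_dep = e  # photon absorbed with its residual energy
                        alive = False
                    else:
                        e = e_new
                    balance.deposited += weight * e_dep
                    if dose_arr is not None and not tracklength:
                        grid.deposit(dose_arr, ix, iy, iz,
                                     weight * e_dep / (WATER_RHO * grid.voxel_volume))
                else:  # coherent: direction change only
                    mu_s = sample_thomson_mu(rng)
                    phi = 2.0 * math.pi * rng.random()
                    du, dv, dw = rotate_direction(du, dv, dw, mu_s, phi)
                px, py, pz = ix, iy, iz
                break
            if not interacted:
                balance.escaped += weight * e
                alive = False


# ---------------------------------------------------------------------------
# Forward-cone spherical-shell kerma tally (desk-scale PDD estimator)
# ---------------------------------------------------------------------------

class ShellTally:
    """Kerma-to-water in spherical shells about the isocentre, restricted to
    a forward cone around +z.

    With the source's near-isotropic emission, the polar/azimuthal average
    inside a narrow forward cone estimates the central-axis depth dose while
    letting every photon contribute at every radius it crosses -- recovering
    smooth PDDs at desk-scale history counts where single-voxel tallies
    starve.  Scored like the track-length estimator (water segments only).
    """

    def __init__(self, r_edges, cone_half_angle_deg: float = 30.0,
                 step_cm: float = 0.02):
        self.r_edges = np.asarray(r_edges, float)
        if np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("shell edges must be ascending")
        self.cos_cone = math.cos(math.radians(cone_half_angle_deg))
        self.step_cm = step_cm
        n = len(self.r_edges) - 1
        # shell volume clipped to the solid cone
        self.volumes = (2.0 * math.pi / 3.0) * (1.0 - self.cos_cone) * (
            self.r_edges[1:] ** 3 - self.r_edges[:-1] ** 3
        )
        self.n_shells = n

    def new_array(self) -> np.ndarray:
        return np.zeros(self.n_shells)

    def score(self, arr: np.ndarray, p0, p1, value_per_cm: float) -> None:
        x0, y0, z0 = p0
        dx, dy, dz = p1[0] - x0, p1[1] - y0, p1[2] - z0
        length = math.sqrt(dx * dx + dy * dy + dz * dz)
        if length <= 0:
            return
        n = max(1, int(length / self.step_cm))
        t = (np.arange(n) + 0.5) * (length / n)
        xs = x0 + t * (dx / length)
        ys = y0 + t * (dy / length)
        zs = z0 + t * (dz / length)
        r = np.sqrt(xs * xs + ys * ys + zs * zs)
        ok = (r > 1e-9) & (zs / np.maximum(r, 1e-9) >= self.cos_cone)
        ok &= (r >= self.r_edges[0]) & (r < self.r_edges[-1])
        if not np.any(ok):
            return
        idx = np.searchsorted(self.r_edges, r[ok], side="right") - 1
        np.add.at(arr, idx, value_per_cm * (length / n))

    def dose(self, arr: np.ndarray) -> np.ndarray:
        return arr / self.volumes

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

@dataclass
class PointSource:
    """Isotropic monoenergetic point source (analytic-oracle runs)."""

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    energy_kev: float = 30.0
    n_histories: int = 10000

    def __len__(self):
        return self.n_histories

    def emit(self, i: int, rng: np.random.Generator):
        mu = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        st = math.sqrt(1.0 - mu * mu)
        x, y, z = self.position
        return (x, y, z, st * math.cos(phi), st * math.sin(phi), mu,
                self.energy_kev, 1.0)


# ---------------------------------------------------------------------------
# Batch runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    grid: DoseGrid | None
    exit_spectrum: "object | None"
    balance: Balance
    batch_doses: np.ndarray | None = None
    exit_records: list = field(default_factory=list)
    shell_tally: "ShellTally | None" = None
    shell_dose: np.ndarray | None = None
    shell_rel_unc: np.ndarray | None = None


def run(source, scene: Scene, config: TransportConfig, seed: int,
        grid: DoseGrid | None = None,
        physics: PhysicsData | None = None,
        collect_exit: bool = False,
        shell: "ShellTally | None" = None,
        spectrum_bin_kev: float = 0.2) -> RunResult:
    """Transport a phase space (or live source) through ``scene``.

    ``source`` is a :class:`PhaseSpaceFile`, a structured record array of
    the same dtype, or a :class:`PointSource`.  Histories are split into
    ``config.n_batches`` contiguous batches for the statistical-uncertainty
    estimate; the grid's ``rel_unc`` is filled at coverage
    ``config.coverage_k``.
    """
    physics = physics or default_physics()
    if grid is not None:
        grid.assert_inside(scene.bounds)
    rng = np.random.default_rng(seed)
    balance = Balance()
    exit_records: list = []

    if isinstance(source, PhaseSpaceFile):
        records = source.records
    elif isinstance(source, np.ndarray):
        records = source
    else:
        records = None

    n = len(records) if records is not None else len(source)
    nb = config.n_batches
    edges_idx = np.linspace(0, n, nb + 1).astype(int)
    batch_doses = (
        np.zeros((nb, *grid.shape)) if grid is not None else None
    )
    batch_shells = np.zeros((nb, shell.n_shells)) if shell is not None else None

    for b in range(nb):
        arr = batch_doses[b] if grid is not None else None
        sarr = batch_shells[b] if shell is not None else None
        for i in range(edges_idx[b], edges_idx[b + 1]):
            if records is not None:
                r = records[i]
                x, y, z, u, v, w, e, wt = (r["x"], r["y"], r["z"], r["u"],
                                           r["v"], r["w"], r["E_keV"], r["weight"])
            else:
                x, y, z, u, v, w, e, wt = source.emit(i, rng)
            balance.entered += wt * e
            transport_photon(
                scene, physics, config, rng, float(x), float(y), float(z),
                float(u), float(v), float(w), float(e), float(wt), balance,
                dose_arr=arr, grid=grid,
                exit_records=exit_records if collect_exit else None,
                shell=shell, shell_arr=sarr,
            )

    spectrum = None
    if collect_exit and exit_records:
        from .analysis import Spectrum

        arr = np.asarray(exit_records)
        spectrum = Spectrum.from_energies(
            arr[:, 6], weights=arr[:, 7], bin_kev=spectrum_bin_kev,
            provenance="applicator surface" if scene.applicator else "probe surface",
        )

    if grid is not None:
        grid.dose = batch_doses.mean(axis=0)
        grid.rel_unc = estimate_uncertainty(batch_doses, config.coverage_k)
        grid.coverage_k = config.coverage_k

    shell_dose = shell_rel = None
    if shell is not None:
        per_batch = batch_shells / shell.volumes  # dose per batch
        shell_dose = per_batch.mean(axis=0)
        shell_rel = estimate_uncertainty(per_batch, config.coverage_k)

    return RunResult(grid=grid, exit_spectrum=spectrum, balance=balance,
                     batch_doses=batch_doses, exit_records=exit_records,
                     shell_tally=shell, shell_dose=shell_dose,
                     shell_rel_unc=shell_rel)


def estimate_uncertainty(batch_doses: np.ndarray, k: float = 1.0) -> np.ndarray:
    """Per-voxel relative uncertainty: k x (standard error of the batch
    mean) / mean.  Zero-dose voxels are flagged with NaN, never divided."""
    batch_doses = np.asarray(batch_doses)
    if batch_doses.shape[0] < 2:
        raise ValueError("need at least 2 batches")
    mean = batch_doses.mean(axis=0)
    sem = batch_doses.std(axis=0, ddof=1) / math.sqrt(batch_doses.shape[0])
    out = np.full(mean.shape, np.nan)
    nz = mean > 0
    out[nz] = k * sem[nz] / mean[nz]
    return out
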