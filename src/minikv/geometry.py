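"""Probe, spherical-applicator and water-phantom geometry with ray tracing.

Coordinates are right-handed with z along the probe axis pointing distally
(out of the tip) and all lengths in cm.  The origin is the device isocentre:
the centre of the gold hemisphere for bare-probe scenes, the applicator ball
centre for applicator scenes (the probe isocentre is registered to the ball
centre by default).

``Scene.path_segments`` returns the ordered material path a ray traverses up
to the phantom boundary.  It works by collecting the parametric distances of
the ray's intersections with every bounding surface in the scene and
classifying the midpoint of each resulting interval with ``region_at``; the
two are therefore consistent by construction.  Points exactly on an
interface resolve to the outer region (strict inequalities on the inner
side), with a geometric epsilon of 1e-7 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

EPS = 1e-7

APPLICATOR_DIAMETERS = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class ProbeGeometry:
    """Layered x-ray probe: evacuated tube, gold target, Be window, coatings.

    The tip is a hemisphere (z >= 0) whose layers from inside out are
    vacuum | Au target | Be window | NiO | Ni | CrN.  The distal 1.6 cm of
    the cylindrical body carries the Be exit window; the proximal 8.4 cm
    wall is mu-metal.  All three coatings cover the whole exterior.
    """

    outer_radius: float = 0.16075
    body_length: float = 10.0
    window_length: float = 1.6
    au_thickness: float = 1e-4  # 1 um
    wall_thickness: float = 0.05  # 500 um (Be window and mu-metal alike)
    coating_thickness: float = 2.5e-4  # 2.5 um each of NiO, Ni, CrN

    def __post_init__(self):
        for t in (self.au_thickness, self.wall_thickness, self.coating_thickness):
            if t <= 0:
                raise ValueError("layer thicknesses must be positive")

    @property
    def radii(self) -> tuple[float, ...]:
        """(r_vac, r_au, r_wall, r_nio, r_ni, r_crn=outer) boundary radii."""
        r5 = self.outer_radius
        r4 = r5 - self.coating_thickness
        r3 = r4 - self.coating_thickness
        r2 = r3 - self.coating_thickness
        r1 = r2 - self.wall_thickness
        r0 = r1 - self.au_thickness
        return (r0, r1, r2, r3, r4, r5)


def default_shell_cm(diameter_cm: float) -> float:
    """Shell-thickness policy: 0.25 cm for the Al-filtered (<= 3 cm)
    applicators; near-solid balls with a fixed 0.45 cm air cavity above."""
    if diameter_cm <= 3.0:
        return 0.25
    return diameter_cm / 2.0 - 0.45


@dataclass(frozen=True)
class ApplicatorGeometry:
    """Spherical ULTEM applicator: ball + shank, optional inner Al layer."""

    diameter_cm: float
    shell_cm: float | None = None
    al_cm: float | None = None
    # shank defaults (backscatter-only influence): probe air channel, neck,
    # cone flare and wide cylinder radii/lengths
    channel_radius: float = 0.2
    neck_radius: float = 0.4
    neck_length: float = 1.5
    cone_length: float = 2.0
    wide_radius: float = 0.7

    def __post_init__(self):
        if self.diameter_cm not in APPLICATOR_DIAMETERS:
            raise ValueError(
                f"diameter must be one of {APPLICATOR_DIAMETERS}, "
                f"got {self.diameter_cm}"
            )
        if self.shell_cm is None:
            object.__setattr__(self, "shell_cm", default_shell_cm(self.diameter_cm))
        if self.al_cm is None:
            object.__setattr__(
                self, "al_cm", 0.1 if self.has_aluminium_filter else 0.0
            )
        if self.cavity_radius <= ProbeGeometry().outer_radius:
            raise ValueError("ball cavity does not clear the probe")

    @property
    def has_aluminium_filter(self) -> bool:
        return self.diameter_cm <= 3.0

    @property
    def ball_radius(self) -> float:
        return self.diameter_cm / 2.0

    @property
    def cavity_radius(self) -> float:
        return self.ball_radius - self.shell_cm - self.al_cm

    @property
    def attach_z(self) -> float:
        """z of the ball/shank attachment plane (negative side)."""
        return -math.sqrt(self.ball_radius**2 - self.neck_radius**2)


def has_aluminium_filter(applicator: ApplicatorGeometry) -> bool:
    """True iff the applicator diameter is <= 3 cm."""
    return applicator.has_aluminium_filter


@dataclass
class Scene:
    """Device (optional) inside a rectangular water phantom.

    ``bounds`` is (xlo, xhi, ylo, yhi, zlo, zhi); the default 30 x 20 x 30 cm
    box is centred on the device axis with the isocentre 12 cm from the
    proximal face.
    """

    probe: ProbeGeometry | None = None
    applicator: ApplicatorGeometry | None = None
    bounds: tuple[float, float, float, float, float, float] = (
        -15.0, 15.0, -10.0, 10.0, -12.0, 18.0,
    )
    _surfaces: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.applicator is not None and self.probe is None:
            self.probe = ProbeGeometry()
        self._build_surfaces()

    # -- classification ----------------------------------------------------

    def inside_box(self, x: float, y: float, z: float) -> bool:
        xlo, xhi, ylo, yhi, zlo, zhi = self.bounds
        return xlo <= x <= xhi and ylo <= y <= yhi and zlo <= z <= zhi

    def region_at(self, point) -> str:
        x, y, z = point
        if not self.inside_box(x, y, z):
            raise ValueError(f"point {point} outside the phantom box")
        m = self._probe_region(x, y, z)
        if m is not None:
            return m
        if self.applicator is not None:
            m = self._applicator_region(x, y, z)
            if m is not None:
                return m
        return "water"

    def _probe_region(self, x: float, y: float, z: float) -> str | None:
        p = self.probe
        if p is None:
            return None
        r0, r1, r2, r3, r4, r5 = p.radii
        if z >= 0.0:
            r = math.sqrt(x * x + y * y + z * z)
            if r >= r5:
                return None
            if r < r0:
                return "vacuum"
            if r < r1:
                return "Au"
            if r < r2:
                return "Be"
            if r < r3:
                return "NiO"
            if r < r4:
                return "Ni"
            return "CrN"
        if z < -p.body_length:
            return None
        rc = math.hypot(x, y)
        if rc >= r5:
            return None
        if rc < r1:
            return "vacuum"
        if rc < r2:
            return "Be" if z >= -p.window_length else "mu-metal"
        if rc < r3:
            return "NiO"
        if rc < r4:
            return "Ni"
        return "CrN"

    def _applicator_region(self, x: float, y: float, z: float) -> str | None:
        a = self.applicator
        rc = math.hypot(x, y)
        if z < 0.0 and rc < a.channel_radius and z >= -a.ball_radius:
            # probe insertion channel through the ball's proximal cap
            if x * x + y * y + z * z >= a.cavity_radius**2:
                return "air"
        r2 = x * x + y * y + z * z
        if r2 < a.ball_radius**2:
            if r2 < a.cavity_radius**2:
                return "air"
            if a.al_cm > 0 and r2 < (a.cavity_radius + a.al_cm) ** 2:
                return "Al"
            return "ULTEM"
        # shank, proximal of the attachment plane
        z0 = a.attach_z
        if z <= z0:
            if rc < a.channel_radius:
                return "air" if z >= -self.probe.body_length else None
            z1 = z0 - a.neck_length
            z2 = z1 - a.cone_length
            if z >= z1:
                return "ULTEM" if rc < a.neck_radius else None
            if z >= z2:
                rcone = a.neck_radius + (a.wide_radius - a.neck_radius) * (z1 - z) / a.cone_length
                return "ULTEM" if rc < rcone else None
            if z >= -self.probe.body_length:
                return "ULTEM" if rc < a.wide_radius else None
        return None

    # -- surfaces and tracing ---------------------------------------------

    def _build_surfaces(self):
        s: list[tuple] = []
        if self.probe is not None:
            p = self.probe
            for r in p.radii:
                s.append(("sphere", r * r))
                s.append(("cyl", r * r))
            for z in (0.0, -p.window_length, -p.body_length):
                s.append(("plane", z))
        if self.applicator is not None:
            a = self.applicator
            for r in (a.cavity_radius, a.cavity_radius + a.al_cm, a.ball_radius):
                if r > 0:
                    s.append(("sphere", r * r))
            for r in (a.channel_radius, a.neck_radius, a.wide_radius):
                s.append(("cyl", r * r))
            z0 = a.attach_z
            z1 = z0 - a.neck_length
            z2 = z1 - a.cone_length
            for z in (z0, z1, z2):
                s.append(("plane", z))
            k = (a.wide_radius - a.neck_radius) / a.cone_length
            # cone radius = neck_radius + k (z1 - z) -> (a + b z) with
            s.append(("cone", a.neck_radius + k * z1, -k))
        self._surfaces = s

    def _box_exit(self, ox, oy, oz, ux, uy, uz) -> float:
        xlo, xhi, ylo, yhi, zlo, zhi = self.bounds
        t = math.inf
        for o, u, lo, hi in ((ox, ux, xlo, xhi), (oy, uy, ylo, yhi), (oz, uz, zlo, zhi)):
            if u > EPS:
                t = min(t, (hi - o) / u)
            elif u < -EPS:
                t = min(t, (lo - o) / u)
        return t

    def _candidate_ts(self, ox, oy, oz, ux, uy, uz, tmax: float) -> list[float]:
        ts = []
        oo_c = ox * ox + oy * oy
        ou_c = ox * ux + oy * uy
        uu_c = ux * ux + uy * uy
        oo_s = oo_c + oz * oz
        ou_s = ou_c + oz * uz
        for surf in self._surfaces:
            kind = surf[0]
            if kind == "sphere":
                r2 = surf[1]
                disc = ou_s * ou_s - (oo_s - r2)
                if disc > 0:
                    rt = math.sqrt(disc)
                    ts.append(-ou_s - rt)
                    ts.append(-ou_s + rt)
            elif kind == "cyl":
                r2 = surf[1]
                if uu_c > 1e-16:
                    disc = ou_c * ou_c - uu_c * (oo_c - r2)
                    if disc > 0:
                        rt = math.sqrt(disc)
                        ts.append((-ou_c - rt) / uu_c)
                        ts.append((-ou_c + rt) / uu_c)
            elif kind == "plane":
                if abs(uz) > 1e-16:
                    ts.append((surf[1] - oz) / uz)
            else:  # cone: x^2 + y^2 = (a + b z)^2
                a, b = surf[1], surf[2]
                g = a + b * oz
                qa = uu_c - b * b * uz * uz
                qb = ou_c - b * uz * g
                qc = oo_c - g * g
                if abs(qa) > 1e-16:
                    disc = qb * qb - qa * qc
                    if disc > 0:
                        rt = math.sqrt(disc)
                        ts.append((-qb - rt) / qa)
                        ts.append((-qb + rt) / qa)
                elif abs(qb) > 1e-16:
                    ts.append(-0.5 * qc / qb)
        return sorted(t for t in ts if EPS < t < tmax - EPS)

    def trace(self, origin, direction) -> list[tuple[str, float, float]]:
        """Ordered (material, t_enter, t_exit) intervals to the box exit."""
        ox, oy, oz = map(float, origin)
        ux, uy, uz = map(float, direction)
        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not self.inside_box(ox, oy, oz):
            raise ValueError("ray origin outside the phantom box")
        t_exit = self._box_exit(ox, oy, oz, ux, uy, uz)
        ts = [0.0] + self._candidate_ts(ox, oy, oz, ux, uy, uz, t_exit) + [t_exit]
        out: list[tuple[str, float, float]] = []
        for i in range(len(ts) - 1):
            t0, t1 = ts[i], ts[i + 1]
            if t1 - t0 <= EPS * 0.1:
                continue
            tm = 0.5 * (t0 + t1)
            m = self.region_at((ox + tm * ux, oy + tm * uy, oz + tm * uz))
            if out and out[-1][0] == m:
                out[-1] = (m, out[-1][1], t1)
            else:
                out.append((m, t0, t1))
        return out

    def path_segments(self, origin, direction) -> list[tuple[str, float]]:
        """Ordered (material, length) segments from origin to the box wall."""
        return [(m, t1 - t0) for m, t0, t1 in self.trace(origin, direction)]


def bare_probe_scene(**kwargs) -> Scene:
    return Scene(probe=ProbeGeometry(), **kwargs)


def applicator_scene(diameter_cm: float, *, shell_cm: float | None = None,
                     al_cm: float | None = None, **kwargs) -> Scene:
    app = ApplicatorGeometry(diameter_cm, shell_cm=shell_cm, al_cm=al_cm)
    return Scene(probe=ProbeGeometry(), applicator=app, **kwargs)


def water_scene(**kwargs) -> Scene:
    """Device-free water box (for analytic-oracle point-source runs)."""
    return Scene(probe=None, applicator=None, **kwargs)
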