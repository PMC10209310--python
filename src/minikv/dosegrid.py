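"""Voxelised dose grid with batch statistics and EGSnrc ``.3ddose`` text IO.

Dose is stored in arbitrary units per history (energy per unit mass of
water); all downstream quantities (PDD, isodose) are relative, so no
absolute calibration is applied.  The ``.3ddose`` layout is the EGSnrc text
format: voxel counts, the three boundary lists, the dose block and the
relative-error block, with x varying fastest.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

DEFAULT_VOXEL_CM = (0.16, 0.16, 0.1)


class DoseGrid:
    """Rectilinear dose grid: uniform voxels defined by origin/size/shape."""

    def __init__(self, origin: tuple[float, float, float],
                 voxel_cm: tuple[float, float, float],
                 shape: tuple[int, int, int]):
        self.origin = tuple(float(v) for v in origin)
        self.voxel_cm = tuple(float(v) for v in voxel_cm)
        self.shape = tuple(int(n) for n in shape)
        self.dose = np.zeros(self.shape)
        self.rel_unc = np.full(self.shape, np.nan)
        self.coverage_k = 1.0

    @classmethod
    def from_extents(cls, x, y, z, voxel_cm=DEFAULT_VOXEL_CM) -> "DoseGrid":
        """Build a grid covering [x0,x1] x [y0,y1] x [z0,z1] (whole voxels)."""
        spans = (x, y, z)
        shape = [max(1, round((hi - lo) / v)) for (lo, hi), v in zip(spans, voxel_cm)]
        origin = tuple(lo for lo, _ in spans)
        return cls(origin, voxel_cm, tuple(shape))

    # -- geometry helpers ---------------------------------------------------

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(o + n * v for o, v, n in zip(self.origin, self.voxel_cm, self.shape))

    def edges(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_cm[axis] * np.arange(self.shape[axis] + 1)

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel_cm[axis] * (np.arange(self.shape[axis]) + 0.5)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_cm[0] * self.voxel_cm[1] * self.voxel_cm[2]

    def contains(self, x: float, y: float, z: float) -> bool:
        (x0, y0, z0), (x1, y1, z1) = self.origin, self.upper
        return x0 <= x < x1 and y0 <= y < y1 and z0 <= z < z1

    def voxel_index(self, x: float, y: float, z: float):
        if not self.contains(x, y, z):
            return None
        return tuple(
            min(int((c - o) / v), n - 1)
            for c, o, v, n in zip((x, y, z), self.origin, self.voxel_cm, self.shape)
        )

    def assert_inside(self, bounds) -> None:
        xlo, xhi, ylo, yhi, zlo, zhi = bounds
        (x0, y0, z0), (x1, y1, z1) = self.origin, self.upper
        if not (xlo <= x0 and x1 <= xhi and ylo <= y0 and y1 <= yhi
                and zlo <= z0 and z1 <= zhi):
            raise ValueError("scoring grid extends outside the phantom")

    # -- scoring ------------------------------------------------------------

    def deposit(self, arr: np.ndarray, x: float, y: float, z: float,
                value: float) -> None:
        idx = self.voxel_index(x, y, z)
        if idx is not None:
            arr[idx] += value

    def score_track(self, arr: np.ndarray, p0, p1, value_per_cm: float) -> None:
        """Add ``value_per_cm * (path length in voxel)`` along segment p0-p1.

        3D amanatides-woo style traversal; segments fully outside the grid
        are clipped first.
        """
        x0, y0, z0 = p0
        dx, dy, dz = (p1[0] - x0, p1[1] - y0, p1[2] - z0)
        seg_len = math.sqrt(dx * dx + dy * dy + dz * dz)
        if seg_len <= 0:
            return
        ux, uy, uz = dx / seg_len, dy / seg_len, dz / seg_len
        # clip [t0, t1] to the grid box
        t0, t1 = 0.0, seg_len
        for o, u, lo, hi in (
            (x0, ux, self.origin[0], self.upper[0]),
            (y0, uy, self.origin[1], self.upper[1]),
            (z0, uz, self.origin[2], self.upper[2]),
        ):
            if abs(u) < 1e-14:
                if not (lo <= o < hi):
                    return
                continue
            ta, tb = (lo - o) / u, (hi - o) / u
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
        if t1 <= t0:
            return
        eps = 1e-9
        t = t0 + eps
        px, py, pz = x0 + t * ux, y0 + t * uy, z0 + t * uz
        idx = self.voxel_index(px, py, pz)
        if idx is None:
            return
        ix, iy, iz = idx
        vx, vy, vz = self.voxel_cm
        while t < t1 - eps:
            # distance to next boundary on each axis
            tn = t1
            step = None
            if ux > 0:
                cand = t0 + ((self.origin[0] + (ix + 1) * vx) - (x0 + t0 * ux)) / ux
                if cand < tn:
                    tn, step = cand, (1, 0, 0)
            elif ux < 0:
                cand = t0 + ((self.origin[0] + ix * vx) - (x0 + t0 * ux)) / ux
                if cand < tn:
                    tn, step = cand, (-1, 0, 0)
            if uy > 0:
                cand = t0 + ((self.origin[1] + (iy + 1) * vy) - (y0 + t0 * uy)) / uy
                if cand < tn:
                    tn, step = cand, (0, 1, 0)
            elif uy < 0:
                cand = t0 + ((self.origin[1] + iy * vy) - (y0 + t0 * uy)) / uy
                if cand < tn:
                    tn, step = cand, (0, -1, 0)
            if uz > 0:
                cand = t0 + ((self.origin[2] + (iz + 1) * vz) - (z0 + t0 * uz)) / uz
                if cand < tn:
                    tn, step = cand, (0, 0, 1)
            elif uz < 0:
                cand = t0 + ((self.origin[2] + iz * vz) - (z0 + t0 * uz)) / uz
                if cand < tn:
                    tn, step = cand, (0, 0, -1)
            tn = min(tn, t1)
            if tn > t:
                arr[ix, iy, iz] += value_per_cm * (tn - t)
            if step is None or tn >= t1 - eps:
                break
            ix, iy, iz = ix + step[0], iy + step[1], iz + step[2]
            if not (0 <= ix < self.shape[0] and 0 <= iy < self.shape[1]
                    and 0 <= iz < self.shape[2]):
                break
            t = tn + eps

    # -- .3ddose ------------------------------------------------------------

    def write_3ddose(self, path: str | Path) -> None:
        nx, ny, nz = self.shape
        parts = [f"{nx} {ny} {nz}"]
        for ax in range(3):
            parts.append(" ".join(f"{e:.6f}" for e in self.edges(ax)))
        # x fastest: transpose to (z, y, x) then ravel
        dose = self.dose.transpose(2, 1, 0).ravel()
        err = np.nan_to_num(self.rel_unc, nan=0.0).transpose(2, 1, 0).ravel()
        parts.append(" ".join(f"{v:.8e}" for v in dose))
        parts.append(" ".join(f"{v:.6e}" for v in err))
        Path(path).write_text("\n".join(parts) + "\n")

    @classmethod
    def read_3ddose(cls, path: str | Path) -> "DoseGrid":
        tokens = Path(path).read_text().split()
        it = iter(tokens)
        nx, ny, nz = (int(next(it)) for _ in range(3))
        bx = np.array([float(next(it)) for _ in range(nx + 1)])
        by = np.array([float(next(it)) for _ in range(ny + 1)])
        bz = np.array([float(next(it)) for _ in range(nz + 1)])
        grid = cls(
            (bx[0], by[0], bz[0]),
            ((bx[-1] - bx[0]) / nx, (by[-1] - by[0]) / ny, (bz[-1] - bz[0]) / nz),
            (nx, ny, nz),
        )
        dose = np.array([float(next(it)) for _ in range(nx * ny * nz)])
        grid.dose = dose.reshape(nz, ny, nx).transpose(2, 1, 0)
        err = [float(t) for t in it]
        if len(err) == nx * ny * nz:
            grid.rel_unc = np.asarray(err).reshape(nz, ny, nx).transpose(2, 1, 0)
        return grid
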