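"""Phase-space records and an exact-round-trip text file format.

A phase space is the set of photon states scored while crossing a surface
(here the outer probe surface); stored to disk it acts as a reusable
virtual source for downstream applicator and dose runs.  The file dialect
is a commented CSV: ``#`` header lines carrying format version, device
configuration hash, history count and RNG seed, then one row per record
with columns ``x,y,z,u,v,w,E_keV,weight,history``.  Floats are written with
17 significant digits so that ``read(write(x)) == x`` exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1
_FIELDS = ["x", "y", "z", "u", "v", "w", "E_keV", "weight", "history"]


@dataclass(frozen=True)
class PhaseSpaceRecord:
    """One photon crossing the scoring surface."""

    x: float
    y: float
    z: float
    u: float
    v: float
    w: float
    energy_kev: float
    weight: float = 1.0
    history: int = 0

    def __post_init__(self):
        n = (self.u**2 + self.v**2 + self.w**2) ** 0.5
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must have unit norm")
        if self.energy_kev < 1.0:
            raise ValueError("photon energy below the 1 keV cutoff")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


class PhaseSpaceFile:
    """Header + record block; records held as a structured numpy array."""

    def __init__(self, records: np.ndarray, *, device_hash: str = "",
                 n_histories: int = 0, seed: int | None = None):
        self.records = np.asarray(records)
        self.device_hash = device_hash
        self.n_histories = int(n_histories)
        self.seed = seed

    @staticmethod
    def dtype() -> np.dtype:
        return np.dtype([(f, np.int64 if f == "history" else np.float64)
                         for f in _FIELDS])

    @classmethod
    def from_records(cls, recs: list[PhaseSpaceRecord], **kw) -> "PhaseSpaceFile":
        arr = np.zeros(len(recs), dtype=cls.dtype())
        for i, r in enumerate(recs):
            arr[i] = (r.x, r.y, r.z, r.u, r.v, r.w, r.energy_kev, r.weight, r.history)
        return cls(arr, **kw)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def energies(self) -> np.ndarray:
        return self.records["E_keV"]

    @property
    def weights(self) -> np.ndarray:
        return self.records["weight"]

    def write(self, path: str | Path) -> None:
        lines = [
            f"# minikv-phsp {FORMAT_VERSION}",
            f"# device: {self.device_hash}",
            f"# n_histories: {self.n_histories}",
            f"# seed: {self.seed if self.seed is not None else ''}",
            ",".join(_FIELDS),
        ]
        for r in self.records:
            vals = [f"{r[f]:d}" if f == "history" else f"{r[f]:.17g}"
                    for f in _FIELDS]
            lines.append(",".join(vals))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PhaseSpaceFile":
        lines = Path(path).read_text().strip().splitlines()
        if not lines[0].startswith(f"# minikv-phsp {FORMAT_VERSION}"):
            raise ValueError("not a minikv phase-space file (or wrong version)")
        device_hash = lines[1].split(":", 1)[1].strip()
        n_hist = int(lines[2].split(":", 1)[1])
        seed_s = lines[3].split(":", 1)[1].strip()
        seed = int(seed_s) if seed_s else None
        assert lines[4] == ",".join(_FIELDS)
        arr = np.zeros(len(lines) - 5, dtype=cls.dtype())
        for i, line in enumerate(lines[5:]):
            parts = line.split(",")
            arr[i] = tuple(
                int(p) if f == "history" else float(p)
                for f, p in zip(_FIELDS, parts)
            )
        return cls(arr, device_hash=device_hash, n_histories=n_hist, seed=seed)


def device_hash(*objects) -> str:
    """Short stable hash of device-configuration dataclass reprs."""
    h = hashlib.sha256("|".join(repr(o) for o in objects).encode())
    return h.hexdigest()[:12]
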