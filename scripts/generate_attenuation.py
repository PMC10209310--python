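"""Regenerate the shipped attenuation table from the semi-empirical model.

Usage:  python scripts/generate_attenuation.py [out.csv]

Writes per-material photon mass coefficients (photoelectric, incoherent,
coherent, total, energy absorption; cm^2/g) on a 1-200 keV log grid with
points straddling every absorption edge of the material's constituents.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from minikv import _xsmodel as xs
from minikv.materials import REGISTRY

EXTRA_POINTS = [2, 5, 10, 15, 20, 30, 40, 50, 100, 150]


def energy_grid(composition: dict[str, float]) -> np.ndarray:
    e = list(np.geomspace(1.0, 200.0, 64)) + EXTRA_POINTS
    for el in composition:
        for edge, _ in xs._EDGES.get(el, []):
            e += [edge * (1 - 1e-4), edge * (1 + 1e-4)]
    return np.unique(np.asarray(sorted(e)))


def main(out: str) -> None:
    rows = ["material,energy_keV,pe,incoh,coh,total,mu_en"]
    for name, mat in REGISTRY.items():
        if name == "vacuum":
            continue
        for e in energy_grid(mat.composition):
            pe, inc, coh, mu_en = xs.material_coefficients(mat.composition, float(e))
            rows.append(
                f"{name},{e:.6g},{pe:.6g},{inc:.6g},{coh:.6g},"
                f"{pe + inc + coh:.6g},{mu_en:.6g}"
            )
    Path(out).write_text("\n".join(rows) + "\n")
    print(f"wrote {len(rows) - 1} rows to {out}")


if __name__ == "__main__":
    out = sys.argv[1] if len(sys.argv) > 1 else str(
        Path(__file__).resolve().parents[1] / "src" / "minikv" / "data" / "attenuation.csv"
    )
    main(out)
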