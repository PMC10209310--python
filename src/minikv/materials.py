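"""Material registry for the probe / applicator / phantom model.

Densities in g/cm^3, compositions as element mass fractions.  ``vacuum`` is
a registered pseudo-material with zero density and no composition; the
attenuation machinery treats it as perfectly transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Material:
    """A named medium with density and elemental mass-fraction composition."""

    name: str
    density: float
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name != "vacuum":
            if self.density <= 0:
                raise ValueError(f"density must be > 0 for {self.name!r}")
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"mass fractions of {self.name!r} sum to {total}, not 1"
                )


# GE ULTEM 1000 polyetherimide, C37 H24 O6 N2 (1.27 g/cm^3)
_ULTEM_M = 37 * 12.011 + 24 * 1.008 + 6 * 15.999 + 2 * 14.007
_ULTEM = {
    "C": 37 * 12.011 / _ULTEM_M,
    "H": 24 * 1.008 / _ULTEM_M,
    "O": 6 * 15.999 / _ULTEM_M,
    "N": 2 * 14.007 / _ULTEM_M,
}

REGISTRY: dict[str, Material] = {
    m.name: m
    for m in [
        Material("vacuum", 0.0, {}),
        Material("water", 0.998, {"H": 0.1119, "O": 0.8881}),
        Material(
            "air", 1.2041e-3, {"N": 0.7551, "O": 0.2318, "Ar": 0.0129, "C": 0.0002}
        ),
        Material("Be", 1.848, {"Be": 1.0}),
        Material("Al", 2.699, {"Al": 1.0}),
        Material("Au", 19.32, {"Au": 1.0}),
        Material("Ni", 8.908, {"Ni": 1.0}),
        # NiO and CrN as compounds; standard handbook densities
        Material("NiO", 6.67, {"Ni": 0.785, "O": 0.215}),
        Material("CrN", 5.90, {"Cr": 0.788, "N": 0.212}),
        # mu-metal: soft magnetic Ni/Fe/Cu/Mo alloy (nominal composition)
        Material("mu-metal", 8.7, {"Ni": 0.77, "Fe": 0.16, "Cu": 0.05, "Mo": 0.02}),
        Material("ULTEM", 1.27, _ULTEM),
    ]
}


def get_material(name: str) -> Material:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}") from None
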