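"""Tissue materials: density and elemental mass fractions.

The organ compositions mirror the segmented adult-male voxel phantom
tissues relevant near a respiratory-tract source (lung/respiratory system
at 0.26 g/cc, heart wall, liver, thyroid, bone, muscle); fat, skin, air
and water are standard reference compositions.  Mass fractions sum to
1 ± 0.001 per material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Material", "ELEMENTS", "BUILTIN_MATERIALS", "material"]

#: element symbol -> (Z, standard atomic weight)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
    "I": (53, 126.904),
    "U": (92, 238.029),
}


@dataclass(frozen=True)
class Material:
    name: str
    density_g_cc: float
    mass_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density_g_cc <= 0:
            raise ValueError("density must be positive")
        unknown = set(self.mass_fractions) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements {unknown}")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1.5e-3:
            raise ValueError(f"mass fractions of {self.name} sum to {total:.4f}, not 1")

    def electrons_per_gram(self) -> float:
        """N_A Σ w_i Z_i / A_i."""
        na = 6.02214076e23
        return na * sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in self.mass_fractions.items())

    def effective_sqrt_A(self) -> float:
        """Bragg–Kleeman effective √A: (Σ w_i/√A_i)⁻¹."""
        return 1.0 / sum(w / ELEMENTS[el][1] ** 0.5 for el, w in self.mass_fractions.items())


BUILTIN_MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("lung_respiratory", 0.26, {
            "H": 0.103, "O": 0.749, "S": 0.003, "C": 0.105, "Na": 0.002,
            "Cl": 0.003, "N": 0.031, "P": 0.002, "K": 0.002,
        }),
        Material("heart_wall", 1.03, {
            "H": 0.103, "O": 0.734, "S": 0.002, "C": 0.121, "Na": 0.001,
            "Cl": 0.003, "N": 0.032, "P": 0.001, "K": 0.002, "Fe": 0.001,
        }),
        Material("liver", 1.05, {
            "H": 0.102, "O": 0.716, "S": 0.003, "C": 0.139, "Na": 0.002,
            "Cl": 0.002, "N": 0.030, "P": 0.003, "K": 0.003,
        }),
        Material("thyroid", 1.05, {
            "H": 0.104, "O": 0.745, "S": 0.001, "C": 0.119, "Na": 0.002,
            "Cl": 0.002, "N": 0.024, "P": 0.001, "I": 0.001,
        }),
        Material("bone", 1.55, {
            "H": 0.034, "O": 0.435, "P": 0.103, "C": 0.155, "Na": 0.001,
            "S": 0.003, "N": 0.042, "Mg": 0.002, "Ca": 0.225,
        }),
        Material("muscle", 1.04, {
            "H": 0.102, "O": 0.710, "S": 0.003, "C": 0.143, "Na": 0.001,
            "Cl": 0.001, "N": 0.034, "P": 0.002, "K": 0.004,
        }),
        Material("adipose", 0.95, {
            "H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
            "S": 0.001, "Cl": 0.001,
        }),
        Material("skin", 1.09, {
            "H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "Na": 0.002,
            "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.001,
        }),
        Material("air", 1.2e-3, {"N": 0.768, "O": 0.232}),
        Material("water", 1.0, {"H": 0.1119, "O": 0.8881}),
        Material("uo2", 10.97, {"U": 0.8815, "O": 0.1185}),
    ]
}


def material(name: str) -> Material:
    try:
        return BUILTIN_MATERIALS[name]
    except KeyError:
        raise KeyError(f"no builtin material {name!r}") from None
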