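"""Radionuclide emission library and beta-spectrum construction.

The built-in library covers the airborne fission/activation products of
interest after a reactor release — ``I-131``, ``Cs-134``, ``Cs-137``,
``Ru-103``, the secular-equilibrium pair ``Sr-90/Y-90`` and the alpha
emitter ``Pu-239/240`` — with discrete gamma/x-ray/alpha lines (energy and
emissions per decay) and beta-minus branch data (endpoint energy, branch
probability, daughter proton number).

Beta spectra are built from allowed-shape Fermi theory,

    N(E) dE  ∝  p · E_tot · (Q − E)^2 · F(Z, E) dE,

where ``p`` and ``E_tot`` are the electron momentum and total energy and
``F`` is the nonrelativistic Fermi Coulomb correction
``F(Z,E) = 2πη / (1 − exp(−2πη))`` with ``η = +Z α / β`` for β⁻ decay.
Branches are summed with their branch probabilities and the result is
normalised to unit integral over ``[0, Q_max]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "EmissionLine",
    "BetaBranch",
    "BetaSpectrum",
    "Nuclide",
    "load_builtin_library",
    "lookup",
    "photon_energy_per_decay",
    "build_beta_spectrum",
    "mean_beta_energy_per_decay",
    "sample_emission",
]

ELECTRON_MASS_KEV = 510.99895
FINE_STRUCTURE = 1.0 / 137.035999

_PHOTON_KINDS = ("gamma", "xray")


@dataclass(frozen=True)
class EmissionLine:
    """A discrete emission: energy in keV, yield in emissions per decay."""

    energy_keV: float
    yield_per_decay: float
    kind: str  # gamma | xray | alpha

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError("emission line energy must be positive")
        if not 0 < self.yield_per_decay <= 1.0001:
            raise ValueError("line yield must lie in (0, 1] per decay")
        if self.kind not in ("gamma", "xray", "alpha"):
            raise ValueError(f"unknown emission kind {self.kind!r}")


@dataclass(frozen=True)
class BetaBranch:
    """A beta-minus branch: endpoint (Q) keV, emission probability, daughter Z."""

    endpoint_keV: float
    fraction: float
    daughter_Z: int

    def __post_init__(self) -> None:
        if self.endpoint_keV <= 0:
            raise ValueError("beta endpoint must be positive")
        if not 0 < self.fraction <= 1:
            raise ValueError("branch fraction must lie in (0, 1]")


@dataclass
class BetaSpectrum:
    """Tabulated beta spectrum: probability density per keV on [0, Q_max]."""

    energy_keV: np.ndarray  # monotone ascending grid, 0 .. Q_max
    density: np.ndarray  # probability per keV, trapezoid-normalised to 1

    def __post_init__(self) -> None:
        self.energy_keV = np.asarray(self.energy_keV, float)
        self.density = np.asarray(self.density, float)
        if np.any(np.diff(self.energy_keV) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")

    @property
    def q_max_keV(self) -> float:
        return float(self.energy_keV[-1])

    def mean_energy_keV(self) -> float:
        """Mean beta energy per emission, by trapezoid quadrature."""
        return float(np.trapezoid(self.energy_keV * self.density, self.energy_keV))

    def cdf(self) -> np.ndarray:
        """Trapezoid cumulative distribution on the energy grid."""
        e, f = self.energy_keV, self.density
        c = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(e))])
        return c / c[-1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of ``n`` beta energies (keV)."""
        return np.interp(rng.random(n), self.cdf(), self.energy_keV)


@dataclass
class Nuclide:
    """One library entry (possibly an equilibrium pair treated as a unit)."""

    name: str
    half_life_s: float
    lines: list[EmissionLine]
    beta_branches: list[BetaBranch]
    betas_per_decay: float
    default_amad_um: float
    default_gsd: float
    amad_borrowed: bool = False
    _spectrum: BetaSpectrum | None = field(default=None, repr=False)

    def lines_of_kind(self, kind: str) -> list[EmissionLine]:
        if kind in _PHOTON_KINDS:
            return [ln for ln in self.lines if ln.kind == kind]
        if kind == "photon":
            return [ln for ln in self.lines if ln.kind in _PHOTON_KINDS]
        return [ln for ln in self.lines if ln.kind == kind]

    def total_yield(self, kind: str) -> float:
        """Emissions per decay of a radiation kind (photon = gamma + xray)."""
        if kind == "beta":
            return self.betas_per_decay
        return sum(ln.yield_per_decay for ln in self.lines_of_kind(kind))

    def beta_spectrum(self, grid_points: int = 2000) -> BetaSpectrum:
        if self._spectrum is None or len(self._spectrum.energy_keV) != grid_points:
            self._spectrum = build_beta_spectrum(self.beta_branches, grid_points)
        return self._spectrum


def fermi_coulomb_correction(Z: int, kinetic_keV: np.ndarray) -> np.ndarray:
    """Nonrelativistic Fermi function F(Z, E) for beta-minus decay.

    ``F = 2πη / (1 − exp(−2πη))`` with ``η = +Zα/β``.  The E→0 limit of the
    integrand remains finite because F diverges as 1/β while the phase-space
    factor p·E_tot vanishes as β.
    """
    e = np.asarray(kinetic_keV, float)
    gamma = 1.0 + e / ELECTRON_MASS_KEV
    beta = np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 1e-30, None))
    eta = Z * FINE_STRUCTURE / beta
    x = 2.0 * np.pi * eta
    return x / -np.expm1(-x)


def build_beta_spectrum(branches: list[BetaBranch], grid_points: int = 2000) -> BetaSpectrum:
    """Branch-weighted allowed-shape Fermi spectrum, unit-normalised.

    The grid spans ``[0, max endpoint]``; the density vanishes at the
    endpoint by construction of the (Q − E)² phase-space factor.
    """
    if not branches:
        raise ValueError("no beta branches")
    if grid_points < 100:
        raise ValueError("grid_points must be >= 100")
    q_max = max(b.endpoint_keV for b in branches)
    e = np.linspace(0.0, q_max, grid_points)
    dens = np.zeros_like(e)
    for b in branches:
        inside = e < b.endpoint_keV
        ek = e[inside]
        gamma = 1.0 + ek / ELECTRON_MASS_KEV
        e_tot = ek + ELECTRON_MASS_KEV
        p = np.sqrt(np.clip(e_tot**2 - ELECTRON_MASS_KEV**2, 0.0, None))
        shape = p * e_tot * (b.endpoint_keV - ek) ** 2
        shape *= fermi_coulomb_correction(b.daughter_Z, ek)
        norm = np.trapezoid(shape, ek)
        if norm > 0:
            dens[inside] += b.fraction * shape / norm
    total = sum(b.fraction for b in branches)
    dens /= total
    # renormalise the tabulated curve so its trapezoid integral is exactly 1
    dens /= np.trapezoid(dens, e)
    return BetaSpectrum(e, dens)


def mean_beta_energy_per_decay(nuclide: Nuclide, grid_points: int = 4000) -> float:
    """Mean beta energy emitted per decay, in MeV.

    Per-emission spectrum mean times the number of betas per decay (2 for
    the Sr-90/Y-90 equilibrium pair, ~1 otherwise); 0 for pure alpha emitters.
    """
    if not nuclide.beta_branches:
        return 0.0
    spec = nuclide.beta_spectrum(grid_points)
    return spec.mean_energy_keV() / 1000.0 * nuclide.betas_per_decay


def photon_energy_per_decay(nuclide: Nuclide) -> float:
    """Σ energy × yield over all gamma and x-ray lines, in MeV."""
    return sum(ln.energy_keV * ln.yield_per_decay for ln in nuclide.lines_of_kind("photon")) / 1000.0


def load_builtin_library() -> dict[str, Nuclide]:
    """Load the built-in nuclide table shipped with the package."""
    text = resources.files("inhaledose.data").joinpath("nuclide_library.json").read_text()
    raw = json.loads(text)
    lib: dict[str, Nuclide] = {}
    for name, entry in raw.items():
        if name.startswith("_"):
            continue
        lib[name] = Nuclide(
            name=name,
            half_life_s=entry["half_life_s"],
            lines=[
                EmissionLine(ln["energy_keV"], ln["yield"], ln["kind"]) for ln in entry["lines"]
            ],
            beta_branches=[
                BetaBranch(b["endpoint_keV"], b["fraction"], b["daughter_Z"])
                for b in entry["beta_branches"]
            ],
            betas_per_decay=entry["betas_per_decay"],
            default_amad_um=entry["default_aerosol"]["amad_um"],
            default_gsd=entry["default_aerosol"]["gsd"],
            amad_borrowed=entry["default_aerosol"].get("borrowed", False),
        )
    return lib


def lookup(name: str, library: dict[str, Nuclide] | None = None) -> Nuclide:
    lib = library if library is not None else load_builtin_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"nuclide {name!r} not in library (available: {sorted(lib)})"
        ) from None


def sample_emission(
    nuclide: Nuclide, kind: str, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` emission energies (keV) of the given kind.

    Discrete lines are sampled with probability ``yield_i / Σ yields``;
    ``kind='beta'`` samples the Fermi spectrum by inverse CDF.
    """
    if kind == "beta":
        if not nuclide.beta_branches:
            raise ValueError(f"{nuclide.name} emits no betas")
        return nuclide.beta_spectrum().sample(n, rng)
    lines = nuclide.lines_of_kind(kind)
    if not lines:
        raise ValueError(f"{nuclide.name} emits no {kind} radiation")
    energies = np.array([ln.energy_keV for ln in lines])
    yields = np.array([ln.yield_per_decay for ln in lines])
    idx = rng.choice(len(lines), size=n, p=yields / yields.sum())
    return energies[idx]
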