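"""Lognormal polydisperse aerosol ensembles and mass/count bookkeeping.

An aerosol release is described by its activity median aerodynamic diameter
(AMAD, µm) and geometric standard deviation (GSD).  Diameters are stored as
aerodynamic; where the physical carrier geometry matters (alpha
self-shielding in dense UO₂ spheres) the aerodynamic→geometric conversion
``d_g = d_ae √(χ/ρ)`` is applied explicitly.

Activity is taken proportional to particle mass (uniform specific activity
through the carrier material), so mass-basis and activity-basis weights
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistributionSpec",
    "ParticleEnsemble",
    "sample_ensemble",
    "particle_mass",
    "aerodynamic_to_geometric",
    "deposition_fraction",
    "size_histogram",
]

STATUSES = ("airborne", "deposited", "alveolar_retained", "exhaled")

#: CSV column schema shared with externally produced deposition tables
CSV_COLUMNS = ["id", "d_ae_um", "x_cm", "y_cm", "z_cm", "region", "status"]


@dataclass(frozen=True)
class SizeDistributionSpec:
    """Lognormal size spec: AMAD (µm), GSD (≥1), carrier density (g/cc)."""

    amad_um: float
    gsd: float
    particle_density_g_cc: float = 1.0

    def __post_init__(self) -> None:
        if self.amad_um <= 0:
            raise ValueError("AMAD must be positive")
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")
        if self.particle_density_g_cc <= 0:
            raise ValueError("particle density must be positive")


class ParticleEnsemble:
    """Tabular particle state: diameter, position, region, status.

    Thin wrapper over a :class:`pandas.DataFrame` with the columns of
    :data:`CSV_COLUMNS`; the same schema round-trips to CSV and is accepted
    from external fluid-dynamics deposition runs.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in CSV_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"ensemble table missing columns {missing}")
        if (table["d_ae_um"] <= 0).any():
            raise ValueError("diameters must be positive")
        bad = set(table["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown particle status values {bad}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def diameters_um(self) -> np.ndarray:
        return self.table["d_ae_um"].to_numpy()

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    def positions_cm(self) -> np.ndarray:
        return self.table[["x_cm", "y_cm", "z_cm"]].to_numpy()

    def counts_by_status(self) -> dict[str, int]:
        c = self.table["status"].value_counts()
        return {s: int(c.get(s, 0)) for s in STATUSES}

    def to_csv(self, path) -> None:
        self.table[CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ParticleEnsemble":
        return cls(pd.read_csv(path))


def sample_ensemble(
    spec: SizeDistributionSpec, n: int, seed: int | np.random.Generator = 0
) -> ParticleEnsemble:
    """Draw ``n`` i.i.d. aerodynamic diameters: lognormal with median AMAD
    and ln-standard-deviation ln(GSD)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.exp(np.log(spec.amad_um) + np.log(spec.gsd) * rng.standard_normal(n))
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "d_ae_um": d,
            "x_cm": np.nan,
            "y_cm": np.nan,
            "z_cm": np.nan,
            "region": "",
            "status": "airborne",
        }
    )
    return ParticleEnsemble(table)


def particle_mass(diameter_um, density_g_cc: float = 1.0):
    """Sphere mass (π/6)ρd³ in picograms for diameter in µm, ρ in g/cc.

    1 µm³ of unit-density material is exactly 1 pg, so the unit bookkeeping
    reduces to the geometric volume.
    """
    d = np.asarray(diameter_um, float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    return (np.pi / 6.0) * density_g_cc * d**3


def aerodynamic_to_geometric(d_ae_um, density_g_cc: float, shape_factor: float = 1.0):
    """Convert aerodynamic to geometric diameter: d_g = d_ae √(χ/ρ).

    ``density_g_cc`` is the carrier material density relative to the
    unit-density reference sphere defining the aerodynamic diameter.
    """
    if density_g_cc <= 0:
        raise ValueError("density must be positive")
    return np.asarray(d_ae_um, float) * np.sqrt(shape_factor / density_g_cc)


def _basis_weights(ensemble: ParticleEnsemble, basis: str) -> np.ndarray:
    if basis == "count":
        return np.ones(len(ensemble))
    if basis == "mass":
        return particle_mass(ensemble.diameters_um)
    raise ValueError("basis must be 'mass' or 'count'")


def deposition_fraction(
    ensemble: ParticleEnsemble, basis: str = "mass", scope: set[str] | None = None
) -> float:
    """Deposited fraction of the inhaled aerosol on a mass or count basis.

    ``scope`` restricts the numerator to a set of region labels (None =
    whole respiratory tract).  Alveolar-retained particles count as
    deposited.  The ensemble must be finalized (no airborne particles).
    """
    if len(ensemble) == 0:
        raise ValueError("no inhaled particles")
    if (ensemble.status == "airborne").any():
        raise ValueError("ensemble not finalized: airborne particles remain")
    w = _basis_weights(ensemble, basis)
    dep = ensemble.status.isin(["deposited", "alveolar_retained"]).to_numpy()
    if scope is not None:
        dep &= ensemble.table["region"].isin(scope).to_numpy()
    return float(w[dep].sum() / w.sum())


def size_histogram(
    ensemble: ParticleEnsemble, region: str | None, bin_edges
) -> pd.DataFrame:
    """Per-bin particle count and mass for one region (None = all regions)."""
    edges = np.asarray(bin_edges, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    tab = ensemble.table
    if region is not None:
        tab = tab[tab["region"] == region]
    d = tab["d_ae_um"].to_numpy()
    counts, _ = np.histogram(d, edges)
    mass, _ = np.histogram(d, edges, weights=particle_mass(d))
    return pd.DataFrame(
        {"bin_lo_um": edges[:-1], "bin_hi_um": edges[1:], "count": counts, "mass_pg": mass}
    )
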