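"""Drivers for photon and electron transport in a voxel phantom.

These wrap the numba kernels: they build cross-section / stopping-power
tables for the phantom's material set, lay out source and emission
distributions, run the requested number of histories in batches, and
return mesh (:class:`~inhaledose.transport.tally.TallyGrid`) and organ
(:class:`~inhaledose.transport.tally.OrganTally`) tallies together with a
per-batch energy-conservation record.

One emission is transported per history; converting a tally to a
per-decay quantity means multiplying by the emissions per decay of that
radiation kind, done at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nuclides import Nuclide
from .electron_physics import electron_stopping_power, radiation_length_g_cm2
from .kernels import run_electron_batches, run_photon_batches
from .tally import OrganTally, TallyGrid
from .xs import PhotonCrossSectionModel

__all__ = ["TransportConfig", "run_photon_transport", "run_electron_transport"]


@dataclass
class TransportConfig:
    """Histories, batching and physics cutoffs for one transport run.

    The default desk-scale history counts (10⁶ photons, 2×10⁵ electrons)
    are 1% of the production-scale runs the per-decay dose tables are
    meant to be computed with; statistical errors scale as 1/√N.
    """

    histories: int = 1_000_000
    batches: int = 10
    seed: int = 1
    photon_cutoff_keV: float = 10.0
    electron_cutoff_keV: float = 10.0
    electron_step_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.histories >= self.batches >= 2:
            raise ValueError("need histories >= batches >= 2")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must fit in a signed 32-bit integer")


def _prepare_common(sources, phantom):
    idx = np.asarray(sources.voxel_indices, dtype=np.int64)
    shape = np.array(phantom.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("source voxel outside the phantom grid")
    w = sources.normalized_weights()
    src_cdf = np.cumsum(w)
    src_cdf[-1] = 1.0
    mat_grid, mats = phantom.material_index_grid()
    organ_grid = phantom.organ_ids.astype(np.int32)
    return idx, src_cdf, mat_grid, mats, organ_grid


def _organ_tally(phantom, organ_batch, histories) -> OrganTally:
    present = np.array(sorted(int(i) for i in np.unique(phantom.organ_ids)))
    masses = np.array([phantom.organ_mass_g(i) for i in present])
    batch = organ_batch[:, present]
    return OrganTally(
        organ_ids=present,
        energy_MeV=batch.sum(axis=0),
        batch_energy=batch,
        organ_mass_g=masses,
        histories=histories,
    )


def run_photon_transport(
    sources,
    nuclide: Nuclide,
    phantom,
    config: TransportConfig,
    absorb_all: bool = False,
    energies_keV: np.ndarray | None = None,
) -> tuple[TallyGrid, OrganTally, dict]:
    """Transport the nuclide's photon lines from the registered sources.

    ``absorb_all`` switches every real collision to full absorption (an
    attenuation-only physics mode used for analytic benchmarking);
    ``energies_keV`` overrides the emission lines with a custom discrete
    set (equiprobable if given as a bare array).
    """
    idx, src_cdf, mat_grid, mats, organ_grid = _prepare_common(sources, phantom)
    if energies_keV is not None:
        line_e = np.asarray(energies_keV, float)
        line_cdf = np.cumsum(np.full(len(line_e), 1.0 / len(line_e)))
    else:
        plines = nuclide.lines_of_kind("photon")
        if not plines:
            raise ValueError(f"{nuclide.name} emits no photons")
        line_e = np.array([ln.energy_keV for ln in plines])
        yields = np.array([ln.yield_per_decay for ln in plines])
        line_cdf = np.cumsum(yields / yields.sum())
    line_cdf[-1] = 1.0
    if line_e.max() > 2300.0:
        raise ValueError("photon line above the 2.3 MeV model ceiling")

    model = PhotonCrossSectionModel(mats, cutoff_keV=min(config.photon_cutoff_keV, 10.0))
    ln_e0 = float(np.log(model.energy_grid_keV[0]))
    inv_dln = 1.0 / float(np.log(model.energy_grid_keV[1] / model.energy_grid_keV[0]))

    grid = TallyGrid(phantom.shape, phantom.voxel_size_cm, phantom.origin_cm)
    n_slots = int(phantom.organ_ids.max()) + 1
    organ_batch = np.zeros((config.batches, n_slots))
    conservation = np.zeros((config.batches, 3))

    run_photon_batches(
        mat_grid,
        organ_grid,
        ln_e0,
        inv_dln,
        model.mu_linear,
        model.photoelectric_fraction,
        model.majorant,
        phantom.origin_cm.astype(np.float64),
        float(phantom.voxel_size_cm),
        idx,
        src_cdf,
        line_e,
        line_cdf,
        int(config.histories),
        int(config.batches),
        int(config.seed),
        float(config.photon_cutoff_keV),
        bool(absorb_all),
        grid.fluence,
        grid.energy_MeV,
        grid.fluence_batch_sq,
        grid.energy_batch_sq,
        organ_batch,
        conservation,
    )
    # the photon kernel scores energies in keV; convert tallies to MeV
    grid.energy_MeV /= 1000.0
    grid.energy_batch_sq /= 1.0e6
    histories = (config.histories // config.batches) * config.batches
    grid.histories = histories
    grid.n_batches = config.batches
    info = {
        "emitted_MeV": conservation[:, 0].sum() / 1000.0,
        "deposited_MeV": conservation[:, 1].sum() / 1000.0,
        "escaped_MeV": conservation[:, 2].sum() / 1000.0,
        "per_batch_keV": conservation,
        "histories": histories,
    }
    return grid, _organ_tally(phantom, organ_batch / 1000.0, histories), info


def run_electron_transport(
    sources,
    nuclide: Nuclide,
    phantom,
    config: TransportConfig,
    spectrum=None,
) -> tuple[TallyGrid, OrganTally, dict]:
    """Transport beta electrons sampled from the nuclide's Fermi spectrum.

    ``spectrum`` may override the source spectrum (a
    :class:`~inhaledose.nuclides.BetaSpectrum`); by default the nuclide's
    branch-weighted spectrum is used.
    """
    idx, src_cdf, mat_grid, mats, organ_grid = _prepare_common(sources, phantom)
    spec = spectrum if spectrum is not None else nuclide.beta_spectrum(2000)
    spec_e = spec.energy_keV / 1000.0
    spec_cdf = spec.cdf()

    e_grid = np.geomspace(1e-3, max(spec_e[-1] * 1.05, 0.02), 96)
    stop = np.array([electron_stopping_power(m, e_grid) for m in mats])
    inv_x0 = np.array([m.density_g_cc / radiation_length_g_cm2(m) for m in mats])
    ln_e0 = float(np.log(e_grid[0]))
    inv_dln = 1.0 / float(np.log(e_grid[1] / e_grid[0]))

    grid = TallyGrid(phantom.shape, phantom.voxel_size_cm, phantom.origin_cm)
    n_slots = int(phantom.organ_ids.max()) + 1
    organ_batch = np.zeros((config.batches, n_slots))
    conservation = np.zeros((config.batches, 3))

    run_electron_batches(
        mat_grid,
        organ_grid,
        ln_e0,
        inv_dln,
        stop,
        inv_x0,
        phantom.origin_cm.astype(np.float64),
        float(phantom.voxel_size_cm),
        idx,
        src_cdf,
        spec_e,
        spec_cdf,
        int(config.histories),
        int(config.batches),
        int(config.seed),
        float(config.electron_cutoff_keV) / 1000.0,
        float(config.electron_step_fraction),
        grid.energy_MeV,
        grid.energy_batch_sq,
        organ_batch,
        conservation,
    )
    histories = (config.histories // config.batches) * config.batches
    grid.histories = histories
    grid.n_batches = config.batches
    info = {
        "emitted_MeV": conservation[:, 0].sum(),
        "deposited_MeV": conservation[:, 1].sum(),
        "escaped_MeV": conservation[:, 2].sum(),
        "per_batch_MeV": conservation,
        "histories": histories,
    }
    return grid, _organ_tally(phantom, organ_batch, histories), info
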