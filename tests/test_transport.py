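"""Photon/electron transport physics against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from inhaledose.materials import Material, material
from inhaledose.nuclides import BetaSpectrum, lookup
from inhaledose.transport.electron_physics import (
    electron_csda_range_cm,
    electron_stopping_power,
)
from inhaledose.transport.engine import (
    TransportConfig,
    run_electron_transport,
    run_photon_transport,
)
from inhaledose.transport.kernels import sample_compton_ratios
from inhaledose.transport.tally import relative_error
from inhaledose.transport.xs import (
    PhotonCrossSectionModel,
    compton_mass_attenuation,
    mass_attenuation,
)

from conftest import center_source, make_box_phantom


class TestCrossSections:
    def test_compton_water_at_cs137_line(self):
        # closed-form KN total × water electron density (Z/A = 0.555)
        assert compton_mass_attenuation(material("water"), 661.6) == pytest.approx(
            0.086, abs=0.002
        )

    def test_monotone_decreasing_for_soft_tissue(self):
        e = np.linspace(200, 2000, 50)
        mu = mass_attenuation(material("muscle"), e)
        assert np.all(np.diff(mu) < 0)

    def test_mixture_additivity(self):
        # μ/ρ of a compound equals the mass-fraction sum over elements
        water = material("water")
        h = Material("h", 1.0, {"H": 1.0})
        o = Material("o", 1.0, {"O": 1.0})
        for e in (30.0, 100.0, 662.0):
            expect = 0.1119 * mass_attenuation(h, e) + 0.8881 * mass_attenuation(o, e)
            assert mass_attenuation(water, e) == pytest.approx(float(expect), rel=1e-9)

    def test_energy_range_enforced(self):
        with pytest.raises(ValueError):
            mass_attenuation(material("water"), 5.0)
        with pytest.raises(ValueError):
            mass_attenuation(material("water"), 5000.0)

    def test_majorant_dominates(self):
        mats = [material(n) for n in ("water", "bone", "lung_respiratory", "air")]
        model = PhotonCrossSectionModel(mats)
        assert np.all(model.majorant[None, :] >= model.mu_linear)


def _kn_mean_ratio(e_keV):
    k = e_keV / 510.99895

    def dsig(x):
        ct = 1.0 - (1.0 / x - 1.0) / k
        return x + 1.0 / x - (1.0 - ct * ct)

    lo = 1.0 / (1 + 2 * k)
    return quad(lambda x: x * dsig(x), lo, 1)[0] / quad(dsig, lo, 1)[0]


@pytest.mark.parametrize("e_keV", [200.0, 661.6, 1250.0])
def test_compton_sampling_mean_matches_klein_nishina(e_keV):
    draws = sample_compton_ratios(e_keV, 200_000, 7)
    se = draws.std() / np.sqrt(len(draws))
    assert abs(draws.mean() - _kn_mean_ratio(e_keV)) < 3 * se


class TestPhotonTransport:
    def test_energy_conservation_per_batch(self, water_phantom):
        src = center_source(water_phantom)
        cfg = TransportConfig(histories=20_000, batches=5, seed=3)
        _, _, info = run_photon_transport(src, None, water_phantom, cfg, energies_keV=[661.6])
        c = info["per_batch_keV"]
        assert np.allclose(c[:, 0], c[:, 1] + c[:, 2], rtol=1e-12)

    def test_vacuum_phantom_everything_escapes(self):
        ph = make_box_phantom("air", n=21)
        src = center_source(ph)
        cfg = TransportConfig(histories=5_000, batches=2, seed=1)
        _, _, info = run_photon_transport(src, None, ph, cfg, energies_keV=[661.6])
        # air is so thin that essentially all energy leaves the 21 cm box
        assert info["escaped_MeV"] / info["emitted_MeV"] > 0.999

    def test_dense_absorber_captures_everything(self):
        ph = make_box_phantom("uo2", n=31, h=2.0)
        src = center_source(ph)
        cfg = TransportConfig(histories=5_000, batches=2, seed=1)
        _, _, info = run_photon_transport(src, None, ph, cfg, energies_keV=[200.0])
        assert info["deposited_MeV"] / info["emitted_MeV"] > 0.99

    def test_uncollided_fluence_attenuation_oracle(self):
        # point isotropic source, absorption-only: Φ(r) = e^{-μr}/(4πr²)
        ph = make_box_phantom("water", n=41)
        src = center_source(ph)
        cfg = TransportConfig(histories=2_000_000, batches=4, seed=11)
        grid, _, _ = run_photon_transport(
            src, None, ph, cfg, absorb_all=True, energies_keV=[661.6]
        )
        mu = float(mass_attenuation(material("water"), 661.6))  # ρ=1
        flu = grid.per_history(grid.fluence)
        c = np.array(ph.shape) // 2
        ii, jj, kk = np.indices(ph.shape)
        r = np.sqrt(
            ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2).astype(float)
        ) * ph.voxel_size_cm
        for r0 in (5.0, 8.0, 12.0):
            shell = (np.abs(r - r0) < 0.3) & (flu > 0)
            got = flu[shell].mean()
            expect = np.mean(np.exp(-mu * r[shell]) / (4 * np.pi * r[shell] ** 2))
            assert got == pytest.approx(expect, rel=0.05), r0

    def test_heterogeneous_attenuation_oracle(self):
        # water with a bone slab: uncollided fluence follows the line
        # integral of μ along the ray (checks Woodcock against direct
        # exponential attenuation through layered media)
        ph = make_box_phantom("water", n=41, layers=[(24, 28, "bone")])
        src = center_source(ph)
        cfg = TransportConfig(histories=2_000_000, batches=4, seed=13)
        grid, _, _ = run_photon_transport(
            src, None, ph, cfg, absorb_all=True, energies_keV=[661.6]
        )
        flu = grid.per_history(grid.fluence)
        mu_w = float(mass_attenuation(material("water"), 661.6))
        mu_b = float(mass_attenuation(material("bone"), 661.6)) * 1.55
        c = 20
        # mirror-ratio: +z rays cross 4 cm of bone, −z rays only water; the
        # voxel-averaging bias cancels and only the optical-path difference
        # exp(−(μ_b−μ_w)·4) remains
        patch = slice(c - 1, c + 2)
        behind = flu[patch, patch, 30:37].sum()
        mirror = flu[patch, patch, 4:11][:, :, ::-1].sum()
        assert behind / mirror == pytest.approx(np.exp(-(mu_b - mu_w) * 4.0), rel=0.05)

    def test_mesh_and_organ_tallies_agree(self, water_phantom):
        src = center_source(water_phantom)
        cfg = TransportConfig(histories=20_000, batches=4, seed=5)
        grid, organ, _ = run_photon_transport(
            src, None, water_phantom, cfg, energies_keV=[661.6]
        )
        assert grid.energy_MeV.sum() == pytest.approx(organ.total_deposited_MeV(), rel=1e-3)

    def test_source_outside_grid_rejected(self, water_phantom):
        from inhaledose.registration import SourceEnsemble

        src = SourceEnsemble(np.array([[99, 0, 0]]), np.zeros((1, 3)), np.array([1.0]))
        with pytest.raises(ValueError, match="outside"):
            run_photon_transport(
                src, None, water_phantom, TransportConfig(histories=10, batches=2),
                energies_keV=[661.6],
            )


class TestRelativeError:
    def test_identical_batches_zero(self):
        assert relative_error(np.array([[2.0], [2.0], [2.0]]))[0] == 0.0

    def test_zero_mean_flagged(self):
        assert np.isinf(relative_error(np.array([[0.0], [0.0]]))[0])

    def test_too_few_batches(self):
        with pytest.raises(ValueError):
            relative_error(np.array([[1.0]]))

    def test_inverse_sqrt_scaling(self, water_phantom):
        # shell-averaged per-voxel relative error: 4x histories halves R
        src = center_source(water_phantom)
        c = np.array(water_phantom.shape) // 2
        ii, jj, kk = np.indices(water_phantom.shape)
        r = np.sqrt(((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2).astype(float))
        shell = (r > 4) & (r < 8)
        rs = {}
        for n in (20_000, 80_000):
            cfg = TransportConfig(histories=n, batches=8, seed=17)
            grid, _, _ = run_photon_transport(
                src, None, water_phantom, cfg, energies_keV=[661.6]
            )
            rel = grid.relative_error_energy()
            sel = shell & np.isfinite(rel) & (grid.energy_MeV > 0)
            rs[n] = rel[sel].mean()
        assert rs[80_000] == pytest.approx(rs[20_000] / 2, rel=0.3)


class TestElectronTransport:
    def test_csda_range_matches_published_tables(self):
        # reference CSDA range of a 2.28 MeV electron in water ≈ 1.10 g/cm²
        assert electron_csda_range_cm(2.28, material("water")) == pytest.approx(1.1, rel=0.07)

    def test_stopping_power_scale(self):
        # minimum-ionising plateau in water is ~2 MeV/cm
        assert float(electron_stopping_power(material("water"), 1.0)) == pytest.approx(
            1.87, rel=0.1
        )

    def test_full_containment_absorbed_fraction(self, water_phantom):
        src = center_source(water_phantom)
        nuc = lookup("Sr-90/Y-90")
        cfg = TransportConfig(histories=20_000, batches=4, seed=7)
        _, organ, info = run_electron_transport(src, nuc, water_phantom, cfg)
        af = info["deposited_MeV"] / info["emitted_MeV"]
        assert af == pytest.approx(1.0, abs=1e-3)

    def test_energy_conservation_per_batch(self, water_phantom):
        src = center_source(water_phantom)
        cfg = TransportConfig(histories=10_000, batches=5, seed=9)
        _, _, info = run_electron_transport(src, lookup("Cs-137"), water_phantom, cfg)
        c = info["per_batch_MeV"]
        assert np.allclose(c[:, 0], c[:, 1] + c[:, 2], rtol=1e-9)

    def test_deposition_confined_to_csda_sphere(self):
        ph = make_box_phantom("water", n=21, h=0.5)
        src = center_source(ph)
        e0 = 2.0  # MeV, monoenergetic-narrow spectrum
        spec = BetaSpectrum(np.array([0.999 * e0, e0]) * 1000, np.array([1.0, 1.0]) / e0)
        cfg = TransportConfig(histories=5_000, batches=2, seed=21)
        grid, _, info = run_electron_transport(src, None, ph, cfg, spectrum=spec)
        r_max = electron_csda_range_cm(e0, material("water")) + 3 * 0.25
        c = np.array(ph.shape) // 2
        ii, jj, kk = np.indices(ph.shape)
        r = np.sqrt(((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2).astype(float)) * 0.5
        outside = grid.energy_MeV[r > r_max + 0.5 * np.sqrt(3)].sum()
        assert outside == 0.0
        assert info["escaped_MeV"] == 0.0
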