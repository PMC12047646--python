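"""Monte Carlo transport: analytic oracles, energy bookkeeping, dose/SPR outputs."""

import dataclasses

import numpy as np
import pytest

from truncbct.geometry import build_geometry
from truncbct.montecarlo import (
    DoseScatterTally,
    DoseUndefinedError,
    MCConfig,
    dgn_ct,
    mgd,
    spr_profile,
    transport,
)
from truncbct.spectrum_materials import Spectrum


def mono_spectrum(table, e_kev):
    e = np.array([float(e_kev)])
    return Spectrum(e, np.array([1.0]), table.kerma_factors(e))


@pytest.fixture(scope="module")
def small_panel():
    # narrow panel: near-normal incidence for slab oracles
    return build_geometry(det_cols_full=128, det_rows=96, n_views=1)


class TestTransportOracles:
    def test_vacuum_phantom_all_primary(self, small_panel, material_table):
        vacuum_table = dataclasses.replace(
            material_table, densities={**material_table.densities, "air": 0.0})
        labels = np.zeros((32, 32, 32), dtype=np.uint8)
        cfg = MCConfig(n_photons=20_000, n_projections=1, rng_seed=1)
        tally = transport(labels, 4.0, mono_spectrum(material_table, 30.0),
                          small_panel, cfg, materials=("air",), table=vacuum_table)
        assert tally.scatter.sum() == 0.0
        assert tally.primary.sum() == pytest.approx(tally.emitted_kev)
        assert tally.total_deposited_kev == 0.0

    def test_beer_lambert_slab_transmission(self, small_panel, material_table):
        """Primary fraction through a 4 mm Al slab at 30 keV = exp(-mu t)."""
        labels = np.zeros((96, 96, 1), dtype=np.uint8)
        labels[:, :, 0] = 1
        cfg = MCConfig(n_photons=100_000, n_projections=1, rng_seed=3)
        tally = transport(labels, 4.0, mono_spectrum(material_table, 30.0),
                          small_panel, cfg, materials=("air", "aluminum"),
                          table=material_table)
        frac = tally.primary.sum() / tally.emitted_kev
        expected = np.exp(-material_table.mu("aluminum", 30.0) * 0.4)
        se = np.sqrt(frac * (1 - frac) / tally.n_emitted)
        assert abs(frac - expected) <= 3 * se

    def test_energy_conservation_exact(self, small_panel, material_table,
                                       spectrum49):
        labels = np.zeros((48, 48, 48), dtype=np.uint8)
        labels[12:36, 12:36, 12:36] = 1
        cfg = MCConfig(n_photons=30_000, n_projections=3, rng_seed=5)
        tally = transport(labels, 4.0, spectrum49, small_panel, cfg,
                          materials=("air", "fibroglandular"), table=material_table)
        assert tally.energy_balance_error() <= 1e-3

    def test_deterministic_per_seed(self, small_panel, material_table, spectrum49):
        labels = np.zeros((24, 24, 24), dtype=np.uint8)
        labels[6:18, 6:18, 6:18] = 1
        cfg = MCConfig(n_photons=5_000, n_projections=2, rng_seed=9)
        t1 = transport(labels, 6.0, spectrum49, small_panel, cfg,
                       materials=("air", "adipose"), table=material_table)
        t2 = transport(labels, 6.0, spectrum49, small_panel, cfg,
                       materials=("air", "adipose"), table=material_table)
        assert t1.total_deposited_kev == t2.total_deposited_kev
        np.testing.assert_array_equal(t1.scatter, t2.scatter)


def synthetic_tally(e_dep_fibro, n_g=1000, vox=2.0, primary=None, scatter=None):
    shape = (2, 4, 8)
    return DoseScatterTally(
        deposited_kev={"fibroglandular": e_dep_fibro, "air": 0.0},
        primary=np.ones(shape) if primary is None else primary,
        scatter=np.zeros(shape) if scatter is None else scatter,
        emitted_kev=e_dep_fibro * 2, escaped_kev=e_dep_fibro,
        n_emitted=1000, voxel_size_mm=vox,
        voxel_counts={"fibroglandular": n_g, "air": 500},
        fluence_iso_per_cm2=1e6,
    )


class TestDgN:
    def test_no_fibroglandular_raises(self, material_table, spectrum49):
        tally = synthetic_tally(1e5, n_g=0)
        with pytest.raises(DoseUndefinedError):
            dgn_ct(tally, spectrum49, table=material_table)

    def test_linear_in_deposited_energy(self, material_table, spectrum49):
        d1 = dgn_ct(synthetic_tally(1e5), spectrum49, table=material_table)
        d2 = dgn_ct(synthetic_tally(2e5), spectrum49, table=material_table)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_formula_against_direct_bookkeeping(self, material_table, spectrum49):
        """DgN equals mean fibroglandular dose over isocenter air kerma computed
        by independent hand arithmetic on the tally fields."""
        tally = synthetic_tally(3.3e6, n_g=2500, vox=2.0)
        rho = material_table.density("fibroglandular")
        mass_g = 2500 * rho * 0.2**3
        dose_mgy = 3.3e6 * 1.602177e-16 / (mass_g * 1e-3) * 1e3
        frac = spectrum49.fluence / spectrum49.fluence.sum()
        kf = material_table.kerma_factors(spectrum49.energies_kev)
        k_air = 1e6 * float((frac * kf).sum())
        assert dgn_ct(tally, spectrum49, table=material_table) == pytest.approx(
            dose_mgy / k_air, rel=1e-9)

    def test_mgd_scales_with_scan_kerma(self, material_table, spectrum49):
        tally = synthetic_tally(1e5)
        assert mgd(tally, spectrum49, 10.0, table=material_table) == pytest.approx(
            10 * dgn_ct(tally, spectrum49, table=material_table))


class TestSprProfile:
    def test_zero_scatter_gives_zero_profile(self):
        tally = synthetic_tally(1.0)
        profile, mx = spr_profile(tally)
        assert mx == 0.0 and np.nanmax(profile) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        prim = rng.random((2, 4, 8)) + 0.5
        scat = rng.random((2, 4, 8))
        t1 = synthetic_tally(1.0, primary=prim, scatter=scat)
        t2 = synthetic_tally(1.0, primary=7 * prim, scatter=7 * scat)
        p1, m1 = spr_profile(t1)
        p2, m2 = spr_profile(t2)
        np.testing.assert_allclose(p1, p2)
        assert m1 == pytest.approx(m2)

    def test_all_zero_primary_rejected(self):
        tally = synthetic_tally(1.0, primary=np.zeros((2, 4, 8)))
        from truncbct.montecarlo import MCError
        with pytest.raises(MCError):
            spr_profile(tally)
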