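"""Voxel-FE torsion: analytic oracle, material model, structural checks.

The heavy cylinder benchmark (full accuracy bands at production
resolution) lives in test_acceptance; here the oracle runs on a small
cylinder, plus the model-construction and physics invariants.
"""

import numpy as np
import pytest

from osteoquant import (
    DensityImage,
    DiscontinuousStructureError,
    MaterialModel,
    analytic_cylinder_vtr,
    assign_modulus,
    build_fe_model,
    downsample_density,
    simulate_torsion,
)
from osteoquant.fe import FEModel

from conftest import cylinder_density


class TestMaterialModel:
    def test_soft_tissue_below_cutoff(self):
        assert assign_modulus(600.0) == 50.0

    def test_cutoff_is_exclusive_below(self):
        mat = MaterialModel()
        assert assign_modulus(664.999, mat) == 50.0
        expected = mat.e_ref * (665.0 / mat.rho_ref) ** mat.gamma
        assert assign_modulus(665.0, mat) == pytest.approx(expected)

    def test_reference_point_normalization(self):
        mat = MaterialModel()
        assert assign_modulus(mat.rho_ref, mat) == pytest.approx(mat.e_ref)

    def test_clamped_to_rho_max(self):
        mat = MaterialModel(rho_max=1500.0)
        assert assign_modulus(5000.0, mat) == assign_modulus(1500.0, mat)

    def test_vectorized(self):
        out = assign_modulus(np.array([100.0, 664.0, 1200.0]))
        assert out[0] == out[1] == 50.0
        assert out[2] == pytest.approx(20000.0)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel(poisson=0.5)


class TestDownsample:
    def test_uniform_volume_unchanged(self):
        d = DensityImage(np.full((8, 8, 8), 800.0), 0.2)
        out = downsample_density(d, 0.4)
        assert np.allclose(out.data, 800.0)
        assert out.spacing == 0.4

    def test_checkerboard_block_mean(self):
        base = np.indices((8, 8, 8)).sum(axis=0) % 2
        d = DensityImage(base * 800.0, 0.2)
        out = downsample_density(d, 0.4)
        assert np.allclose(out.data, 400.0)

    def test_mass_conserved_on_tibia(self, small_scan):
        d = DensityImage(small_scan.truth_density, small_scan.spacing)
        out = downsample_density(d, 0.8)
        mass_in = d.data.sum() * d.spacing**3
        mass_out = out.data.sum() * out.spacing**3
        assert mass_out == pytest.approx(mass_in, rel=0.005)

    def test_finer_target_rejected(self):
        d = DensityImage(np.zeros((4, 4, 4)), 0.4)
        with pytest.raises(ValueError):
            downsample_density(d, 0.2)


class TestBuildModel:
    def test_solid_cuboid_uniform_modulus(self):
        d = DensityImage(np.full((4, 4, 6), 1200.0), 0.5)
        m = build_fe_model(d)
        assert m.n_elements == 4 * 4 * 6
        assert np.allclose(m.element_modulus, 20000.0)
        assert m.gauge_length == pytest.approx(3.0)

    def test_annulus_element_count_matches_mask(self):
        d = cylinder_density(4.0, 2.5, 3.0, 0.5)
        mask = d.data > 0
        m = build_fe_model(d)
        assert m.n_elements == int(mask.sum())

    def test_disconnected_gap_raises_nonunion_error(self):
        d = cylinder_density(4.0, 2.5, 6.0, 0.5)
        data = d.data.copy()
        data[:, :, 5:7] = 0.0  # transverse gap, no callus
        with pytest.raises(DiscontinuousStructureError):
            build_fe_model(DensityImage(data, 0.5))

    def test_floating_island_dropped(self):
        d = cylinder_density(4.0, 2.5, 6.0, 0.5)
        data = d.data.copy()
        n_before = int((data > 0).sum())
        data[0, 0, 3] = 900.0  # isolated voxel far from the annulus
        m = build_fe_model(DensityImage(data, 0.5))
        assert m.n_elements == n_before


@pytest.fixture(scope="module")
def small_cylinder_model():
    # 16 voxels across the outer diameter: coarse but fast
    d = cylinder_density(4.0, 2.5, 4.0, 0.5)
    return build_fe_model(d, MaterialModel())


class TestTorsion:
    def test_oracle_within_coarse_band(self, small_cylinder_model):
        res = simulate_torsion(small_cylinder_model, 1.0)
        exact = analytic_cylinder_vtr(20000.0, 0.3, 4.0, 2.5)
        # 8 voxels per radius: the staircase boundary costs several percent
        assert res.vtr == pytest.approx(exact, rel=0.10)

    def test_linearity_in_modulus(self, small_cylinder_model):
        m = small_cylinder_model
        res1 = simulate_torsion(m, 1.0)
        doubled = FEModel(
            m.spacing, m.element_nodes, m.node_coords, 2.0 * m.element_modulus,
            m.distal_nodes, m.proximal_nodes, m.gauge_length, m.poisson,
        )
        res2 = simulate_torsion(doubled, 1.0)
        assert res2.vtr == pytest.approx(2.0 * res1.vtr, rel=1e-9)

    def test_vtr_independent_of_applied_rotation(self, small_cylinder_model):
        r_half = simulate_torsion(small_cylinder_model, 0.5)
        r_two = simulate_torsion(small_cylinder_model, 2.0)
        assert r_half.vtr == pytest.approx(r_two.vtr, rel=1e-9)

    def test_rotation_sign_symmetry(self, small_cylinder_model):
        pos = simulate_torsion(small_cylinder_model, 1.0)
        neg = simulate_torsion(small_cylinder_model, -1.0)
        assert neg.reaction_torque == pytest.approx(-pos.reaction_torque, rel=1e-9)
        assert abs(neg.vtr) == pytest.approx(abs(pos.vtr), rel=1e-9)

    def test_stiffness_monotone_in_modulus(self):
        # raising any element modulus never decreases the rigidity
        rng = np.random.default_rng(0)
        base = rng.uniform(600.0, 1200.0, size=(3, 3, 4))
        d = DensityImage(base, 1.0)
        m = build_fe_model(d)
        vtr0 = simulate_torsion(m).vtr
        for _ in range(5):
            bumped = m.element_modulus.copy()
            idx = rng.integers(0, bumped.size)
            bumped[idx] *= 1.0 + rng.uniform(0.1, 2.0)
            m2 = FEModel(
                m.spacing, m.element_nodes, m.node_coords, bumped,
                m.distal_nodes, m.proximal_nodes, m.gauge_length, m.poisson,
            )
            assert simulate_torsion(m2).vtr >= vtr0 - 1e-12


class TestMassStiffnessCoupling:
    def test_bigger_denser_callus_is_stiffer(self, small_geometry):
        # directional agreement: more and denser callus -> higher VTR
        from osteoquant import CallusSpec, make_tibia_scan

        vtrs = []
        for vol, rho in [(1.0, 674.0), (2.5, 762.0)]:
            scan = make_tibia_scan(small_geometry, CallusSpec(vol, rho), seed=5)
            d = DensityImage(scan.truth_density, scan.spacing)
            coarse = downsample_density(d, 0.8)
            model = build_fe_model(coarse)
            vtrs.append(simulate_torsion(model).vtr)
        assert vtrs[1] > vtrs[0]
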