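"""SAXS: Debye forward model, Guinier, p(r), mass, chi^2 fit, MC refinement."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from coldzyme import saxs
from coldzyme.saxs import (
    BeadStructure,
    MassInputs,
    MCConfig,
    SAXSCurve,
    ScatterFitParams,
)
from coldzyme.synthetic import gen_bead_dimer


def rigid_transform(coords, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return coords @ Q.T + rng.uniform(-50, 50, 3)


class TestDebye:
    def test_single_bead_flat_curve(self):
        b = BeadStructure(coords=[[0.0, 0.0, 0.0]], weights=[2.0])
        p = ScatterFitParams(scale=3.0, rho_hydration=0.2, background=0.5)
        w = saxs.effective_weights(b, 0.2)[0]
        c = saxs.debye_intensity(b, [0.01, 0.1, 0.3], p)
        assert np.allclose(c.I, 3.0 * w**2 + 0.5)

    def test_two_bead_closed_form(self):
        d = 10.0
        b = BeadStructure(coords=[[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 0.3, 30)
        c = saxs.debye_intensity(b, q, ScatterFitParams(1.0, 0.2, 0.0))
        w = saxs.effective_weights(b, 0.2)[0]
        expected = 2 * w**2 * (1 + np.sin(q * d) / (q * d))
        assert np.allclose(c.I, expected, rtol=1e-12)

    def test_rigid_invariance(self):
        b, _ = gen_bead_dimer(bead_spacing=14.0)
        q = np.linspace(0.01, 0.3, 40)
        c1 = saxs.debye_intensity(b, q)
        c2 = saxs.debye_intensity(replace(b, coords=rigid_transform(b.coords)), q)
        assert np.max(np.abs(c1.I - c2.I) / c1.I) < 1e-10

    def test_forward_intensity_dominates(self):
        b, _ = gen_bead_dimer(bead_spacing=14.0)
        q = np.linspace(0.005, 0.3, 50)
        c = saxs.debye_intensity(b, q)
        assert np.argmax(c.I) == 0

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            BeadStructure(coords=np.empty((0, 3)))


class TestGuinier:
    def test_exact_gaussian_curve(self):
        q = np.linspace(0.005, 0.05, 60)
        I = 7.0 * np.exp(-(q**2) * 43.0**2 / 3.0)
        rg, i0, res = saxs.guinier_fit(SAXSCurve(q=q, I=I))
        assert rg == pytest.approx(43.0, rel=1e-6)
        assert i0 == pytest.approx(7.0, rel=1e-6)

    def test_dimer_sized_state(self):
        # the 25 C native state: Rg 4.3 nm
        q = np.linspace(0.006, 0.06, 50)
        I = 0.16 * np.exp(-(q**2) * 43.0**2 / 3.0)
        rg, _, _ = saxs.guinier_fit(SAXSCurve(q=q, I=I))
        assert rg / 10.0 == pytest.approx(4.3, abs=0.01)

    def test_aggregation_warning_on_upturn(self):
        q = np.linspace(0.005, 0.06, 60)
        I = np.exp(-(q**2) * 30.0**2 / 3.0) + 0.5 * np.exp(-(q**2) * 300.0**2 / 3.0)
        rg, _, res = saxs.guinier_fit(SAXSCurve(q=q, I=I))
        assert "aggregation" in res.message


class TestPrInvert:
    def test_two_bead_pr_peaks_at_distance(self):
        d = 30.0
        b = BeadStructure(coords=[[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 0.6, 150)
        c = saxs.debye_intensity(b, q)
        pr = saxs.pr_invert(c, Dmax=60.0, alpha=1e-3)
        # the bead self-terms contribute a spike near r = 0; the
        # cross-term peak must sit at the bead separation
        cross = pr.r > 0.15 * 60.0
        peak_r = pr.r[cross][np.argmax(pr.pr[cross])]
        assert peak_r == pytest.approx(d, abs=3.0)

    def test_sphere_rg_within_three_percent(self):
        from coldzyme.synthetic import _sphere_grid

        R = 20.0
        b = BeadStructure(coords=_sphere_grid(np.zeros(3), R, 2.5))
        q = np.linspace(0.01, 0.35, 120)
        c = saxs.debye_intensity(b, q)
        pr = saxs.pr_invert(c, Dmax=2.2 * R, alpha=1e-3)
        assert pr.Rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.03)

    def test_zero_intensity_gives_zero_pr(self):
        q = np.linspace(0.01, 0.3, 50)
        pr = saxs.pr_invert(SAXSCurve(q=q, I=np.zeros(50)), Dmax=50.0)
        assert np.allclose(pr.pr, 0.0)
        assert pr.Rg == 0.0

    def test_nonnegative_and_pinned_endpoints(self):
        b, c = gen_bead_dimer(bead_spacing=12.0, q_grid=np.linspace(0.01, 0.3, 100))
        pr = saxs.pr_invert(c, Dmax=140.0)
        assert np.all(pr.pr >= 0)
        assert pr.pr[0] == 0.0 and pr.pr[-1] == 0.0


class TestI0Consistency:
    def test_three_routes_agree(self):
        b, _ = gen_bead_dimer(bead_spacing=12.0)
        q = np.linspace(0.004, 0.25, 150)
        c = saxs.debye_intensity(b, q, ScatterFitParams(1e-6, 0.2, 0.0))
        w = saxs.effective_weights(b, 0.2)
        i0_debye = 1e-6 * float(np.sum(w)) ** 2
        rg, i0_guinier, _ = saxs.guinier_fit(c)
        pr = saxs.pr_invert(c, Dmax=150.0, alpha=1e-3)
        assert i0_guinier == pytest.approx(i0_debye, rel=0.02)
        assert pr.I0 == pytest.approx(i0_debye, rel=0.02)


class TestMass:
    def test_inversion_of_printed_dimer_mass(self):
        M, n = saxs.mass_from_i0(MassInputs(I0=0.1612, c=1.15e-3), monomer_mass=119130.0)
        assert M == pytest.approx(211e3, rel=0.005)

    def test_monomer_counts_match_reported_values(self):
        # 211 kDa -> 1.7 +/- 0.2 monomers; 1994 kDa -> 17 +/- 2
        _, n_dimer = saxs.mass_from_i0(
            MassInputs(I0=0.1612, c=1.15e-3), monomer_mass=119130.0
        )
        assert n_dimer == pytest.approx(1.7, abs=0.2)
        n_agg = 1994e3 / 119.13e3
        assert round(n_agg) == 17

    def test_linear_in_i0_and_inverse_in_c(self):
        m1 = saxs.mass_from_i0(MassInputs(I0=0.1, c=1e-3))
        m2 = saxs.mass_from_i0(MassInputs(I0=0.2, c=1e-3))
        m3 = saxs.mass_from_i0(MassInputs(I0=0.1, c=2e-3))
        assert m2 == pytest.approx(2 * m1)
        assert m3 == pytest.approx(m1 / 2)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            MassInputs(I0=0.1, c=0.0)


class TestQWindows:
    def test_flat_curve_equal_metrics(self):
        q = np.linspace(0.005, 0.3, 200)
        c = SAXSCurve(q=q, I=np.full(200, 2.0))
        low, mid = saxs.q_window_summary(c)
        assert low == pytest.approx(mid)

    def test_linearity(self):
        b, c = gen_bead_dimer(bead_spacing=12.0, q_grid=np.linspace(0.005, 0.3, 200))
        low1, mid1 = saxs.q_window_summary(c)
        c2 = SAXSCurve(q=c.q, I=2 * c.I)
        low2, mid2 = saxs.q_window_summary(c2)
        assert low2 == pytest.approx(2 * low1) and mid2 == pytest.approx(2 * mid1)

    def test_aggregation_signature(self):
        # growing mass raises low-q; loss of internal structure dims mid-q
        q = np.linspace(0.005, 0.3, 200)
        native = SAXSCurve(q=q, I=1.0 * np.exp(-(q * 43) ** 2 / 3) + 0.05 * np.exp(-(q * 8) ** 2))
        aggregated = SAXSCurve(q=q, I=5.0 * np.exp(-(q * 80) ** 2 / 3) + 0.01 * np.exp(-(q * 8) ** 2))
        low_n, mid_n = saxs.q_window_summary(native)
        low_a, mid_a = saxs.q_window_summary(aggregated)
        assert low_a > low_n
        assert mid_a < mid_n

    def test_empty_window_rejected(self):
        q = np.linspace(0.05, 0.3, 100)
        c = SAXSCurve(q=q, I=np.ones(100))
        with pytest.raises(ValueError):
            saxs.q_window_summary(c, low_window=(0.001, 0.002))


class TestChi2Fit:
    def test_self_fit_is_near_zero(self):
        b, c = gen_bead_dimer(bead_spacing=12.0, q_grid=np.linspace(0.01, 0.25, 80))
        _, chi2 = saxs.chi2_fit(b, c)
        assert chi2 < 1e-10

    def test_unit_noise_gives_reduced_chi2_near_one(self):
        q = np.linspace(0.01, 0.3, 400)
        b, c = gen_bead_dimer(bead_spacing=12.0, q_grid=q)
        rng = np.random.default_rng(3)
        sig = 0.02 * c.I
        noisy = SAXSCurve(q=q, I=c.I + rng.normal(0, 1, q.size) * sig, sigma=sig)
        _, chi2 = saxs.chi2_fit(b, noisy)
        assert chi2 == pytest.approx(1.0, abs=0.2)

    def test_wrong_structure_scores_worse(self):
        q = np.linspace(0.01, 0.25, 80)
        b, c = gen_bead_dimer(bead_spacing=12.0, q_grid=q)
        _, chi2_true = saxs.chi2_fit(b, c)
        rng = np.random.default_rng(17)
        for _ in range(20):
            mask = b.parts == 0
            shift = rng.uniform(5, 20, 3)
            coords = b.coords.copy()
            coords[mask] += shift
            _, chi2_wrong = saxs.chi2_fit(replace(b, coords=coords), c)
            assert chi2_wrong > chi2_true

    def test_missing_sigma_warns(self):
        q = np.linspace(0.01, 0.25, 50)
        b, c = gen_bead_dimer(bead_spacing=14.0, q_grid=q)
        with pytest.warns(UserWarning, match="unweighted"):
            saxs.chi2_fit(b, SAXSCurve(q=q, I=c.I))


def nearest_anchor(structure, p, q):
    A = np.where(structure.parts == p)[0]
    B = np.where(structure.parts == q)[0]
    d = cdist(structure.coords[A], structure.coords[B])
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return int(A[i]), int(B[j])


@pytest.fixture(scope="module")
def dimer():
    structure, curve = gen_bead_dimer(
        bead_spacing=12.0, q_grid=np.linspace(0.01, 0.25, 80)
    )
    anchors = [nearest_anchor(structure, 0, 1), nearest_anchor(structure, 1, 2)]
    return structure, curve, anchors


class TestRigidBodyMC:

    def test_start_at_target_stays_converged(self, dimer):
        structure, curve, anchors = dimer
        cfg = MCConfig(n_steps=20, n_runs=2, anchors=anchors, seed=1)
        _, best_chi2, _ = saxs.rigid_body_mc(structure, curve, cfg)
        assert np.all(best_chi2 < 1e-6)

    def test_best_objective_non_increasing(self, dimer):
        structure, curve, anchors = dimer
        pert = replace(structure, coords=structure.coords + 0.0)
        coords = pert.coords.copy()
        coords[pert.parts == 0] += np.array([4.0, 2.0, 0.0])
        pert = replace(pert, coords=coords)
        cfg = MCConfig(n_steps=30, n_runs=1, anchors=anchors, seed=2)
        _, _, traces = saxs.rigid_body_mc(pert, curve, cfg)
        best_so_far = np.minimum.accumulate(traces[0])
        assert np.all(np.diff(best_so_far) <= 1e-12)

    def test_bit_stable_given_seed(self, dimer):
        structure, curve, anchors = dimer
        coords = structure.coords.copy()
        coords[structure.parts == 2] += np.array([0.0, 3.0, 1.0])
        pert = replace(structure, coords=coords)
        cfg = MCConfig(n_steps=15, n_runs=2, anchors=anchors, seed=7)
        r1, c1, t1 = saxs.rigid_body_mc(pert, curve, cfg)
        r2, c2, t2 = saxs.rigid_body_mc(pert, curve, cfg)
        assert np.array_equal(r1.coords, r2.coords)
        assert np.array_equal(c1, c2)

    def test_anchor_within_one_part_rejected(self, dimer):
        structure, curve, _ = dimer
        ids = np.where(structure.parts == 0)[0][:2]
        cfg = MCConfig(anchors=[(int(ids[0]), int(ids[1]))])
        with pytest.raises(ValueError, match="different parts"):
            saxs.rigid_body_mc(structure, curve, cfg)


class TestSuperpose:
    def test_identity(self):
        b, _ = gen_bead_dimer(bead_spacing=14.0)
        assert saxs.superpose_rmsd(b, b) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self):
        b, _ = gen_bead_dimer(bead_spacing=14.0)
        moved = replace(b, coords=rigid_transform(b.coords, seed=4))
        assert saxs.superpose_rmsd(b, moved) == pytest.approx(0.0, abs=1e-8)

    def test_single_displaced_bead_closed_form(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, (100, 3))
        A = BeadStructure(coords=coords)
        # displacing one bead changes the RMSD by sqrt(d^2/N) up to the
        # (small) re-superposition correction
        coords2 = coords.copy()
        coords2[0] += np.array([10.0, 0.0, 0.0])
        B = BeadStructure(coords=coords2)
        assert saxs.superpose_rmsd(A, B) == pytest.approx(1.0, abs=0.05)

    def test_size_mismatch(self):
        A = BeadStructure(coords=np.zeros((3, 3)))
        B = BeadStructure(coords=np.zeros((4, 3)))
        with pytest.raises(ValueError):
            saxs.superpose_rmsd(A, B)
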