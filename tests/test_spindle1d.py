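import numpy as np
import pytest
from dataclasses import replace

import spindlecortex as sc


DOM = sc.Domain1D(80.0, periodic=True)


class TestMicrotubuleModel:
    def test_exponential_normalization_and_mean(self, mt):
        u = np.linspace(0, 25, 2001)
        assert np.trapezoid(mt.pdf(u), u) == pytest.approx(1.0, rel=1e-3)
        # truncated-exponential mean < nominal scale
        assert 0 < mt.mean_length < 6.0
        assert mt.pdf(25.0) == 0.0

    def test_signed_end_density_is_odd_and_unit_mass(self, mt):
        u = np.linspace(-25, 25, 4001)
        p = mt.signed_end_density(u)
        assert np.allclose(p, -mt.signed_end_density(-u))
        assert np.trapezoid(np.abs(p), u) == pytest.approx(1.0, rel=5e-3)

    def test_survival_monotone_with_correct_limits(self, mt):
        d = np.linspace(0, 25, 200)
        s = mt.survival(d)
        assert s[0] == pytest.approx(1.0)
        assert s[-1] == 0.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_from_histogram_matches_bin_masses(self):
        edges = np.array([0.0, 2.0, 5.0, 10.0])
        counts = np.array([10.0, 30.0, 10.0])
        model = sc.MicrotubuleModel.from_histogram(edges, counts)
        u = np.linspace(0, 10, 4001)
        total = np.trapezoid(model.pdf(u), u)
        assert total == pytest.approx(1.0, rel=1e-3)
        mid = np.trapezoid(model.pdf(np.linspace(2.001, 4.999, 1001)),
                           np.linspace(2.001, 4.999, 1001))
        assert mid == pytest.approx(0.6, rel=2e-2)


class TestDnaVelocity:
    def test_uniform_field_gives_zero(self, mt):
        field = sc.CortexField(DOM, np.ones(DOM.n_nodes))
        spindle = sc.MonopolarSpindle(dna_center=40.0, v0=6.7)
        assert sc.dna_velocity(field, spindle, mt) == pytest.approx(0.0, abs=1e-12)

    def test_step_contrast_gives_v0_times_epsilon(self, mt):
        # c̄ = 1 + ε sign(x - xc): the force integral reduces to v0 ε
        eps, xc = 0.05, 40.1  # off-node centrosome
        u = (DOM.x - xc + 40.0) % 80.0 - 40.0
        field = sc.CortexField(DOM, 1.0 + eps * np.sign(u))
        spindle = sc.MonopolarSpindle(dna_center=xc, v0=6.7)
        v = sc.dna_velocity(field, spindle, mt)
        assert v == pytest.approx(6.7 * eps, rel=1e-2)

    def test_mirror_reflection_negates_velocity(self, mt):
        rng = np.random.default_rng(6)
        c = rng.uniform(0.5, 1.5, DOM.n_nodes)
        xc = 25.3
        field = sc.CortexField(DOM, c)
        spindle = sc.MonopolarSpindle(dna_center=xc, v0=6.7)
        v = sc.dna_velocity(field, spindle, mt)
        # mirror about x = 0: c(x) -> c(-x), xc -> -xc
        x_ref = (-DOM.x) % 80.0
        c_ref = np.interp(x_ref, DOM.x, c, period=80.0)
        field_ref = sc.CortexField(DOM, c_ref)
        spindle_ref = sc.MonopolarSpindle(dna_center=(-xc) % 80.0, v0=6.7)
        v_ref = sc.dna_velocity(field_ref, spindle_ref, mt)
        assert v_ref == pytest.approx(-v, rel=1e-9, abs=1e-12)


class TestMonopolarSimulation:
    def test_no_feedback_is_stationary(self, mt):
        kin = sc.LgnKinetics(koff_near=1 / 90, koff_far=1 / 90)
        spindle = sc.MonopolarSpindle(dna_center=40.0)
        res = sc.simulate_monopolar(kin, spindle, mt, DOM, T=450.0,
                                    perturbation=0.01, sample_interval=5.0)
        assert res.regime == "stationary"
        assert res.asymptotic_speed < 1e-3

    def test_defaults_reach_traveling_wave(self, traveling_run):
        assert traveling_run.regime == "traveling"
        assert traveling_run.asymptotic_speed > 0.05
        assert traveling_run.speed_cv < 0.05

    def test_symmetry_breaking_direction_follows_perturbation(self, kinetics, mt):
        spindle = sc.MonopolarSpindle(dna_center=40.0)
        final = {}
        for amp in (+0.05, -0.05):
            res = sc.simulate_monopolar(kinetics, spindle, mt, DOM, T=250.0,
                                        perturbation=amp, sample_interval=5.0)
            assert res.asymptotic_speed > 0.05
            final[amp] = np.sign(res.v[-1])
        assert final[+0.05] == 1.0
        assert final[-0.05] == -1.0

    def test_seeded_perturbation_growth_matches_linear_oracle(self, kinetics, mt):
        # small-time oracle: before the cortex responds, the velocity from a
        # frozen field c = 1 + A sin(2π(x - x0)/L) is the quadrature
        # v0 A ∫ sin(2π u / L) pMT(u) du
        A, x0 = 1e-3, 40.0
        u = (DOM.x - x0 + 40.0) % 80.0 - 40.0
        c = 1.0 + A * np.sin(2 * np.pi * u / 80.0)
        field = sc.CortexField(DOM, c)
        spindle = sc.MonopolarSpindle(dna_center=x0)
        v_model = sc.dna_velocity(field, spindle, mt)
        # dense quadrature of v0 ∫ ρ(u)/2 (c̄(x0+u) - c̄(x0-u)) du with the
        # analytic perturbation (independent of the solver's grid)
        u_dense = np.linspace(0.0, 20.0, 40001)
        mean_c = np.average(c, weights=DOM.node_weights)
        contrast = 2 * A * np.sin(2 * np.pi * u_dense / 80.0) / mean_c
        oracle = 6.7 * np.trapezoid(mt.pdf(u_dense) / 2 * contrast, u_dense)
        assert v_model == pytest.approx(oracle, rel=1e-3)
        assert v_model > 0  # growth direction set by the perturbation sign

    def test_traveling_wave_translates_rigidly(self, traveling_run, domain):
        res = traveling_run
        i1, i2 = int(0.85 * len(res.t)) - 1, len(res.t) - 1
        steps = (np.diff(res.xn) + 40.0) % 80.0 - 40.0
        disp = steps[i1:i2].sum()
        c1 = res.kymograph.intensity[:, i1]
        c2 = res.kymograph.intensity[:, i2]
        c1_shifted = np.interp((domain.x - disp) % 80.0, domain.x, c1,
                               period=80.0)
        rms = np.sqrt(np.mean((c2 - c1_shifted) ** 2)) / c2.mean()
        assert rms < 0.02

    def test_translation_equivariance(self, kinetics, mt):
        delta = 10.0  # whole multiple of dx keeps the comparison exact
        r1 = sc.simulate_monopolar(kinetics, sc.MonopolarSpindle(40.0), mt,
                                   DOM, T=60.0, perturbation=0.05,
                                   sample_interval=5.0)
        r2 = sc.simulate_monopolar(kinetics, sc.MonopolarSpindle(40.0 + delta),
                                   mt, DOM, T=60.0, perturbation=0.05,
                                   sample_interval=5.0)
        assert np.allclose((r2.xn - r1.xn) % 80.0, delta, atol=1e-8)
        shift = int(round(delta / DOM.spacing))
        assert np.allclose(r2.kymograph.intensity,
                           np.roll(r1.kymograph.intensity, shift, axis=0),
                           atol=1e-8)

    def test_parity_negates_velocities(self, kinetics, mt):
        # frame-by-frame parity over a horizon short enough that the
        # feedback instability does not amplify roundoff differences
        r1 = sc.simulate_monopolar(kinetics, sc.MonopolarSpindle(40.0), mt,
                                   DOM, T=20.0, perturbation=0.05,
                                   sample_interval=2.0)
        r2 = sc.simulate_monopolar(kinetics, sc.MonopolarSpindle(40.0), mt,
                                   DOM, T=20.0, perturbation=-0.05,
                                   sample_interval=2.0)
        assert np.allclose(r2.v, -r1.v, rtol=1e-6, atol=1e-9)

    def test_no_stable_rest_state_with_separated_centrosome(self, kinetics, mt):
        # start from the stationary cortex around the DNA with the centrosome
        # 4 μm away: the configuration immediately departs and keeps moving
        dna = sc.DnaRegion(center=40.0)
        ss = sc.steady_state_profile(dna, kinetics, DOM)
        spindle = sc.MonopolarSpindle(dna_center=40.0, offset=4.0)
        res = sc.simulate_monopolar(kinetics, spindle, mt, DOM, T=40.0,
                                    perturbation=0.0, init_field=ss,
                                    sample_interval=2.0)
        assert abs(res.v[0]) > 0.1
        assert np.min(np.abs(res.v[2:])) > 0.1  # never returns to rest

    def test_asymptotic_speed_converged_in_dx_and_dt(self, kinetics, mt):
        spindle = sc.MonopolarSpindle(dna_center=40.0)
        speeds = {}
        for dx, dt in ((0.2, 0.05), (0.1, 0.025)):
            dom = sc.Domain1D(80.0, dx=dx)
            res = sc.simulate_monopolar(kinetics, spindle, mt, dom, T=450.0,
                                        dt=dt, perturbation=0.05,
                                        sample_interval=5.0)
            speeds[dx] = res.asymptotic_speed
        assert speeds[0.1] == pytest.approx(speeds[0.2], rel=0.02)


class TestLineSimulation:
    def test_oscillatory_regime_with_end_avoidance(self, line_run):
        assert line_run.regime == "oscillatory"
        assert line_run.n_reversals >= 2
        # turning points within 15 μm of the line ends
        assert line_run.xn.min() < 15.0
        assert line_run.xn.max() > 45.0
        assert line_run.xn.min() > 0.0 and line_run.xn.max() < 60.0

    def test_speed_maximal_in_the_middle_third(self, line_run):
        pos, vel = sc.phase_portrait(line_run.trajectory(), 5)
        middle = (pos > 20.0) & (pos < 40.0)
        assert np.abs(vel[middle]).max() == pytest.approx(np.abs(vel).max())

    def test_no_feedback_line_is_stationary(self, mt):
        kin = sc.LgnKinetics(koff_near=1 / 90, koff_far=1 / 90)
        dom = sc.Domain1D(60.0, periodic=False)
        res = sc.simulate_on_line(kin, sc.MonopolarSpindle(30.0), mt, dom,
                                  T=450.0, perturbation=0.01,
                                  sample_interval=5.0)
        assert res.regime == "stationary"

    def test_rejects_short_line(self, kinetics, mt):
        dom = sc.Domain1D(8.0, periodic=False)
        with pytest.raises(ValueError, match="longer"):
            sc.simulate_on_line(kinetics, sc.MonopolarSpindle(4.0), mt, dom)


class TestImposedDna:
    def test_stationary_track_reaches_steady_state(self, kinetics, domain):
        t = np.arange(0, 60.0 + 1e-9, 3.0)
        track = sc.Trajectory(t, np.full_like(t, 40.0))
        dna = sc.DnaRegion(center=40.0)
        kymo = sc.simulate_imposed_dna(kinetics, track, domain, dna=dna,
                                       normalization="raw")
        ss = sc.steady_state_profile(dna, kinetics, domain)
        err = np.max(np.abs(kymo.intensity[:, -1] - ss.c)) / ss.c.max()
        assert err < 1e-3

    def test_depletion_trail_shallower_at_higher_speed(self, kinetics, domain):
        depth = {}
        for v in (1.0, 3.0):
            t = np.arange(0, 120.0 + 1e-9, 3.0)
            track = sc.Trajectory(t, np.mod(v * t, 80.0))
            kymo = sc.simulate_imposed_dna(kinetics, track, domain,
                                           dna=sc.DnaRegion(center=0.0),
                                           normalization="global-mean")
            depth[v] = 1.0 - kymo.intensity[:, -1].min()
        assert depth[3.0] < depth[1.0]

    def test_self_consistency_with_coupled_run(self, kinetics, mt,
                                               monopolar_frames_run, domain):
        res = monopolar_frames_run
        init = sc.uniform_field(domain, kinetics)
        u = (domain.x - 40.0 + 40.0) % 80.0 - 40.0
        amp = res.params["perturbation"]
        init = sc.CortexField(
            domain, init.c * (1.0 + amp * np.sin(2 * np.pi * u / 80.0)))
        kymo = sc.simulate_imposed_dna(kinetics, res.trajectory(), domain,
                                       dna=sc.DnaRegion(center=40.0),
                                       init=init, normalization="raw")
        rms = np.sqrt(np.mean((kymo.intensity
                               - res.kymograph.intensity) ** 2))
        assert rms / res.kymograph.intensity.mean() < 0.01

    def test_track_outside_domain_rejected(self, kinetics):
        dom = sc.Domain1D(60.0, periodic=False)
        track = sc.Trajectory([0.0, 3.0], [30.0, 70.0])
        with pytest.raises(ValueError, match="domain"):
            sc.simulate_imposed_dna(kinetics, track, dom)


class TestBipolar1D:
    def test_symmetric_state_is_exactly_stationary(self, mt):
        kin, spindle, dna, dom = sc.bipolar_moving_setup()
        res = sc.simulate_bipolar_1d(kin, spindle, mt, dom, T=50.0, dna=dna,
                                     perturbation=0.0, sample_interval=5.0)
        assert np.abs(res.xn - res.xn[0]).max() < 1e-9
        assert res.asymptotic_speed < 1e-9

    def test_no_feedback_perturbation_decays(self, mt):
        _, spindle, dna, dom = sc.bipolar_moving_setup()
        kin = sc.LgnKinetics(koff_near=1 / 90, koff_far=1 / 90)
        res = sc.simulate_bipolar_1d(kin, spindle, mt, dom, T=450.0, dna=dna,
                                     perturbation=0.05, sample_interval=5.0)
        assert res.asymptotic_speed < 0.05

    def test_shipped_parameter_set_yields_moving_state(self, mt):
        kin, spindle, dna, dom = sc.bipolar_moving_setup()
        res = sc.simulate_bipolar_1d(kin, spindle, mt, dom, T=450.0, dna=dna,
                                     perturbation=0.05, sample_interval=5.0)
        assert res.regime == "traveling"
        assert res.asymptotic_speed > 0.05
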