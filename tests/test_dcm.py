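"""Bilinear DCM: model grid, integrator, inversion, selection, summaries."""

import numpy as np
import pytest

from mionpipe import dcm, synth
from mionpipe.dcm import INPUTS, NODES


@pytest.fixture(scope="module")
def designs():
    return [
        synth.make_design("GB", seed=1, n_cycles=1),
        synth.make_design("NF", seed=2, n_cycles=1),
    ]


@pytest.fixture(scope="module")
def gen_model():
    return dcm.enumerate_models()[0]     # temporal input, simple self-mod


class TestModelGrid:
    def test_nine_models(self):
        models = dcm.enumerate_models()
        assert len(models) == 9
        assert len({m.name for m in models}) == 9
        schemes = {(m.input_scheme, m.self_mod_scheme) for m in models}
        assert len(schemes) == 9

    def test_temporal_input_contralateral(self):
        m = next(x for x in dcm.enumerate_models() if x.name == "temporal/simple")
        targets = {i for i, _ in m.c_entries}
        assert targets == {NODES.index("temporal_L"), NODES.index("temporal_R")}
        for node, u in m.c_entries:
            hemi = INPUTS[u].rsplit("_", 1)[1]
            # left-hemifield input drives the right-hemisphere node
            assert NODES[node].endswith("R" if hemi == "left" else "L")

    def test_simple_scheme_no_self_modulation(self):
        for m in dcm.enumerate_models():
            diag = [e for e in m.b_entries if e[1] == e[2]]
            if m.self_mod_scheme == "simple":
                assert diag == []
            elif m.self_mod_scheme == "GN":
                assert len(diag) == 16
            else:
                assert len(diag) == 32

    def test_shared_a_mask_and_gn_modulation(self):
        models = dcm.enumerate_models()
        masks = {m.a_off for m in models}
        assert len(masks) == 1           # same fixed connectivity everywhere
        for m in models:
            inter = {e for e in m.b_entries if e[1] != e[2]}
            mods = {INPUTS[u] for u, _, _ in inter}
            assert mods == {"good_left", "good_right", "novel_left", "novel_right"}
            assert {(i, j) for _, i, j in inter} == set(m.a_off)


class TestSimulate:
    def test_no_drive_zero_output(self, gen_model, designs):
        theta = gen_model.prior_mean()
        base = 4 + len(gen_model.a_off) + len(gen_model.b_entries)
        theta[base:-1] = 0.0             # C = 0
        y = dcm.simulate_dcm(gen_model, theta, designs)
        assert np.abs(y).max() < 1e-12

    def test_scalar_node_exponential_approach(self):
        # one node, A = -1, constant unit input: z(t) -> 1
        m = dcm.DcmModel(
            name="scalar", input_scheme="temporal", self_mod_scheme="simple",
            a_off=(), b_entries=(), c_entries=((0, 0),),
        )
        # constant input: a design whose every block drives input 0 is not
        # expressible, so integrate the neural ODE directly via the kernel
        from mionpipe.dcm import _integrate

        n_vols, n_sub, dt = 40, 16, 0.15625
        M_stack = np.array([[[-1.0]]])
        cu = np.array([[1.0]])
        idx = np.zeros(n_vols * n_sub, np.int64)
        out = _integrate(M_stack, cu, idx, n_vols, n_sub, dt, 1.0)
        # volume v responds to z; check the neural fixed point through a
        # fresh integration of z only: analytic z(T) = 1 - exp(-T)
        T = n_vols * n_sub * dt
        assert T > 60
        # closed form: z -> 1, so flow settles at f = 1 + z/gamma and
        # volume at v = f^alpha; readout is -eps*(v-1)
        f_ss = 1.0 + 1.0 / dcm.GAMMA
        expected = -(f_ss**dcm.ALPHA - 1.0)
        assert out[-1, 0] == pytest.approx(expected, abs=1e-3)
        assert abs(out[-1, 0] - out[-2, 0]) < 1e-4

    def test_unstable_system_rejected(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=0)
        theta[4:8] = 2.0                 # huge reciprocal excitation
        with pytest.raises(ValueError, match="unstable"):
            dcm.simulate_dcm(gen_model, theta, designs)

    def test_step_halving_convergence(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=1)
        y16 = dcm.simulate_dcm(gen_model, theta, designs, n_sub=16)
        y32 = dcm.simulate_dcm(gen_model, theta, designs, n_sub=32)
        rel = np.abs(y16 - y32).max() / np.abs(y32).max()
        # RK4 at the default TR/16 step leaves a few-1e-6 discretization
        # residual for these dynamics; halving must stay within that scale
        assert rel < 5e-6

    def test_rk4_convergence_order(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=2)
        ref = dcm.simulate_dcm(gen_model, theta, designs, n_sub=1024)
        errs = []
        subs = [16, 32, 64, 128]     # asymptotic regime for these dynamics
        for n_sub in subs:
            y = dcm.simulate_dcm(gen_model, theta, designs, n_sub=n_sub)
            errs.append(np.abs(y - ref).max())
        slopes = np.diff(np.log(errs)) / np.diff(np.log([1 / s for s in subs]))
        assert abs(slopes.mean() - 4.0) < 0.3

    def test_seeded_noise_reproducible(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=3)
        a = dcm.simulate_dcm(gen_model, theta, designs, seed=9, snr=5)
        b = dcm.simulate_dcm(gen_model, theta, designs, seed=9, snr=5)
        assert np.array_equal(a, b)


class TestFit:
    def test_noise_free_self_inversion(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=4)
        data = dcm.simulate_dcm(gen_model, theta, designs)
        fit = dcm.fit_dcm(data, gen_model, designs, seed=0, n_starts=2, maxiter=200)
        assert fit.converged
        assert np.abs(fit.theta - theta).max() < 1e-2

    def test_data_length_precondition(self, gen_model, designs):
        with pytest.raises(ValueError, match="free parameters"):
            dcm.fit_dcm(np.zeros((10, 4)), gen_model, designs)

    def test_posterior_covariance_psd(self, gen_model, designs):
        theta = dcm.example_parameters(gen_model, seed=5)
        data = dcm.simulate_dcm(gen_model, theta, designs, seed=11, snr=5)
        fit = dcm.fit_dcm(data, gen_model, designs, seed=0, n_starts=1, maxiter=30)
        assert np.isfinite(fit.log_evidence)
        assert np.linalg.eigvalsh(fit.posterior_cov).min() > -1e-10


class TestSelection:
    def test_dominant_evidence_probability_one(self, gen_model):
        fits = []
        for i, ev in enumerate([0.0, -30.0, -40.0]):
            f = dcm.DcmFit(
                model=dcm.enumerate_models()[i], theta=np.zeros(1),
                log_evidence=ev, fitted=np.zeros((1, 4)), sigma2=1.0,
            )
            fits.append(f)
        best, table = dcm.model_select(fits)
        assert best.log_evidence == 0.0
        assert table[best.model.name]["probability"] > 0.999

    def test_tie_prefers_fewer_parameters(self):
        models = dcm.enumerate_models()
        rich = max(models, key=lambda m: m.n_free)
        slim = min(models, key=lambda m: m.n_free)
        fits = [
            dcm.DcmFit(model=rich, theta=np.zeros(1), log_evidence=5.0,
                       fitted=np.zeros((1, 4)), sigma2=1.0),
            dcm.DcmFit(model=slim, theta=np.zeros(1), log_evidence=5.0,
                       fitted=np.zeros((1, 4)), sigma2=1.0),
        ]
        best, table = dcm.model_select(fits)
        assert best.model is slim
        probs = [v["probability"] for v in table.values()]
        assert np.allclose(probs, 0.5)

    def test_flagged_fits_excluded(self, gen_model):
        good = dcm.DcmFit(model=gen_model, theta=np.zeros(1), log_evidence=1.0,
                          fitted=np.zeros((1, 4)), sigma2=1.0)
        bad = dcm.DcmFit(model=gen_model, theta=np.zeros(1), log_evidence=9.0,
                         fitted=np.zeros((1, 4)), sigma2=1.0, converged=False)
        with pytest.warns(UserWarning, match="flagged"):
            best, _ = dcm.model_select([good, bad])
        assert best is good

    def test_occam_prefers_simple_on_noise(self, designs):
        models = dcm.enumerate_models()
        simple = models[0]               # temporal/simple (33 free)
        rich = models[2]                 # temporal/GBNF (65 free)
        rng = np.random.default_rng(21)
        wins = 0
        for rep in range(3):
            noise = 0.05 * rng.standard_normal((192, 4))
            f_s = dcm.fit_dcm(noise, simple, designs, seed=rep, n_starts=1, maxiter=30)
            f_r = dcm.fit_dcm(noise, rich, designs, seed=rep, n_starts=1, maxiter=30)
            wins += f_s.log_evidence > f_r.log_evidence
        assert wins >= 2


class TestEdgeSummary:
    def test_zero_modulation_equals_a(self, gen_model):
        theta = dcm.example_parameters(gen_model, seed=6)
        base = 4 + len(gen_model.a_off)
        theta[base : base + len(gen_model.b_entries)] = 0.0
        fit = dcm.DcmFit(model=gen_model, theta=theta, log_evidence=0.0,
                         fitted=np.zeros((1, 4)), sigma2=1.0)
        out = dcm.summarize_edges(fit)
        A, _, _, _ = gen_model.build(theta)
        # with B=0 and left/right-symmetric A the averages equal the A entries
        assert out["weights"]["good"]["temporal->prefrontal:contra"] == pytest.approx(A[2, 0])
        assert out["weights"]["novel"]["prefrontal->temporal:ipsi"] == pytest.approx(A[0, 2])

    def test_symmetric_parameters_lossless_average(self, gen_model):
        theta = dcm.example_parameters(gen_model, seed=0)
        # example parameters are left/right symmetric up to jitter; force
        # exact symmetry for the forward edges
        A, B, _, _ = gen_model.build(theta)
        fit = dcm.DcmFit(model=gen_model, theta=theta, log_evidence=0.0,
                         fitted=np.zeros((1, 4)), sigma2=1.0)
        out = dcm.summarize_edges(fit)
        uidx = {name: i for i, name in enumerate(INPUTS)}
        manual = 0.5 * (
            (A[3, 1] + B[uidx["good_left"], 3, 1])
            + (A[2, 0] + B[uidx["good_right"], 2, 0])
        )
        assert out["weights"]["good"]["temporal->prefrontal:contra"] == pytest.approx(manual)

    def test_negative_feedback_sign_reported(self, gen_model):
        theta = dcm.example_parameters(gen_model, seed=7)
        fit = dcm.DcmFit(model=gen_model, theta=theta, log_evidence=0.0,
                         fitted=np.zeros((1, 4)), sigma2=1.0)
        out = dcm.summarize_edges(fit)
        # example truth plants inhibitory prefrontal->temporal feedback
        assert out["signs"]["good"]["prefrontal->temporal:contra"] == "-"
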