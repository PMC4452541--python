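"""Hill transfers, closed-form two-node covariance, motif trajectories, loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from induce.errors import InputError, StabilityError
from induce.langevin_core import NetworkModel, solve_lyapunov
from induce.motif_models import (
    ConstantTransfer,
    HillTransfer,
    MotifSpec,
    TwoNodeNoiseParams,
    detect_open_loop,
    hill_drive,
    hill_response,
    log_gain,
    motif_trajectory,
    two_node_covariance,
    var2_of_cov,
)
from induce.presets import example_design


class TestHillResponse:
    def test_half_maximal_at_K(self):
        h = HillTransfer(nu=3.0, K=2.0, n=1.7)
        assert hill_response(2.0, h) == pytest.approx(1.5)
        hr = HillTransfer(nu=3.0, K=2.0, n=1.7, repression=True)
        assert hill_response(2.0, hr) == pytest.approx(1.5)

    def test_saturation_limits(self):
        h = HillTransfer(nu=2.0, K=1.0, n=2.0)
        assert hill_response(0.0, h) == 0.0
        assert hill_response(1e9, h) == pytest.approx(2.0)
        hr = HillTransfer(nu=2.0, K=1.0, n=2.0, repression=True)
        assert hill_response(0.0, hr) == pytest.approx(2.0)
        assert hill_response(1e9, hr) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        # ν xⁿ/(Kⁿ+xⁿ) = 1·9/(1+9)
        assert hill_response(3.0, HillTransfer(nu=1.0, K=1.0, n=2.0)) == pytest.approx(0.9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            hill_response(-1.0, HillTransfer(nu=1.0, K=1.0, n=1.0))

    def test_invalid_parameters_rejected(self):
        for bad in ({"nu": 0.0}, {"K": -1.0}, {"n": 0.0}):
            kw = {"nu": 1.0, "K": 1.0, "n": 1.0, **bad}
            with pytest.raises(InputError):
                HillTransfer(**kw)

    def test_constant_transfer_is_flat(self):
        c = ConstantTransfer(level=2.5)
        assert hill_response(0.01, c) == hill_response(100.0, c) == 2.5
        assert log_gain(5.0, c, lam=3.0) == 0.0


def _numeric_log_gain(x, h, lam, rel=1e-6):
    """Central-difference d ln f / d ln x — the independent oracle."""
    lx = np.log(x)
    f = lambda u: np.log(hill_response(np.exp(u), h))
    return lam * (f(lx + rel) - f(lx - rel)) / (2 * rel)


class TestLogGain:
    @pytest.mark.parametrize("repression", [False, True])
    @pytest.mark.parametrize("x", [0.3, 2.0, 7.7])
    def test_matches_numerical_derivative(self, x, repression):
        h = HillTransfer(nu=4.0, K=2.0, n=2.5, repression=repression)
        lam = 1.7
        assert log_gain(x, h, lam) == pytest.approx(
            _numeric_log_gain(x, h, lam), rel=1e-6)

    def test_half_activation_value(self):
        h = HillTransfer(nu=1.0, K=2.0, n=3.0)
        assert log_gain(2.0, h, lam=2.0) == pytest.approx(2.0 * 3.0 / 2.0)
        hr = HillTransfer(nu=1.0, K=2.0, n=3.0, repression=True)
        assert log_gain(2.0, hr, lam=2.0) == pytest.approx(-2.0 * 3.0 / 2.0)

    def test_limits(self):
        h = HillTransfer(nu=1.0, K=1.0, n=2.0)
        assert log_gain(1e-9, h, lam=1.0) == pytest.approx(2.0)
        assert log_gain(1e9, h, lam=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_concentration_rejected(self):
        with pytest.raises(InputError):
            log_gain(0.0, HillTransfer(nu=1.0, K=1.0, n=1.0), 1.0)

    def test_half_activation_is_the_gain_midpoint(self):
        """The log-gain is monotone along the sweep and crosses half its
        supremum exactly at half-maximal activation (x = K) — the operating
        point where the connection strength is changing fastest per decade
        of source concentration."""
        h = HillTransfer(nu=1.0, K=1.0, n=2.0)
        xs = np.geomspace(1e-3, 1e3, 41)
        gains = log_gain(xs, h, 1.0)
        assert np.all(np.diff(gains) < 0)                     # monotone in x
        assert log_gain(1.0, h, 1.0) == pytest.approx(0.5 * 1.0 * 2.0)
        # steepest change of the gain per log-x sits at x = K
        dg = np.abs(np.diff(gains))
        assert abs(np.log(xs[np.argmax(dg)]) - np.log(h.K)) < np.log(10)


class TestTwoNodeCovariance:
    def test_disconnected_case(self):
        S = two_node_covariance(TwoNodeNoiseParams(alpha=0.3, beta=0.7, lam=2.0, k=0.0))
        assert S.cov(0, 1) == 0.0
        assert S.var(1) == pytest.approx(0.7)

    def test_unit_parameter_example(self):
        S = two_node_covariance(TwoNodeNoiseParams(alpha=1, beta=1, lam=1, k=1))
        np.testing.assert_allclose(S.Sigma0, [[1.0, 0.5], [0.5, 1.5]])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.01, 10), st.floats(0.0, 10), st.floats(0.05, 10),
           st.floats(-10, 10))
    def test_matches_lyapunov_solver(self, alpha, beta, lam, k):
        """Closed form equals the numeric Lyapunov solution (dual route)."""
        p = TwoNodeNoiseParams(alpha=alpha, beta=beta, lam=lam, k=k)
        q1 = np.sqrt(2 * lam * alpha)
        q2 = np.sqrt(2 * lam * beta)
        model = NetworkModel(A=[[-lam, 0.0], [k, -lam]], Q=np.diag([q1, q2]))
        S_num = solve_lyapunov(model).Sigma0
        S_cf = two_node_covariance(p).Sigma0
        np.testing.assert_allclose(S_cf, S_num, rtol=1e-10, atol=1e-12)

    def test_covariance_sign_follows_k(self):
        for k in (-3.0, -0.1, 0.1, 3.0):
            S = two_node_covariance(TwoNodeNoiseParams(1.0, 1.0, 1.0, k))
            assert np.sign(S.cov(0, 1)) == np.sign(k)


class TestVar2OfCov:
    def test_zero_covariance_gives_beta(self):
        assert var2_of_cov(0.0, alpha=2.0, beta=0.9) == pytest.approx(0.9)

    def test_consistency_with_closed_form(self):
        # α=1, β=1, k=1, λ=1 → σ₁₂=0.5, σ₂²=1.5
        assert var2_of_cov(0.5, 1.0, 1.0) == pytest.approx(1.5)

    def test_even_in_covariance(self):
        c = np.linspace(-2, 2, 11)
        np.testing.assert_array_equal(var2_of_cov(c, 1.3, 0.2),
                                      var2_of_cov(-c, 1.3, 0.2))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(InputError):
            var2_of_cov(0.1, alpha=0.0, beta=1.0)


class TestMotifTrajectory:
    def test_two_node_path_obeys_quadratic_law(self):
        """σ₁² constant and σ₂² = β + 2σ₁₂²/α exactly along the dose sweep."""
        m, d = example_design("two_node_activation")
        path = motif_trajectory(m, d.doses, d.dose_map(m))
        s12, s11, s22 = path.series()
        alpha = m.qs[0] ** 2 / (2 * m.lambdas[0])
        beta = m.qs[1] ** 2 / (2 * m.lambdas[1])
        assert np.ptp(s11) <= 1e-10 * np.abs(s11).max()
        np.testing.assert_allclose(s11, alpha, rtol=1e-10)
        np.testing.assert_allclose(s22, var2_of_cov(s12, alpha, beta), rtol=1e-10)

    def test_convergent_with_constant_third_node_reduces_to_two_node(self):
        """Pinning node 3 (no noise, flat edge) collapses the convergent
        motif onto the isolated-edge quadratic."""
        m3 = MotifSpec(
            kind="convergent", lambdas=[1.0, 1.0, 1.0], qs=[0.45, 0.20, 0.0],
            edges={(0, 1): HillTransfer(nu=5.0, K=1.0, n=2.0),
                   (2, 1): ConstantTransfer(level=1.0)},
        )
        drive = hill_drive({0: HillTransfer(nu=10.0, K=1.0, n=1.0)})
        doses = np.geomspace(0.01, 100, 15)
        path = motif_trajectory(
            m3, doses, lambda dz: {**drive(dz), 2: 1.0})
        s12, s11, s22 = path.series()
        alpha = 0.45 ** 2 / 2
        beta = 0.20 ** 2 / 2
        np.testing.assert_allclose(s11, alpha, rtol=1e-10)
        np.testing.assert_allclose(s22, var2_of_cov(s12, alpha, beta), rtol=1e-10)
        flag, _ = detect_open_loop(path)
        assert not flag

    def test_cascade_example_opens_loop(self):
        """Disparate stimulus sensitivities in a relay make the path
        multivalued in covariance — the unmeasured-source hallmark."""
        m, d = example_design("cascade")
        path = motif_trajectory(m, d.doses, d.dose_map(m))
        flag_target, score_target = detect_open_loop(path, which=1)
        flag_source, _ = detect_open_loop(path, which=0)
        assert flag_target and flag_source
        assert score_target > 0.1

    def test_gain_grid_peaks_at_K_crossing(self):
        """Along the dose sweep, |a₂₁| ≥ half-max exactly where the source
        mean crosses the edge's half-response constant."""
        m, d = example_design("two_node_activation")
        path = motif_trajectory(m, d.doses, d.dose_map(m))
        gains = np.array([abs(p.gains[(0, 1)]) for p in path.points])
        x1 = np.array([p.means[0] for p in path.points])
        K = m.edges[(0, 1)].K
        # activation gain is sigmoid-decreasing in x: half its sup at x=K
        idx = np.argmin(np.abs(x1 - K))
        sup = m.lambdas[1] * m.edges[(0, 1)].n
        assert gains[idx] == pytest.approx(sup / 2, rel=0.25)

    def test_missing_root_mean_rejected(self):
        m, d = example_design("convergent")
        with pytest.raises(InputError):
            motif_trajectory(m, d.doses, lambda dz: {0: 1.0})


class TestDetectOpenLoop:
    def _two_node_path(self, rng, n_doses=10):
        lam = float(rng.uniform(0.2, 3.0))
        m = MotifSpec(
            kind="two_node", lambdas=[lam, lam],
            qs=[float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.0, 0.5))],
            edges={(0, 1): HillTransfer(
                nu=float(rng.uniform(0.5, 10)), K=float(rng.uniform(0.1, 10)),
                n=float(rng.uniform(0.5, 4)),
                repression=bool(rng.integers(0, 2)))},
        )
        drive = hill_drive({0: HillTransfer(
            nu=float(rng.uniform(1, 50)), K=float(rng.uniform(0.1, 10)),
            n=float(rng.uniform(0.5, 2)))})
        doses = np.geomspace(0.001, 1000, n_doses)
        return motif_trajectory(m, doses, drive)

    def test_no_false_positives_on_random_two_node_paths(self, rng):
        """The isolated edge is single-valued: the detector must stay quiet
        over a large sample of random parameterizations."""
        for _ in range(1000):
            flag, _ = detect_open_loop(self._two_node_path(rng))
            assert not flag

    def test_retraced_quadratic_is_not_a_loop(self):
        m, d = example_design("two_node_activation")
        doses = np.concatenate([d.doses, d.doses[::-1]])  # out and back
        # monotone grid not required by the detector itself
        path = motif_trajectory(m, doses, d.dose_map(m))
        flag, _ = detect_open_loop(path)
        assert not flag

    def test_too_few_points_rejected(self):
        m, d = example_design("two_node_activation")
        path = motif_trajectory(m, d.doses[:3], d.dose_map(m))
        with pytest.raises(InputError):
            detect_open_loop(path)


class TestMotifSpecValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(InputError):
            MotifSpec(kind="loop", lambdas=[1, 1], qs=[1, 1],
                      edges={(0, 1): HillTransfer(1, 1, 1)})

    def test_edge_set_must_match_kind(self):
        with pytest.raises(InputError):
            MotifSpec(kind="cascade", lambdas=[1, 1, 1], qs=[1, 1, 1],
                      edges={(0, 1): HillTransfer(1, 1, 1)})

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(InputError):
            MotifSpec(kind="two_node", lambdas=[1, 0], qs=[1, 1],
                      edges={(0, 1): HillTransfer(1, 1, 1)})

    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_round_trip(self, tmp_path, ext):
        m, _ = example_design("cascade")
        path = tmp_path / f"motif.{ext}"
        m.save(path)
        back = MotifSpec.load(path)
        assert back.kind == m.kind
        np.testing.assert_allclose(back.lambdas, m.lambdas)
        np.testing.assert_allclose(back.qs, m.qs)
        assert back.edges == m.edges

    def test_trajectory_csv_export(self, tmp_path):
        m, d = example_design("two_node_activation")
        path = motif_trajectory(m, d.doses[:6], d.dose_map(m))
        df = path.to_frame()
        assert list(df.columns)[:4] == ["dose", "sigma12", "sigma1_sq", "sigma2_sq"]
        assert "a_21" in df.columns
        f = tmp_path / "traj.csv"
        df.to_csv(f, index=False)
        assert f.exists()
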