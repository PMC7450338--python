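import numpy as np
import pytest
from scipy.special import gamma

from cswolf import ConfigurationError, CuckooParams, levy_scale_coefficient
from cswolf.acs import acs_update, bsrw_abandon, levy_step, lfrw_update


def mantegna_oracle(lam):
    """Independent closed-form evaluation of the Mantegna coefficient."""
    return (
        gamma(1 + lam) * np.sin(np.pi * lam / 2) / (gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2))
    ) ** (1 / lam)


class TestLevyMachinery:
    def test_coefficient_matches_gamma_oracle(self):
        assert levy_scale_coefficient(1.5) == pytest.approx(mantegna_oracle(1.5), abs=1e-12)
        assert levy_scale_coefficient(1.5) == pytest.approx(0.696575, abs=1e-6)

    def test_coefficient_unity_at_lambda_one(self):
        assert levy_scale_coefficient(1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("lam", np.linspace(1.01, 2.0, 9))
    def test_coefficient_positive_finite(self, lam):
        c = levy_scale_coefficient(float(lam))
        assert np.isfinite(c) and c > 0

    def test_coefficient_out_of_range(self):
        with pytest.raises(ConfigurationError):
            levy_scale_coefficient(2.5)

    def test_step_heavy_tailed_vs_matched_normal(self, rng):
        lam = 1.5
        c = levy_scale_coefficient(lam)
        draws = np.array([levy_step(rng, lam, c) for _ in range(100_000)])
        iqr = np.subtract(*np.percentile(draws, [75, 25]))
        sigma = iqr / 1.349  # normal with the same interquartile range
        tail_levy = np.mean(np.abs(draws) > 10)
        from scipy.stats import norm

        tail_normal = 2 * norm.sf(10 / sigma)
        assert tail_levy > tail_normal


class TestWalks:
    def test_lfrw_fixed_point_at_best(self, unit_square, rng):
        x = np.array([0.4, 0.6])
        cand = lfrw_update(x, x.copy(), CuckooParams(), unit_square, rng)
        assert np.array_equal(cand, x)

    def test_lfrw_hand_displacement(self, unit_square, monkeypatch):
        # Levy draw pinned to 2: displacement alpha0 * 2 * (x - best)
        import cswolf.acs as acs_mod

        monkeypatch.setattr(acs_mod, "levy_step", lambda rng, lam, c: 2.0)
        x = np.array([0.5, 0.5])
        best = np.array([-0.5, 1.5])
        cand = acs_mod.lfrw_update(x, best, CuckooParams(), unit_square, None)
        assert cand == pytest.approx([0.52, 0.48])

    def test_lfrw_respects_bounds(self, unit_square, rng):
        params = CuckooParams(alpha0=50.0)
        for _ in range(50):
            x = rng.uniform(size=2)
            cand = lfrw_update(x, rng.uniform(size=2), params, unit_square, rng)
            assert np.all(cand >= 0) and np.all(cand <= 1)

    def test_acs_update_fixed_points(self, unit_square, rng):
        x = np.array([0.3, 0.7])
        assert np.array_equal(acs_update(x, x.copy(), 0.9, unit_square, rng), x)
        assert np.array_equal(acs_update(x, np.zeros(2), 0.0, unit_square, rng), x)

    def test_acs_update_hand_displacement(self, unit_square):
        class OnesRng:
            def standard_normal(self, shape):
                return np.ones(shape)

        x = np.array([1.0, 0.0])
        gbest = np.array([-1.0, 2.0])
        # displacement = 1 * 0.5 * (x - gbest) = (1, -1), clipped to the unit box
        cand = acs_update(x, gbest, 0.5, unit_square, OnesRng())
        assert cand == pytest.approx([1.0, 0.0])

    def test_acs_displacement_scales_linearly_with_step(self, unit_square):
        class FixedRng:
            def __init__(self):
                self.vals = np.array([0.1, -0.2])

            def standard_normal(self, shape):
                return self.vals

        x = np.array([0.6, 0.4])
        gbest = np.array([0.5, 0.5])
        d1 = acs_update(x, gbest, 0.1, unit_square, FixedRng()) - x
        d2 = acs_update(x, gbest, 0.2, unit_square, FixedRng()) - x
        assert d2 == pytest.approx(2 * d1)

    def test_bsrw_zero_probability_is_identity(self, unit_square, rng):
        positions = rng.uniform(size=(5, 2))
        cand = bsrw_abandon(0, positions, 0.0, unit_square, rng)
        assert np.array_equal(cand, positions[0])

    def test_bsrw_full_mixing(self, unit_square):
        class Pinned:
            """a=1, b=2, s=1, full mask."""

            def choice(self, others, size, replace):
                return np.array([others[0], others[1]])

            def uniform(self, size=None):
                return np.zeros(size) if size is not None else 1.0 - 1e-12

        positions = np.array([[0.5, 0.5], [0.8, 0.1], [0.2, 0.3], [0.9, 0.9]])
        cand = bsrw_abandon(0, positions, 1.0, unit_square, Pinned())
        expected = positions[0] + (1.0 - 1e-12) * (positions[1] - positions[2])
        assert cand == pytest.approx(np.clip(expected, 0, 1))

    def test_bsrw_requires_three_agents(self, unit_square, rng):
        with pytest.raises(ConfigurationError):
            bsrw_abandon(0, rng.uniform(size=(2, 2)), 0.25, unit_square, rng)

    def test_bsrw_empirical_mutation_rate(self, unit_square, rng):
        """Per-dimension mutation frequency tracks p_a within 3 binomial SEs."""
        p_a = 0.25
        n_calls = 10_000
        positions = np.array([[0.5, 0.5], [0.8, 0.1], [0.2, 0.3], [0.9, 0.9]])
        mutated = 0
        for _ in range(n_calls):
            cand = bsrw_abandon(0, positions, p_a, unit_square, rng)
            mutated += int(np.sum(cand != positions[0]))
        total = n_calls * positions.shape[1]
        se = np.sqrt(p_a * (1 - p_a) / total)
        # s=0 or coincident donors can mask a mutated coordinate, so the
        # observed rate can only fall below p_a, never above
        assert mutated / total == pytest.approx(p_a, abs=3 * se + 0.01)
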