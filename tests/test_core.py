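"""Unit and property tests for the entropy estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capen.core import (
    CApEnValue,
    DegenerateEpochError,
    EmbeddingParams,
    SignalEpoch,
    apen,
    cross_apen,
    cross_apen_epochs,
    cross_apen_naive,
    embed,
    match_fraction,
    phi,
    standardize,
)


class TestStandardize:
    def test_affine_normalization(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        assert abs(z.mean()) < 1e-10
        assert abs(z.std() - 1.0) < 1e-10

    def test_idempotent(self, rng):
        z = standardize(rng.standard_normal(500))
        np.testing.assert_allclose(standardize(z), z, atol=1e-10)

    def test_constant_raises(self):
        with pytest.raises(DegenerateEpochError):
            standardize(np.full(100, 3.3))

    def test_signal_epoch_round_trip(self, rng):
        ep = SignalEpoch(rng.standard_normal(200), rate=500.0, channel="C3")
        out = standardize(ep)
        assert isinstance(out, SignalEpoch)
        assert out.channel == "C3"
        assert abs(out.samples.std() - 1.0) < 1e-10


class TestEmbed:
    @pytest.mark.parametrize(
        "series, m, lag, expected",
        [
            ([1, 2, 3, 4], 2, 1, [[1, 2], [2, 3], [3, 4]]),
            ([1, 2, 3, 4], 1, 1, [[1], [2], [3], [4]]),
            ([1, 2, 3, 4, 5], 2, 2, [[1, 3], [2, 4], [3, 5]]),
        ],
    )
    def test_definition(self, series, m, lag, expected):
        np.testing.assert_array_equal(embed(series, m, lag), expected)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            embed([1.0, 2.0], 3, 2)


class TestMatchFraction:
    def test_enumeration(self):
        assert match_fraction((0, 0), [(0, 0), (1, 1)], 0.5) == 0.5

    def test_saturation(self, rng):
        targets = rng.uniform(-1, 1, size=(20, 2))
        assert match_fraction((0, 0), targets, 10.0) == 1.0

    def test_no_match(self):
        assert match_fraction((100.0,), [(0.0,), (1.0,)], 0.1) == 0.0

    def test_empty_targets_error(self):
        with pytest.raises(ValueError, match="empty"):
            match_fraction((0.0,), np.empty((0, 1)), 0.1)


class TestPhi:
    def test_identical_singletons(self):
        assert phi([[0.0]], [[0.0]], r=0.5) == 0.0

    def test_all_half_fractions(self):
        # two queries each matching 1 of 2 targets
        q = [[0.0], [1.0]]
        t = [[0.0], [1.0]]
        assert phi(q, t, r=0.4) == pytest.approx(np.log(0.5))

    def test_toy_set_against_enumeration(self, rng):
        q = rng.standard_normal((5, 2))
        t = rng.standard_normal((7, 2))
        r = 0.8
        expected = np.mean(
            [np.log(max(match_fraction(qq, t, r), 1.0 / len(t))) for qq in q]
        )
        assert phi(q, t, r) == pytest.approx(expected, abs=1e-12)

    def test_zero_match_floor_off_raises(self):
        with pytest.raises(ValueError, match="floor"):
            phi([[0.0]], [[5.0]], r=0.1, floor=False)


def _params(n, **kw):
    kw.setdefault("r_frac", 0.3)
    return EmbeddingParams(epoch_len=n, **kw)


class TestCrossApEn:
    def test_self_comparison_equals_apen(self, rng):
        u = rng.standard_normal(300)
        p = _params(300)
        assert cross_apen(u, u, p).value == apen(u, p).value

    def test_constant_series_convention(self):
        p = _params(200)
        res = cross_apen(np.full(200, 1.0), np.full(200, 1.0), p)
        assert res.value == 0.0
        assert res.degenerate
        assert not res.floor_triggered

    def test_alternating_shifted_matches_enumeration(self):
        u = np.tile([1.0, -1.0], 500)
        v = np.roll(u, 1)
        p = EmbeddingParams(m=2, r_frac=0.2, epoch_len=1000)
        assert cross_apen(u, v, p).value == pytest.approx(
            cross_apen_naive(u, v, p), abs=1e-10
        )

    def test_ar1_vs_white_noise_exceeds_self_coupling(self):
        """Coupling to an unrelated series reads as more asynchrony."""
        p = EmbeddingParams(m=2, r_frac=0.2, epoch_len=1000)
        root = np.random.SeedSequence(42)
        wins = 0
        n_rep = 200
        for child in root.spawn(n_rep):
            r = np.random.default_rng(child)
            e = r.standard_normal(1001)
            u = np.empty(1000)
            u[0] = e[0]
            for i in range(1, 1000):
                u[i] = 0.7 * u[i - 1] + e[i]
            w = r.standard_normal(1000)
            wins += cross_apen(u, w, p).value > cross_apen(u, u, p).value
        assert wins >= 0.95 * n_rep

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_apen(rng.standard_normal(200), rng.standard_normal(201))

    def test_symmetry_exact(self, rng):
        u, v = rng.standard_normal((2, 250))
        p = _params(250)
        assert cross_apen(u, v, p).value == cross_apen(v, u, p).value

    def test_determinism(self, rng):
        u, v = rng.standard_normal((2, 250))
        p = _params(250)
        assert cross_apen(u, v, p) == cross_apen(u, v, p)

    @pytest.mark.parametrize("m,lag,r", [(2, 1, 0.2), (1, 1, 0.3), (2, 2, 0.3), (3, 1, 0.4)])
    def test_oracle_equivalence(self, rng, m, lag, r):
        """Optimized implementation equals brute-force enumeration."""
        for _ in range(3):
            n = int(rng.integers(120, 301))
            u, v = rng.standard_normal((2, n))
            p = EmbeddingParams(m=m, r_frac=r, lag=lag, epoch_len=n)
            assert cross_apen(u, v, p).value == pytest.approx(
                cross_apen_naive(u, v, p), abs=1e-10
            )

    def test_scale_invariance(self, rng):
        u, v = rng.standard_normal((2, 250))
        p = _params(250)
        ref = cross_apen(u, v, p).value
        scaled = cross_apen(3.7 * u + 11.0, 0.2 * v - 5.0, p).value
        assert scaled == pytest.approx(ref, abs=1e-10)

    def test_batch_equals_single(self, rng):
        X, Y = rng.standard_normal((2, 6, 250))
        p = _params(250)
        vals, floors, degen = cross_apen_epochs(X, Y, p)
        for e in range(6):
            res = cross_apen(X[e], Y[e], p)
            assert vals[e] == res.value
            assert floors[e] == res.floor_triggered
        assert not degen.any()

    def test_batch_flags_degenerate_epoch(self, rng):
        X, Y = rng.standard_normal((2, 3, 250))
        X[1] = 5.0
        vals, _, degen = cross_apen_epochs(X, Y, _params(250))
        assert degen.tolist() == [False, True, False]
        assert vals[1] == 0.0


class TestApEn:
    def test_periodic_series_matches_enumeration(self):
        u = np.tile([0.5, -1.5], 100)
        p = EmbeddingParams(m=1, r_frac=0.3, epoch_len=200)
        assert apen(u, p).value == pytest.approx(cross_apen_naive(u, u, p), abs=1e-12)

    def test_logistic_map_matches_enumeration(self):
        x = np.empty(1000)
        x[0] = 0.4
        for i in range(1, 1000):
            x[i] = 3.9 * x[i - 1] * (1.0 - x[i - 1])
        p = EmbeddingParams(m=2, r_frac=0.2, epoch_len=1000)
        assert apen(x, p).value == pytest.approx(cross_apen_naive(x, x, p), abs=1e-12)


class TestEmbeddingParams:
    @pytest.mark.parametrize(
        "kw", [{"m": 0}, {"r_frac": 0.0}, {"r_frac": 1.0}, {"lag": 0}, {"epoch_len": 12}]
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            EmbeddingParams(**kw)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    a=st.floats(0.1, 10.0),
    b=st.floats(-5.0, 5.0),
)
def test_property_scale_invariance(seed, a, b):
    """C-ApEn is invariant under positive affine maps of either input."""
    r = np.random.default_rng(seed)
    u, v = r.standard_normal((2, 150))
    p = EmbeddingParams(r_frac=0.3, epoch_len=150)
    assert cross_apen(a * u + b, v, p).value == pytest.approx(
        cross_apen(u, v, p).value, abs=1e-10
    )
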