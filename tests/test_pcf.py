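"""Pair Pearson correlation function and lineage autocorrelation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sistermem as sm
from sistermem.lineage_data import CellCycle, Lineage, AlignedPair, PairEnsemble
from sistermem.memory_stats import DegenerateDataError, symmetric_pearson


def _pair_from_values(vals_a, vals_b, trap="T0", T=30.0):
    def chain(vals, side):
        cycles = []
        parent = f"{trap}/f{side}"
        for k, v in enumerate(vals):
            t0 = k * T
            t = t0 + 3.0 + np.arange(3) * 3.0
            cid = f"{trap}/{side}{k}"
            # encode the target value as the cycle time via division_time
            cycles.append(CellCycle(cid, trap, parent, t0, t0 + v,
                                    t, np.exp(0.02 * t), np.full(3, np.nan)))
            parent = cid
        return Lineage(cycles)

    return AlignedPair(chain(vals_a, "A"), chain(vals_b, "B"), 0.0, 0.0)


def _ensemble(pairs, ptype="SC"):
    return PairEnsemble(ptype, [_pair_from_values(a, b) for a, b in pairs])


def _direct_symmetrized_pearson(x, y):
    """Independent oracle: direct arithmetic of the pooled-ordering Pearson."""
    xs = np.concatenate([x, y])
    ys = np.concatenate([y, x])
    xc, yc = xs - xs.mean(), ys - ys.mean()
    return (xc * yc).mean() / (np.sqrt((xc ** 2).mean()) * np.sqrt((yc ** 2).mean()))


def test_origin_is_one_by_convention():
    ens = _ensemble([([30.0], [31.0]), ([33.0], [29.0]), ([35.0], [30.0])])
    assert sm.pcf(ens, "T", 0) == 1.0


def test_perfectly_correlated_pairs():
    ens = _ensemble([([1.0], [1.0]), ([2.0], [2.0]), ([3.0], [3.0])])
    assert sm.pcf(ens, "T", 1) == pytest.approx(1.0, abs=1e-12)


def test_symmetrized_anticorrelation():
    """Pairs {(1,2),(2,1)} under the pooled-ordering estimator give -1."""
    assert symmetric_pearson([1.0, 2.0], [2.0, 1.0]) == pytest.approx(-1.0, abs=1e-12)


def test_matches_direct_arithmetic_oracle():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = rng.integers(3, 10)
        x = rng.normal(30, 5, n)
        y = 0.5 * x + rng.normal(0, 3, n)
        assert symmetric_pearson(x, y) == pytest.approx(
            _direct_symmetrized_pearson(x, y), abs=1e-12)


def test_member_order_invariance():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=8), rng.normal(size=8)
    assert symmetric_pearson(x, y) == pytest.approx(symmetric_pearson(y, x), abs=1e-15)


@settings(max_examples=80, deadline=None)
@given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                min_size=3, max_size=30))
def test_correlation_bounded(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    try:
        r = symmetric_pearson(x, y)
    except DegenerateDataError:
        return
    assert -1.0 <= r <= 1.0


def test_degenerate_variance_raises():
    with pytest.raises(DegenerateDataError):
        symmetric_pearson([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    ens = _ensemble([([30.0], [30.0])] * 4)
    with pytest.raises(DegenerateDataError):
        sm.pcf(ens, "T", 1)


def test_too_few_pairs_rejected():
    ens = _ensemble([([30.0], [31.0]), ([33.0], [29.0])])
    with pytest.raises(ValueError):
        sm.pcf(ens, "T", 1)


def test_series_has_convention_origin_and_fit(small_lineages):
    sc = sm.build_sc_pairs(small_lineages)
    series = sm.pcf_series(sc, "T", g_max=8, n_boot=50, seed=0)
    assert series.values[0] == 1.0
    assert series.se[0] == 0.0
    finite = series.values[np.isfinite(series.values)]
    assert ((finite >= -1) & (finite <= 1)).all()


class TestACF:
    def _lineages_from_matrix(self, M, trap="T0"):
        return [Lineage([CellCycle(f"{trap}/{i}c{k}", trap,
                                   f"{trap}/{i}c{k-1}" if k else f"{trap}/f{i}",
                                   k * 30.0, k * 30.0 + v,
                                   k * 30.0 + 3 + np.arange(3) * 3.0,
                                   np.exp(0.02 * np.arange(3)),
                                   np.full(3, np.nan))
                         for k, v in enumerate(row)])
                for i, row in enumerate(M)]

    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        lins = self._lineages_from_matrix(rng.normal(30, 5, (5, 12)))
        assert sm.acf(lins, "T", 0) == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        lins = self._lineages_from_matrix(rng.normal(30, 5, (40, 25)))
        n_eff = 40 * 24
        assert abs(sm.acf(lins, "T", 1)) < 3.0 / np.sqrt(n_eff)

    @pytest.mark.parametrize("lag", [1, 2, 4])
    def test_ar1_recovers_phi_power_lag(self, lag):
        """The pooled ACF of AR(1) sequences follows phi^lag."""
        phi, n_lin, n_gen = 0.8, 150, 40
        rng = np.random.default_rng(42)
        M = np.empty((n_lin, n_gen))
        M[:, 0] = rng.standard_normal(n_lin)
        for k in range(1, n_gen):
            M[:, k] = phi * M[:, k - 1] + np.sqrt(1 - phi ** 2) * rng.standard_normal(n_lin)
        lins = self._lineages_from_matrix(30.0 + 5.0 * M)
        expected = phi ** lag
        n_eff = n_lin * (n_gen - lag)
        se = (1 - expected ** 2) / np.sqrt(n_eff) * 2.0  # serial correlation margin
        assert sm.acf(lins, "T", lag) == pytest.approx(expected, abs=3 * se)

    def test_zero_variance_rejected(self):
        lins = self._lineages_from_matrix(np.full((4, 10), 30.0))
        with pytest.raises(DegenerateDataError):
            sm.acf(lins, "T", 1)
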