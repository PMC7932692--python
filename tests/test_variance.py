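"""Difference-variance dynamics and saturation metrics."""

import math

import numpy as np
import pytest

import sistermem as sm
from sistermem.memory_stats import DeltaSeries, saturation_metrics, variance_series
from sistermem import ou_step


def _series(deltas, dt=3.0, prop="fluor", ptype="SC"):
    deltas = np.asarray(deltas, dtype=float)
    grid = np.arange(deltas.shape[1]) * dt
    return DeltaSeries(grid, deltas, prop, ptype)


def test_constant_deltas_flat_with_immediate_saturation():
    d = np.tile(np.array([[1.0], [-1.0], [2.0], [0.5]]), (1, 20))
    vs = variance_series(_series(d), smooth_frames=3)
    np.testing.assert_allclose(vs.var, vs.var[0])
    assert vs.saturation_time == 0.0
    assert vs.saturation_value == pytest.approx(vs.var[0])


def test_gap_where_too_few_pairs():
    d = np.full((4, 10), 1.0)
    d[:, 4] = np.nan
    d[0, :] = np.linspace(0, 1, 10)
    d[1, :] = -np.linspace(0, 1, 10)
    d[:2, 4] = 0.0  # only 2 pairs defined at column 4
    vs = variance_series(_series(d), smooth_frames=1, min_pairs=3)
    assert np.isnan(vs.var_raw[4])
    assert np.isfinite(vs.var_raw[3])


def test_independent_ou_members_match_closed_form():
    """Two OU processes from a common start: var(delta)(t) = 2 s^2 (1 - e^(-2t/tau)),
    crossing 90% of the plateau at about 1.151 tau."""
    sigma, tau, dt, n_pairs, n_steps = 1.0, 30.0, 3.0, 3000, 40
    rng = np.random.default_rng(8)
    x = sigma * rng.standard_normal(n_pairs)
    a, b = x.copy(), x.copy()
    deltas = np.zeros((n_pairs, n_steps + 1))
    decay = math.exp(-dt / tau)
    kick = sigma * math.sqrt(1 - decay ** 2)
    for k in range(1, n_steps + 1):
        a = decay * a + kick * rng.standard_normal(n_pairs)
        b = decay * b + kick * rng.standard_normal(n_pairs)
        deltas[:, k] = a - b
    vs = variance_series(_series(deltas, dt=dt), smooth_frames=1)
    t = vs.grid
    expected = 2 * sigma ** 2 * (1 - np.exp(-2 * t / tau))
    mc_tol = 3 * np.sqrt(2.0 / n_pairs)  # relative MC error of a variance
    mask = t > 0
    np.testing.assert_allclose(vs.var_raw[mask], expected[mask],
                               rtol=4 * mc_tol, atol=0.02)
    # 90%-of-plateau crossing near -(tau/2) ln 0.1
    t90_pred = -(tau / 2) * math.log(0.1)
    i90 = np.argmax(vs.var_raw >= 0.9 * 2 * sigma ** 2)
    assert abs(t[i90] - t90_pred) <= 2 * dt


def test_saturation_band_entry():
    grid = np.arange(20, dtype=float)
    values = np.concatenate([np.linspace(0.2, 1.0, 10), np.full(10, 1.0)])
    sat, t_sat = saturation_metrics(grid, values, plateau_frac=0.25, band=0.10)
    assert sat == pytest.approx(1.0)
    # series first enters and stays within +-10% when it reaches 0.9
    assert t_sat == grid[np.argmax(values >= 0.9)]


def test_variance_by_generation_flat_without_inheritance():
    """With both heritable factors off, SC cycle-time difference variance
    shows no systematic trend across generations."""
    cfg = sm.get_preset("LB-default", n_traps=60, n_generations=12, seed=21,
                        sigma_hT=0.0, sigma_hL=0.0, frac_unrelated=0.0)
    lin = sm.build_lineages(sm.segment_cycles(sm.simulate_experiment(cfg)))
    sc = sm.build_sc_pairs(lin)
    vs = sm.variance_by_generation(sc, "T", g_max=8)
    ok = np.isfinite(vs.var_raw)
    slope = np.polyfit(vs.grid[ok], vs.var_raw[ok], 1)[0]
    # slope consistent with zero at the scale of the sampling noise
    level = np.nanmean(vs.var_raw)
    se_slope = level * np.sqrt(2.0 / sc.n) / np.std(vs.grid[ok])
    assert abs(slope) < 3 * se_slope


def test_sc_variance_grows_with_inheritance(full_bundle):
    """With inherited factors on, SC per-generation T variance rises toward
    the saturation level instead of starting there."""
    vbg = full_bundle["bundle"]["var_by_generation"]["T"]
    sc = vbg["SC"]
    vals = np.array([v for v in sc["var"] if v is not None], dtype=float)
    assert vals[0] < 0.8 * sc["saturation_value"]
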