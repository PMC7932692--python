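"""Division partitioning and adder size control."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sistermem as sm
from sistermem.growth_sim import CellState, _draw_delta


def _cell(length=4.0, f=100.0, kappa_cfg=None):
    return CellState(length=length, birth_length=length / 2, birth_time=0.0,
                     delta_target=2.0, h_T=0.0, h_L=0.0, xi=0.0, c0=0.0,
                     f=f, trap_id="T", cell_id="T/m", parent_id="NA")


@pytest.fixture()
def cfg():
    return sm.get_preset("LB-default", kappa=1.0)


def test_symmetric_partition(cfg):
    rng = np.random.default_rng(0)
    d1, d2 = sm.partition_at_division(_cell(4.0), 0.5, cfg, rng)
    assert d1.length == d2.length == 2.0
    assert d1.f == d2.f == 100.0
    assert d1.c0 == d2.c0 == 0.0


def test_asymmetric_partition_and_compensation(cfg):
    """r = 0.3 gives daughters 1.2/2.8 and opposite amplitudes 0.4 kappa."""
    rng = np.random.default_rng(0)
    d1, d2 = sm.partition_at_division(_cell(4.0), 0.3, cfg, rng)
    assert d1.length == pytest.approx(1.2)
    assert d2.length == pytest.approx(2.8)
    assert d1.c0 == pytest.approx(0.4 * cfg.kappa)
    assert d2.c0 == pytest.approx(-0.4 * cfg.kappa)


def test_concentration_inherited_exactly(cfg):
    rng = np.random.default_rng(3)
    d1, d2 = sm.partition_at_division(_cell(5.0, f=77.7), 0.41, cfg, rng)
    assert d1.f == d2.f == 77.7


def test_invalid_fraction_rejected(cfg):
    rng = np.random.default_rng(0)
    for r in (0.0, 1.0, -0.2, 1.7):
        with pytest.raises(ValueError):
            sm.partition_at_division(_cell(), r, cfg, rng)


@settings(max_examples=50, deadline=None)
@given(r=st.floats(0.01, 0.99), L=st.floats(0.1, 50.0))
def test_length_conserved_at_division(r, L):
    cfg = sm.get_preset("LB-default")
    rng = np.random.default_rng(9)
    d1, d2 = sm.partition_at_division(_cell(L), r, cfg, rng)
    assert d1.length + d2.length == pytest.approx(L, rel=0, abs=1e-12)


def test_adder_target_scales_with_heritable_factor():
    cfg = sm.get_preset("LB-default", sigma_delta_rel=0.0)
    rng = np.random.default_rng(0)
    assert _draw_delta(0.1, cfg, rng) == pytest.approx(1.1 * cfg.delta_bar)


def test_divide_when_adder_met_threshold():
    c = _cell(4.0)  # birth 2.0, target 2.0 -> divides exactly at 4.0
    assert sm.divide_when_adder_met(c)
    c.length = 3.999
    assert not sm.divide_when_adder_met(c)


def _iterate_adder(L0, delta, alpha, n, r=0.5):
    """Brute-force oracle: the noise-free adder map L_b -> r (L_b + delta)."""
    cfg = sm.get_preset("LB-default", delta_bar=delta, alpha_bar=alpha,
                        sigma_delta_rel=0.0, sigma_r=0.0, sigma_hT=0.0,
                        sigma_hL=0.0, kappa=0.0)
    rng = np.random.default_rng(0)
    cell = CellState(length=L0, birth_length=L0, birth_time=0.0,
                     delta_target=delta, h_T=0.0, h_L=0.0, xi=0.0, c0=0.0,
                     f=cfg.f_bar, trap_id="T", cell_id="T/m", parent_id="NA")
    births, cycle_times = [], []
    for _ in range(n):
        T = math.log((cell.birth_length + delta) / cell.birth_length) / alpha
        cycle_times.append(T)
        cell.length = cell.birth_length + delta
        d1, _ = sm.partition_at_division(cell, r, cfg, rng)
        cell = d1
        births.append(cell.birth_length)
    return np.array(births), np.array(cycle_times)


def test_adder_fixed_point_reached_within_ten_generations():
    """Symmetric noise-free division converges to birth length = delta."""
    births, times = _iterate_adder(L0=0.9, delta=2.0, alpha=0.02, n=40)
    assert abs(births[9] - 2.0) / 2.0 < 0.01
    assert times[-1] == pytest.approx(math.log(2.0) / 0.02, rel=1e-6)


def test_cycle_time_invariant_to_adder_size():
    """Doubling delta at fixed alpha leaves the stationary cycle time ln2/alpha."""
    _, t1 = _iterate_adder(L0=1.0, delta=2.0, alpha=0.02, n=40)
    _, t2 = _iterate_adder(L0=1.0, delta=4.0, alpha=0.02, n=40)
    assert t1[-1] == pytest.approx(t2[-1], rel=1e-9)
    assert t2[-1] == pytest.approx(math.log(2.0) / 0.02, rel=1e-9)
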