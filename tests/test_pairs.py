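"""SC/NC/RP pair construction and the stitched-length transform."""

import math

import numpy as np
import pytest

import sistermem as sm
from sistermem.lineage_data import CellCycle, Lineage


def _cycle(cell, trap, parent, t0, Lb, dt=3.0, n=10, alpha=0.02):
    t = t0 + dt + np.arange(n) * dt
    L = Lb * np.exp(alpha * (t - t0))
    return CellCycle(cell_id=cell, trap_id=trap, parent_id=parent,
                     birth_time=t0, division_time=t[-1],
                     times=t, lengths=L, fluors=np.full(n, np.nan))


def _chain(trap, side, t0, Lb, n_cycles, parent, T=30.0):
    cycles = []
    for k in range(n_cycles):
        cid = f"{trap}/{side}{k}"
        cycles.append(_cycle(cid, trap, parent, t0 + k * T, Lb))
        parent = cid
    return Lineage(cycles)


class TestSisterPairs:
    def test_one_pair_per_sister_trap(self, small_lineages):
        sc = sm.build_sc_pairs(small_lineages)
        assert sc.pair_type == "SC"
        for p in sc.pairs:
            assert p.left.trap_id == p.right.trap_id
            assert p.left.root_parent == p.right.root_parent
            assert p.t0_left == p.t0_right
            assert p.left.cycles[0].birth_time == p.t0_left

    def test_different_mothers_never_paired(self):
        a = _chain("T0", "A", 0.0, 2.0, 3, parent="T0/motherA")
        b = _chain("T0", "B", 0.0, 2.0, 3, parent="T0/motherB")
        assert sm.build_sc_pairs([a, b]).n == 0


class TestNeighborPairs:
    def test_synchronous_equal_births_paired(self):
        a = _chain("T0", "A", 0.0, 2.0, 5, parent="T0/fA")
        b = _chain("T0", "B", 0.0, 2.02, 5, parent="T0/fB")
        nc = sm.build_nc_pairs([a, b])
        assert nc.n == 1
        assert nc.pairs[0].t0_left == nc.pairs[0].t0_right == 0.0

    def test_length_mismatch_rejected(self):
        a = _chain("T0", "A", 0.0, 2.0, 5, parent="T0/fA")
        b = _chain("T0", "B", 0.0, 2.2, 5, parent="T0/fB")  # 10% apart
        assert sm.build_nc_pairs([a, b]).n == 0

    def test_asynchronous_divisions_rejected_at_default_tolerance(self):
        a = _chain("T0", "A", 0.0, 2.0, 5, parent="T0/fA")
        b = _chain("T0", "B", 6.0, 2.0, 5, parent="T0/fB")
        assert sm.build_nc_pairs([a, b]).n == 0
        assert sm.build_nc_pairs([a, b], div_sync_tol=2).n == 1

    def test_sisters_excluded(self):
        a = _chain("T0", "A", 0.0, 2.0, 5, parent="T0/mom")
        b = _chain("T0", "B", 0.0, 2.0, 5, parent="T0/mom")
        assert sm.build_nc_pairs([a, b]).n == 0

    def test_one_pair_per_epoch(self):
        a = _chain("T0", "A", 0.0, 2.0, 30, parent="T0/fA")
        b = _chain("T0", "B", 0.0, 2.0, 30, parent="T0/fB")
        nc = sm.build_nc_pairs([a, b], max_generations=11)
        # perfectly synchronous chains re-qualify every 11 generations
        assert nc.n == 3
        assert len(nc.pairs[0].left.cycles) == 11


class TestRandomPairs:
    def test_cross_trap_and_deterministic(self, small_lineages):
        rp1 = sm.build_rp_pairs(small_lineages, 20, np.random.default_rng(5))
        rp2 = sm.build_rp_pairs(small_lineages, 20, np.random.default_rng(5))
        assert [p.left.cycles[0].cell_id for p in rp1.pairs] == \
               [p.left.cycles[0].cell_id for p in rp2.pairs]
        for p in rp1.pairs:
            assert p.left.trap_id != p.right.trap_id

    def test_two_lineages_give_single_cross_pair(self):
        a = _chain("T0", "A", 0.0, 2.0, 3, parent="T0/fA")
        b = _chain("T1", "B", 0.0, 2.0, 3, parent="T1/fB")
        rp = sm.build_rp_pairs([a, b], 1, np.random.default_rng(0))
        assert rp.n == 1
        with pytest.raises(ValueError):
            sm.build_rp_pairs([a, b], 10, np.random.default_rng(0))


def test_pair_types_are_disjoint(small_lineages):
    """No lineage pair appears in more than one ensemble."""
    sc = sm.build_sc_pairs(small_lineages)
    nc = sm.build_nc_pairs(small_lineages)
    rp = sm.build_rp_pairs(small_lineages, 20, np.random.default_rng(1))

    def keys(ens):
        return {frozenset((p.left.cycles[0].cell_id, p.right.cycles[0].cell_id))
                for p in ens.pairs}

    k_sc, k_nc, k_rp = keys(sc), keys(nc), keys(rp)
    assert not (k_sc & k_nc) and not (k_sc & k_rp) and not (k_nc & k_rp)


class TestStitchedLength:
    def test_single_cycle_unchanged(self):
        lin = Lineage([_cycle("a", "T", "NA", 0.0, 2.0)])
        out = sm.stitched_length(lin)
        np.testing.assert_allclose(out["length"], lin.cycles[0].lengths)

    def test_two_doubling_cycles_span_four_to_eight(self):
        c1 = _cycle("a", "T", "NA", 0.0, 2.0, n=10)
        c2 = _cycle("b", "T", "a", c1.division_time, 2.0, n=10)
        scale = c1.lengths[-1] / c2.lengths[0]
        out = sm.stitched_length(Lineage([c1, c2]))
        np.testing.assert_allclose(out["length"][10:], c2.lengths * scale)
        assert out["length"].iloc[10] == pytest.approx(c1.lengths[-1])

    def test_exponential_lineage_stitches_to_single_exponential(
            self, noise_free_cfg, noise_free_df):
        lin = sm.build_lineages(sm.segment_cycles(noise_free_df))[0]
        out = sm.stitched_length(lin)
        # continuous: no factor-two division drops remain
        steps = np.diff(np.log(out["length"]))
        assert (steps >= -1e-12).all()
        # growth within every cycle is the configured exponential rate; the
        # global slope is only slightly diluted by the one flat frame that
        # replaces each division event
        slope, _ = np.polyfit(out["time_min"], np.log(out["length"]), 1)
        assert slope == pytest.approx(noise_free_cfg.alpha_bar, rel=0.12)
        within = steps[steps > 1e-12] / 3.0
        np.testing.assert_allclose(within, noise_free_cfg.alpha_bar, rtol=1e-9)

    def test_idempotent_on_own_output(self):
        c1 = _cycle("a", "T", "NA", 0.0, 2.0)
        c2 = _cycle("b", "T", "a", c1.division_time, 2.1)
        lin = Lineage([c1, c2])
        once = sm.stitched_length(lin)
        # rebuild cycles from the stitched trace and stitch again
        stitched_cycles = [
            CellCycle("a", "T", "NA", 0.0, c1.division_time,
                      once["time_min"].to_numpy()[:10],
                      once["length"].to_numpy()[:10], np.full(10, np.nan)),
            CellCycle("b", "T", "a", c1.division_time, c2.division_time,
                      once["time_min"].to_numpy()[10:],
                      once["length"].to_numpy()[10:], np.full(10, np.nan)),
        ]
        twice = sm.stitched_length(Lineage(stitched_cycles))
        np.testing.assert_allclose(twice["length"], once["length"], rtol=1e-12)
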