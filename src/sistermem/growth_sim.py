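"""Synthetic sisters-machine lineage generator.

Generates tab-separable lineage tables (one row per cell per imaging frame)
from a mechanistic single-cell model:

* exponential elongation at an instantaneous rate composed of a population
  mean, a heritable AR(1) growth factor, a static per-trap micro-niche
  offset, a dynamic trap-shared Ornstein-Uhlenbeck (OU) environment, a fast
  intrinsic OU fluctuation, and a transient post-division compensation term
  that inversely scales with the size fraction inherited from the mother;
* adder size control: a cell divides once it has added a (noisy, heritable)
  length increment since birth, the crossing resolved at sub-frame
  precision;
* division partitions length into fractions ``r`` and ``1 - r`` (r ~ N(0.5,
  sigma_r), truncated) and hands the mother's protein concentration to both
  daughters; heritable factors are re-drawn around the mother's value with
  per-generation retention ``phi``;
* protein concentration relaxes as an OU process toward a trap-dependent
  target, with symmetric partitioning at division;
* observation: frames every ``dt_min`` minutes with multiplicative
  log-normal measurement noise and ground-truth division flags.

Each trap holds two tip lineages.  A *sister* trap starts them from the two
daughters of one burned-in mother (yielding one sister-cell pair per trap);
an *unrelated* trap burns in two independent mothers that share the trap
environment (yielding neighbour-cell candidates with no common ancestry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "CellState",
    "TrapState",
    "ou_step",
    "update_inherited_factor",
    "partition_at_division",
    "advance_cell",
    "divide_when_adder_met",
    "simulate_experiment",
    "LINEAGE_COLUMNS",
]

LINEAGE_COLUMNS = [
    "trap_id", "cell_id", "parent_id", "frame", "time_min",
    "length", "fluor", "division",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class CellState:
    """Latent state of one cell (ground truth, pre measurement noise)."""

    length: float
    birth_length: float
    birth_time: float
    delta_target: float     # adder increment this cycle, drawn at birth
    h_T: float              # heritable growth factor
    h_L: float              # heritable adder factor
    xi: float               # fast intrinsic OU growth noise
    c0: float               # post-division compensation amplitude (1/min)
    f: float                # protein concentration (a.u.)
    trap_id: str = ""
    cell_id: str = ""
    parent_id: str = ""


@dataclass
class TrapState:
    """Per-trap environment: a static micro-niche offset plus OU dynamics."""

    trap_id: str
    eps_static: float
    eps_dyn: float = 0.0


def ou_step(x: float, dt: float, tau: float, sigma: float, rng: np.random.Generator) -> float:
    """Advance an OU state by ``dt`` using the exact discretisation.

    ``x_next = x e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) z`` with
    ``z ~ N(0, 1)``; the stationary law N(0, sigma^2) is preserved for any
    step size.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0.0:
        return x
    a = math.exp(-dt / tau)
    return a * x + sigma * math.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal()


def update_inherited_factor(
    h_mother: float, phi: float, sigma_h: float, rng: np.random.Generator
) -> float:
    """Draw a daughter's heritable factor from the mother's.

    AR(1) across generations: ``h = phi h_mother + sqrt(1 - phi^2) sigma_h
    z``; sisters draw independently, so their correlation at generation g
    (counting from the common mother) is ``phi^(2 g)``.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return phi * h_mother + math.sqrt(1.0 - phi * phi) * sigma_h * rng.standard_normal()


def _draw_delta(h_L: float, cfg: SimConfig, rng: np.random.Generator) -> float:
    eta = cfg.sigma_delta_rel * rng.standard_normal()
    # floor keeps pathological draws from producing a non-growing cycle
    return max(cfg.delta_bar * (1.0 + h_L) * (1.0 + eta), 0.1 * cfg.delta_bar)


def draw_division_fraction(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Division fraction r ~ N(0.5, sigma_r), truncated into (0.2, 0.8)."""
    r = 0.5 + cfg.sigma_r * rng.standard_normal()
    return min(max(r, 0.2), 0.8)


def partition_at_division(
    state: CellState,
    r: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    division_time: float | None = None,
) -> tuple[CellState, CellState]:
    """Split a mother into two daughters at division.

    Daughter lengths are ``r L`` and ``(1 - r) L`` (sum conserved exactly);
    protein concentration is inherited unchanged by both (symmetric
    partitioning); the compensation amplitudes are ``kappa (1 - 2 r)`` for
    the r-daughter and its negative for the other, so the smaller sister
    starts with the faster rate; heritable factors are re-drawn
    independently per daughter.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("division fraction r must lie in (0, 1)")
    t_div = state.birth_time if division_time is None else division_time
    daughters = []
    for frac, sign in ((r, +1.0), (1.0 - r, -1.0)):
        h_T = update_inherited_factor(state.h_T, cfg.phi_T, cfg.sigma_hT, rng)
        h_L = update_inherited_factor(state.h_L, cfg.phi_L, cfg.sigma_hL, rng)
        daughters.append(
            CellState(
                length=frac * state.length,
                birth_length=frac * state.length,
                birth_time=t_div,
                delta_target=_draw_delta(h_L, cfg, rng),
                h_T=h_T,
                h_L=h_L,
                xi=state.xi,
                c0=sign * cfg.kappa * (1.0 - 2.0 * r),
                f=state.f,
                trap_id=state.trap_id,
                parent_id=state.cell_id,
            )
        )
    return daughters[0], daughters[1]


def instantaneous_rate(state: CellState, trap: TrapState, cfg: SimConfig, t: float) -> float:
    """Instantaneous elongation rate alpha(t) = d ln L / dt of one cell."""
    age = max(t - state.birth_time, 0.0)
    return (
        cfg.alpha_bar * (1.0 + state.h_T + trap.eps_static + trap.eps_dyn + state.xi)
        + state.c0 * math.exp(-age / cfg.tau_c)
    )


def advance_cell(
    state: CellState,
    trap: TrapState,
    cfg: SimConfig,
    dt: float,
    rng: np.random.Generator,
    t: float | None = None,
    update_noise: bool = True,
) -> CellState:
    """Advance one cell by ``dt`` minutes (no division handling).

    The rate is held constant over the step (evaluated at its start), then
    the intrinsic growth noise and the protein concentration are advanced by
    their exact OU updates.  Mutates and returns ``state``.
    """
    t0 = state.birth_time if t is None else t
    alpha = instantaneous_rate(state, trap, cfg, t0)
    state.length *= math.exp(alpha * dt)
    if update_noise:
        state.xi = ou_step(state.xi, dt, cfg.tau_xi, cfg.sigma_xi, rng)
        f_target = cfg.f_bar * (1.0 + cfg.beta_f * trap.eps_static)
        state.f = f_target + ou_step(state.f - f_target, dt, cfg.tau_f, cfg.sigma_f_intr, rng)
    return state


def divide_when_adder_met(state: CellState) -> bool:
    """True once the cell has added its adder increment since birth."""
    return state.length - state.birth_length >= state.delta_target


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


@dataclass
class _Side:
    cell: CellState
    founder_id: str
    recording: bool = False
    divisions: int = 0          # divisions seen since this side started
    cycles_recorded: int = 0
    done: bool = False
    last_row: int = -1          # index into the trap's row buffer
    gen_ordinal: int = 0        # ordinal of the currently tracked recorded cell


def _fresh_cell(cfg: SimConfig, rng: np.random.Generator, trap_id: str, tag: str) -> CellState:
    h_T = cfg.sigma_hT * rng.standard_normal()
    h_L = cfg.sigma_hL * rng.standard_normal()
    return CellState(
        length=cfg.delta_bar,
        birth_length=cfg.delta_bar,
        birth_time=0.0,
        delta_target=_draw_delta(h_L, cfg, rng),
        h_T=h_T,
        h_L=h_L,
        xi=cfg.sigma_xi * rng.standard_normal(),
        c0=0.0,
        f=cfg.f_bar,
        trap_id=trap_id,
        cell_id=f"{trap_id}/{tag}",
        parent_id="NA",
    )


def _grow_segment(
    cell: CellState, trap: TrapState, cfg: SimConfig, t_cur: float, t_end: float
) -> float | None:
    """Grow a cell from t_cur toward t_end at a rate frozen at t_cur.

    If the adder target is crossed inside the segment, stop exactly at the
    crossing (length set to birth_length + delta_target) and return the
    crossing time; otherwise advance to t_end and return None.
    """
    alpha = instantaneous_rate(cell, trap, cfg, t_cur)
    target = cell.birth_length + cell.delta_target
    length_end = cell.length * math.exp(alpha * (t_end - t_cur))
    if alpha > 0.0 and length_end >= target:
        t_star = t_cur + math.log(target / cell.length) / alpha
        cell.length = target
        return t_star
    cell.length = length_end
    return None


class _Trap:
    """Frame-synchronous simulation of one v-trap (two tip lineages)."""

    def __init__(self, trap_index: int, cfg: SimConfig, rng: np.random.Generator,
                 unrelated: bool):
        self.cfg = cfg
        self.rng = rng
        self.trap_id = f"T{trap_index:04d}"
        self.state = TrapState(
            trap_id=self.trap_id,
            eps_static=cfg.sigma_env_static * rng.standard_normal(),
            eps_dyn=cfg.sigma_env_dyn * rng.standard_normal(),
        )
        self.rows: list[list] = []
        self.split_pending = not unrelated
        if unrelated:
            self.sides = {
                "A": self._founder_side("A"),
                "B": self._founder_side("B"),
            }
        else:
            self.sides = {"A": self._founder_side("A", tag="M")}

    def _founder_side(self, name: str, tag: str | None = None) -> _Side:
        founder_id = f"{self.trap_id}/{tag or name + '-founder'}"
        cell = _fresh_cell(self.cfg, self.rng, self.trap_id, founder_id.split("/")[1])
        return _Side(cell=cell, founder_id=founder_id)

    def _emit(self, frame: int, t: float) -> None:
        cfg, rng = self.cfg, self.rng
        for name in sorted(self.sides):
            side = self.sides[name]
            if side.done or not side.recording or side.cell.birth_time > t:
                continue
            cell = side.cell
            length_obs = cell.length * math.exp(cfg.sigma_meas_L * rng.standard_normal())
            fluor_obs = cell.f * math.exp(cfg.sigma_meas_f * rng.standard_normal())
            self.rows.append([self.trap_id, cell.cell_id, cell.parent_id, frame, t,
                              length_obs, fluor_obs, 0])
            side.last_row = len(self.rows) - 1

    def _finish_frame(self, cell: CellState) -> None:
        cfg, rng = self.cfg, self.rng
        cell.xi = ou_step(cell.xi, cfg.dt_min, cfg.tau_xi, cfg.sigma_xi, rng)
        f_target = cfg.f_bar * (1.0 + cfg.beta_f * self.state.eps_static)
        cell.f = f_target + ou_step(cell.f - f_target, cfg.dt_min, cfg.tau_f,
                                    cfg.sigma_f_intr, rng)

    def _step_side(self, name: str, t_start: float, t_end: float) -> None:
        """Advance one side across [t_start, t_end], resolving divisions."""
        cfg, rng = self.cfg, self.rng
        side = self.sides[name]
        t_cur = t_start
        for _guard in range(4):
            if side.done:
                return
            t_star = _grow_segment(side.cell, self.state, cfg, t_cur, t_end)
            if t_star is None:
                self._finish_frame(side.cell)
                return
            # --- division event at t_star ---
            side.divisions += 1
            mother = side.cell
            r = draw_division_fraction(cfg, rng)
            d1, d2 = partition_at_division(mother, r, cfg, rng, division_time=t_star)
            pick_first = rng.integers(2) == 0
            if side.recording:
                if side.last_row >= 0:
                    self.rows[side.last_row][7] = 1  # flag mother's last frame
                side.cycles_recorded += 1
                if side.cycles_recorded >= cfg.n_generations:
                    side.done = True
                    return
                side.gen_ordinal += 1
                keep = d1 if pick_first else d2
                keep.cell_id = f"{self.trap_id}/{name}{side.gen_ordinal:03d}"
                side.cell = keep
            elif side.divisions > cfg.burn_in_generations:
                if self.split_pending:
                    # the burned-in mother seeds both tips; recording starts
                    self.split_pending = False
                    d1.cell_id = f"{self.trap_id}/A000"
                    d2.cell_id = f"{self.trap_id}/B000"
                    self.sides["A"] = _Side(cell=d1, founder_id=side.founder_id,
                                            recording=True)
                    self.sides["B"] = _Side(cell=d2, founder_id=side.founder_id,
                                            recording=True)
                    # current side object is stale; finish both tips' frames
                    self._step_side_continue("A", t_star, t_end)
                    self._step_side_continue("B", t_star, t_end)
                    return
                side.recording = True
                side.gen_ordinal = 0
                keep = d1 if pick_first else d2
                keep.cell_id = f"{self.trap_id}/{name}000"
                side.cell = keep
            else:
                # plain burn-in division: keep one daughter under the founder id
                keep = d1 if pick_first else d2
                keep.cell_id = side.founder_id
                keep.parent_id = side.founder_id
                side.cell = keep
            t_cur = t_star
        raise SimulationError("more than 3 divisions within one frame; check parameters")

    def _step_side_continue(self, name: str, t_cur: float, t_end: float) -> None:
        self._step_side(name, t_cur, t_end)

    def run(self) -> list[tuple]:
        cfg = self.cfg
        frames_per_gen = max(int(round(math.log(2.0) / (cfg.alpha_bar * cfg.dt_min))), 1)
        max_frames = (cfg.burn_in_generations + cfg.n_generations + 10) * frames_per_gen * 4
        frame = 0
        while any(not s.done for s in self.sides.values()):
            if frame > max_frames:
                raise SimulationError(
                    f"trap {self.trap_id} did not finish within {max_frames} frames")
            t = frame * cfg.dt_min
            self._emit(frame, t)
            self.state.eps_dyn = ou_step(self.state.eps_dyn, cfg.dt_min,
                                         cfg.tau_env, cfg.sigma_env_dyn, self.rng)
            for name in sorted(self.sides):
                if not self.sides[name].done:
                    self._step_side(name, t, t + cfg.dt_min)
            frame += 1
        return [tuple(r) for r in self.rows]


def _simulate_trap(
    trap_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    unrelated: bool,
) -> list[tuple]:
    return _Trap(trap_index, cfg, rng, unrelated).run()


def simulate_experiment(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a full sisters-machine experiment.

    Returns a lineage table with one row per cell per frame, columns
    ``trap_id, cell_id, parent_id, frame, time_min, length, fluor,
    division`` sorted by (trap_id, cell_id, frame).  Deterministic given
    ``cfg`` (including its seed).
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_traps + 1)
    layout_rng = np.random.default_rng(children[0])
    # which traps host unrelated (neighbour-cell) tips
    n_unrelated = int(round(cfg.frac_unrelated * cfg.n_traps))
    unrelated_idx = set(
        layout_rng.choice(cfg.n_traps, size=n_unrelated, replace=False).tolist()
    )
    all_rows: list[tuple] = []
    for i in range(cfg.n_traps):
        rng = np.random.default_rng(children[i + 1])
        all_rows.extend(_simulate_trap(i, cfg, rng, unrelated=i in unrelated_idx))
    df = pd.DataFrame(all_rows, columns=LINEAGE_COLUMNS)
    df = df.sort_values(["trap_id", "cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    return df
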