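"""Lineage-table data model: TSV I/O, cycle segmentation, pair building.

The on-disk format is a TSV with one row per cell per imaging frame and
columns ``trap_id, cell_id, parent_id, frame, time_min, length, fluor,
division``; missing fluorescence is encoded as ``NA``.  Analysis works on
derived objects: :class:`CellCycle` (one birth-to-division interval),
:class:`Lineage` (a chain of cycles along one trap tip) and
:class:`PairEnsemble` (aligned pairs of lineages of one type).

Pair types follow the sisters-machine analysis:

* SC (sister cells) — the two daughters of one mother, aligned at the
  division that created them;
* NC (neighbour cells) — co-trapped lineages with no recorded common
  ancestor, aligned at a frame where both start a cycle with nearly
  identical birth lengths;
* RP (random pairs) — lineages from different traps aligned artificially
  at a cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_sim import LINEAGE_COLUMNS

__all__ = [
    "SchemaError",
    "CellCycle",
    "Lineage",
    "AlignedPair",
    "PairEnsemble",
    "read_lineage_table",
    "write_lineage_table",
    "segment_cycles",
    "build_lineages",
    "build_sc_pairs",
    "build_nc_pairs",
    "build_rp_pairs",
    "stitched_length",
    "pair_manifest",
]


class SchemaError(ValueError):
    """Lineage table violates the TSV schema."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[LINEAGE_COLUMNS].copy()
    if len(df) == 0:
        return df
    bad = df.index[df["length"].isna() | (df["length"] <= 0)]
    if len(bad):
        raise SchemaError(f"non-positive or missing length at row {bad[0]}")
    for (trap, cell), grp in df.groupby(["trap_id", "cell_id"], sort=False):
        t = grp["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise SchemaError(
                f"time_min not strictly increasing for cell {cell!r} "
                f"(trap {trap!r}) near row {grp.index[i + 1]}"
            )
    return df


def read_lineage_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a lineage TSV; rows sorted by (trap, cell, frame)."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"trap_id": str, "cell_id": str, "parent_id": str},
    )
    if "parent_id" in df.columns:
        df["parent_id"] = df["parent_id"].where(df["parent_id"].notna(), other=pd.NA)
    df = _validate_table(df)
    return df.sort_values(["trap_id", "cell_id", "frame"], kind="mergesort").reset_index(drop=True)


def write_lineage_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a lineage table as TSV (missing values as NA, fixed precision)."""
    out = df[LINEAGE_COLUMNS].sort_values(
        ["trap_id", "cell_id", "frame"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


# ---------------------------------------------------------------------------
# cycles and lineages
# ---------------------------------------------------------------------------


@dataclass
class CellCycle:
    """One birth-to-division interval with per-cycle derived features.

    ``birth_time`` is the time of the mother's division (one frame before
    this cell's first observation); ``division_time`` is the time of the
    division-flagged final frame, so ``T`` is frame-quantised.
    ``alpha_cycle`` is the least-squares slope of ln(length) against time
    over the cycle's frames (1/min).
    """

    cell_id: str
    trap_id: str
    parent_id: str
    birth_time: float
    division_time: float
    times: np.ndarray
    lengths: np.ndarray
    fluors: np.ndarray

    @property
    def T(self) -> float:
        return self.division_time - self.birth_time

    @property
    def L_birth(self) -> float:
        return float(self.lengths[0])

    @property
    def L_div(self) -> float:
        return float(self.lengths[-1])

    @property
    def alpha_cycle(self) -> float:
        t, y = self.times, np.log(self.lengths)
        tc = t - t.mean()
        return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))

    @property
    def f_mean(self) -> float:
        vals = self.fluors[~np.isnan(self.fluors)]
        return float(vals.mean()) if len(vals) else float("nan")


@dataclass
class Lineage:
    """Consecutive, parent-linked cycles along one trap tip."""

    cycles: list[CellCycle]

    @property
    def trap_id(self) -> str:
        return self.cycles[0].trap_id

    @property
    def root_parent(self) -> str:
        return self.cycles[0].parent_id

    def __len__(self) -> int:
        return len(self.cycles)

    def cell_ids(self) -> set[str]:
        return {c.cell_id for c in self.cycles}

    def subseq(self, start: int, max_len: int | None = None) -> "Lineage":
        stop = None if max_len is None else start + max_len
        return Lineage(self.cycles[start:stop])


@dataclass
class AlignedPair:
    """Two lineages with a per-member alignment origin (minutes)."""

    left: Lineage
    right: Lineage
    t0_left: float
    t0_right: float


@dataclass
class PairEnsemble:
    pair_type: str  # 'SC' | 'NC' | 'RP'
    pairs: list[AlignedPair]

    @property
    def n(self) -> int:
        return len(self.pairs)


def _infer_dt(times: np.ndarray) -> float:
    d = np.diff(np.unique(times))
    return float(np.min(d)) if len(d) else 3.0


def segment_cycles(df: pd.DataFrame, drop_threshold: float = 0.25) -> list[CellCycle]:
    """Split frame samples into complete cell cycles.

    Uses explicit division flags when the table carries any; otherwise a
    boundary is declared between consecutive frames of a cell whenever the
    length falls by more than ``drop_threshold`` of its previous value.
    Only complete cycles are returned (segments ending in a division);
    cycles shorter than 3 frames are discarded.  When one ``cell_id`` spans
    several cycles, segment k gets id ``"<cell_id>#k"`` with the previous
    segment as parent.
    """
    if len(df) == 0:
        return []
    dt = _infer_dt(df["time_min"].to_numpy())
    has_flags = bool((df["division"] == 1).any())
    cycles: list[CellCycle] = []
    for (trap, cell), grp in df.groupby(["trap_id", "cell_id"], sort=True):
        t = grp["time_min"].to_numpy(dtype=float)
        L = grp["length"].to_numpy(dtype=float)
        f = grp["fluor"].to_numpy(dtype=float)
        parent = grp["parent_id"].iloc[0]
        parent = "NA" if pd.isna(parent) else str(parent)
        if has_flags:
            ends = np.flatnonzero(grp["division"].to_numpy() == 1)
        else:
            # boundary after index i when the length falls by > drop_threshold;
            # the trailing segment is kept (its division is unobserved)
            drops = np.flatnonzero(L[1:] < (1.0 - drop_threshold) * L[:-1])
            ends = np.append(drops, len(L) - 1)
        start = 0
        seg = 0
        for e in ends:
            if e < start:
                continue
            times = t[start:e + 1]
            if len(times) >= 3:
                cid = cell if seg == 0 else f"{cell}#{seg}"
                pid = parent if seg == 0 else (cell if seg == 1 else f"{cell}#{seg - 1}")
                cycles.append(CellCycle(
                    cell_id=cid, trap_id=trap, parent_id=pid,
                    birth_time=times[0] - dt, division_time=times[-1],
                    times=times, lengths=L[start:e + 1], fluors=f[start:e + 1],
                ))
            start = e + 1
            seg += 1
    return cycles


def build_lineages(cycles: list[CellCycle]) -> list[Lineage]:
    """Chain cycles into tip lineages by following parent links."""
    by_id = {c.cell_id: c for c in cycles}
    children: dict[str, list[CellCycle]] = {}
    for c in cycles:
        children.setdefault(c.parent_id, []).append(c)
    roots = [c for c in cycles if c.parent_id not in by_id]
    lineages = []
    for root in roots:
        chain = [root]
        while True:
            kids = children.get(chain[-1].cell_id, [])
            if len(kids) != 1:
                break
            chain.append(kids[0])
        lineages.append(Lineage(chain))
    return lineages


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def build_sc_pairs(lineages: list[Lineage]) -> PairEnsemble:
    """Pair lineages whose roots are the two daughters of one mother."""
    by_parent: dict[tuple[str, str], list[Lineage]] = {}
    for lin in lineages:
        if lin.root_parent != "NA":
            by_parent.setdefault((lin.trap_id, lin.root_parent), []).append(lin)
    pairs = []
    for (_trap, _parent), group in sorted(by_parent.items()):
        if len(group) == 2:
            a, b = group
            t0 = a.cycles[0].birth_time
            pairs.append(AlignedPair(a, b, t0, b.cycles[0].birth_time))
    return PairEnsemble("SC", pairs)


def _related(a: Lineage, b: Lineage) -> bool:
    ids_a = a.cell_ids() | {a.root_parent}
    ids_b = b.cell_ids() | {b.root_parent}
    ids_a.discard("NA")
    ids_b.discard("NA")
    return bool(ids_a & ids_b)


def build_nc_pairs(
    lineages: list[Lineage],
    div_sync_tol: int = 0,
    len_tol_rel: float = 0.05,
    max_generations: int = 11,
    dt: float | None = None,
) -> PairEnsemble:
    """Harvest neighbour-cell pairs from co-trapped, unrelated lineages.

    Two lineages in the same trap qualify at a frame where both begin a new
    cycle within ``div_sync_tol`` frames and with birth lengths differing by
    less than ``len_tol_rel`` of their mean.  At most one pair is taken per
    non-overlapping window of ``max_generations`` generations.
    """
    by_trap: dict[str, list[Lineage]] = {}
    for lin in lineages:
        by_trap.setdefault(lin.trap_id, []).append(lin)
    if dt is None:
        for lin in lineages:
            if len(lin.cycles[0].times) > 1:
                dt = float(lin.cycles[0].times[1] - lin.cycles[0].times[0])
                break
        else:
            dt = 3.0
    pairs = []
    for trap in sorted(by_trap):
        lins = by_trap[trap]
        for i in range(len(lins)):
            for j in range(i + 1, len(lins)):
                a, b = lins[i], lins[j]
                if _related(a, b):
                    continue
                births_b = np.array([c.birth_time for c in b.cycles])
                ia = 0
                while ia < len(a.cycles):
                    ca = a.cycles[ia]
                    close = np.flatnonzero(
                        np.abs(births_b - ca.birth_time) <= div_sync_tol * dt + 1e-9)
                    hit = None
                    for ib in close:
                        cb = b.cycles[ib]
                        mean_L = 0.5 * (ca.L_birth + cb.L_birth)
                        if abs(ca.L_birth - cb.L_birth) < len_tol_rel * mean_L:
                            hit = int(ib)
                            break
                    if hit is None:
                        ia += 1
                        continue
                    pairs.append(AlignedPair(
                        a.subseq(ia, max_generations),
                        b.subseq(hit, max_generations),
                        ca.birth_time, b.cycles[hit].birth_time,
                    ))
                    ia += max_generations  # next non-overlapping epoch
    return PairEnsemble("NC", pairs)


def build_rp_pairs(
    lineages: list[Lineage],
    n_pairs: int,
    rng: np.random.Generator,
) -> PairEnsemble:
    """Sample cross-trap lineage pairs, aligned at each member's first cycle.

    Sampling is without replacement over unordered lineage pairs from
    distinct traps; deterministic given the generator state.
    """
    traps = np.array([lin.trap_id for lin in lineages])
    n = len(lineages)
    n_available = sum(
        int(np.sum(traps[i + 1:] != traps[i])) for i in range(n)
    )
    if n_pairs > n_available:
        raise ValueError(
            f"requested {n_pairs} random pairs but only {n_available} "
            "distinct-trap combinations exist")
    chosen: set[tuple[int, int]] = set()
    pairs = []
    guard = 0
    while len(pairs) < n_pairs:
        guard += 1
        if guard > 1000 * n_pairs + 1000:
            raise RuntimeError("random-pair sampling failed to converge")
        i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
        if traps[i] == traps[j] or (i, j) in chosen:
            continue
        chosen.add((i, j))
        a, b = lineages[i], lineages[j]
        pairs.append(AlignedPair(a, b, a.cycles[0].birth_time, b.cycles[0].birth_time))
    return PairEnsemble("RP", pairs)


def stitched_length(lineage: Lineage) -> pd.DataFrame:
    """Concatenate a lineage's length trace continuously across divisions.

    Cycle 0 is unchanged; each later cycle is rescaled so its first length
    equals the stitched length at the end of the previous cycle.  Returns a
    frame with columns ``time_min`` and ``length``.
    """
    times, lengths = [], []
    scale = 1.0
    prev_end = None
    for k, cyc in enumerate(lineage.cycles):
        if k > 0:
            if cyc.L_birth <= 0:
                raise ValueError("zero birth length; cannot stitch")
            scale = prev_end / cyc.L_birth
        seg = cyc.lengths * scale
        times.append(cyc.times)
        lengths.append(seg)
        prev_end = seg[-1]
    return pd.DataFrame({
        "time_min": np.concatenate(times),
        "length": np.concatenate(lengths),
    })


def pair_manifest(ensembles: list[PairEnsemble]) -> pd.DataFrame:
    """Tabulate pairs (one row each) for export as a TSV manifest."""
    rows = []
    for ens in ensembles:
        for k, p in enumerate(ens.pairs):
            rows.append({
                "pair_id": f"{ens.pair_type}{k:04d}",
                "pair_type": ens.pair_type,
                "trap_left": p.left.trap_id,
                "trap_right": p.right.trap_id,
                "cell_left": p.left.cycles[0].cell_id,
                "cell_right": p.right.cycles[0].cell_id,
                "t0_left": p.t0_left,
                "t0_right": p.t0_right,
            })
    return pd.DataFrame(rows)
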