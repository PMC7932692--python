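"""Config-driven orchestration: simulate -> segment -> pair -> analyze.

The end-to-end products are a lineage TSV (from :func:`run_simulate`) and a
JSON-serialisable results bundle (from :func:`run_analyze`) containing the
cycle-time and size pair-correlation series per pair type with their
exponential memory fits, the growth-rate and fluorescence
difference-variance dynamics with saturation metrics, the average-rate
difference summary, and full provenance (config echo, seed, package
version, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig, save_config
from .growth_sim import simulate_experiment
from .lineage_data import (
    PairEnsemble,
    build_lineages,
    build_nc_pairs,
    build_rp_pairs,
    build_sc_pairs,
    pair_manifest,
    segment_cycles,
    write_lineage_table,
)
from . import memory_stats as ms

log = logging.getLogger("sistermem")

__all__ = ["AnalysisParams", "run_simulate", "run_analyze", "analyze_dataset"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable statistics settings (windows, tolerances, fit range)."""

    g_max: int = 10
    window_min: float = 6.0          # moving window for alpha(t), minutes
    smooth_frames_size: int = 6      # boxcar for the time-resolved size PCF
    smooth_frames_var: int = 3       # boxcar for variance series
    div_sync_tol: int = 0            # NC division synchrony, frames
    len_tol_rel: float = 0.05        # NC relative birth-length tolerance
    nc_max_generations: int = 11     # one NC pair per such epoch
    n_rp: int = 150
    n_sc_max: int | None = None      # optionally subsample SC pairs
    min_cycles_rate_summary: int = 5
    n_boot: int = 500
    var_t_max: float = 280.0         # minutes of delta-variance grid (~8 gen)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_simulate(cfg: SimConfig, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Simulate an experiment; optionally write the TSV plus a config echo."""
    df = simulate_experiment(cfg)
    log.info("simulated %d traps -> %d frames, %d cells",
             cfg.n_traps, len(df), df["cell_id"].nunique())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_lineage_table(df, out / "lineages.tsv")
        save_config(cfg, out / "sim_config.yaml")
    return df


def build_ensembles(
    df: pd.DataFrame, params: AnalysisParams
) -> tuple[PairEnsemble, PairEnsemble, PairEnsemble, list]:
    """Segment, chain and pair a lineage table into SC/NC/RP ensembles."""
    cycles = segment_cycles(df)
    lineages = build_lineages(cycles)
    sc = build_sc_pairs(lineages)
    if params.n_sc_max is not None and sc.n > params.n_sc_max:
        rng = np.random.default_rng(params.seed)
        keep = rng.choice(sc.n, size=params.n_sc_max, replace=False)
        sc = PairEnsemble("SC", [sc.pairs[i] for i in sorted(keep)])
    nc = build_nc_pairs(lineages, params.div_sync_tol, params.len_tol_rel,
                        params.nc_max_generations)
    rng = np.random.default_rng(params.seed + 1)
    n_rp = min(params.n_rp, _n_cross_trap(lineages))
    rp = build_rp_pairs(lineages, n_rp, rng)
    log.info("cycles=%d lineages=%d pairs: SC=%d NC=%d RP=%d",
             len(cycles), len(lineages), sc.n, nc.n, rp.n)
    return sc, nc, rp, lineages


def _n_cross_trap(lineages) -> int:
    traps = pd.Series([lin.trap_id for lin in lineages]).value_counts()
    n = int(traps.sum())
    return (n * (n - 1) - int((traps * (traps - 1)).sum())) // 2


def _series_dict(series: ms.CorrelationSeries | None) -> dict | None:
    if series is None:
        return None
    d = {
        "grid": series.grid.tolist(),
        "values": _round(series.values),
        "se": _round(series.se) if series.se is not None else None,
        "n_pairs": np.asarray(series.n_pairs).tolist(),
        "kind": series.kind,
        "fit": series.fit.to_dict() if series.fit else None,
    }
    return d


def _var_dict(vs: ms.VarianceSeries | None) -> dict | None:
    if vs is None:
        return None
    return {
        "grid": _round(vs.grid),
        "var": _round(vs.var),
        "n_pairs": np.asarray(vs.n_pairs).tolist(),
        "saturation_value": _f(vs.saturation_value),
        "saturation_time": _f(vs.saturation_time),
        "smooth_window": vs.smooth_window,
    }


def _f(x) -> float | None:
    x = float(x)
    return None if not np.isfinite(x) else float(np.round(x, 10))


def _round(a) -> list:
    out = np.asarray(a, dtype=float)
    return [None if not np.isfinite(v) else float(np.round(v, 10)) for v in out]


def _half_life(series: ms.CorrelationSeries | None) -> float | None:
    if series is None or series.fit is None:
        return None
    h = series.fit.half_life
    return None if not np.isfinite(h) else h


def analyze_dataset(
    df: pd.DataFrame,
    params: AnalysisParams | None = None,
) -> dict:
    """Compute the full results bundle from a lineage table.

    Returns a JSON-serialisable dict; every number is reproducible from the
    input table and ``params`` (including its bootstrap seed).
    """
    params = params or AnalysisParams()
    sc, nc, rp, lineages = build_ensembles(df, params)
    cycles = [c for lin in lineages for c in lin.cycles]
    mean_T = float(np.mean([c.T for c in cycles]))
    sd_T = float(np.std([c.T for c in cycles]))
    frames_per_cycle = float(np.mean([len(c.times) for c in cycles]))

    bundle: dict = {
        "provenance": {
            "package_version": __version__,
            "analysis_params": params.to_dict(),
            "n_input_rows": int(len(df)),
        },
        "counts": {"SC": sc.n, "NC": nc.n, "RP": rp.n,
                   "cycles": len(cycles), "lineages": len(lineages)},
        "cycle_stats": {
            "mean_T_min": mean_T, "sd_T_min": sd_T,
            "frames_per_cycle": frames_per_cycle,
        },
    }
    bundle["provenance"]["params_hash"] = _config_hash(params.to_dict())
    bundle["pair_manifest"] = pair_manifest([sc, nc, rp]).to_dict("records")

    # --- per-generation cycle-time PCF and fits -------------------------
    t_pcf: dict = {}
    for ens in (sc, nc, rp):
        try:
            series = ms.pcf_series(ens, "T", g_max=params.g_max,
                                   n_boot=params.n_boot, seed=params.seed)
        except (ValueError, ms.DegenerateDataError) as exc:
            log.warning("T-PCF for %s unavailable: %s", ens.pair_type, exc)
            series = None
        t_pcf[ens.pair_type] = series
    bundle["t_pcf"] = {k: _series_dict(v) for k, v in t_pcf.items()}
    sc_hl = _half_life(t_pcf["SC"])
    nc_hl = _half_life(t_pcf["NC"])
    bundle["half_lives"] = {
        "sc_t_gen": sc_hl,
        "nc_t_gen": nc_hl,
        "rp_t_gen": _half_life(t_pcf["RP"]),
        "sc_over_nc": (sc_hl / nc_hl) if sc_hl and nc_hl else None,
    }

    # --- time-resolved size PCF (SC), in generations via mean T ---------
    try:
        size_series = ms.pcf_time(
            sc, "length", smooth_frames=params.smooth_frames_size,
            t_max=params.g_max * mean_T, n_boot=min(params.n_boot, 300),
            seed=params.seed, fit_t_max=params.g_max * mean_T)
    except (ValueError, ms.DegenerateDataError) as exc:
        log.warning("size PCF unavailable: %s", exc)
        size_series = None
    bundle["size_pcf_sc"] = _series_dict(size_series)
    size_hl_min = _half_life(size_series)
    bundle["half_lives"]["sc_size_gen"] = (
        size_hl_min / mean_T if size_hl_min else None)

    # --- ACF along lineages (pooled) ------------------------------------
    acf_out = {}
    for prop in ("T", "L_birth"):
        try:
            acf_out[prop] = _series_dict(ms.acf_series(lineages, prop, params.g_max))
        except (ValueError, ms.DegenerateDataError) as exc:
            log.warning("ACF of %s unavailable: %s", prop, exc)
            acf_out[prop] = None
    bundle["acf"] = acf_out

    # --- growth-rate difference variance dynamics ------------------------
    dalpha, var_alpha = {}, {}
    for ens in (sc, nc, rp):
        ds = ms.delta_series(ens, "alpha", window_min=params.window_min,
                             t_max=params.var_t_max)
        dalpha[ens.pair_type] = ds
        var_alpha[ens.pair_type] = ms.variance_series(
            ds, smooth_frames=params.smooth_frames_var)
    bundle["var_dalpha"] = {k: _var_dict(v) for k, v in var_alpha.items()}

    plateau_vals = np.concatenate([
        var_alpha["NC"].var[np.isfinite(var_alpha["NC"].var)],
        var_alpha["RP"].var[np.isfinite(var_alpha["RP"].var)],
    ])
    plateau = float(np.mean(plateau_vals)) if len(plateau_vals) else float("nan")
    sc_var = var_alpha["SC"].var
    sc_grid = var_alpha["SC"].grid
    defined = np.flatnonzero(np.isfinite(sc_var))
    sc0 = float(sc_var[defined[0]]) if len(defined) else float("nan")
    excess_pct = 100.0 * (sc0 / plateau - 1.0) if plateau > 0 else float("nan")
    within = defined[sc_grid[defined] <= 3.0 * mean_T]
    if len(within):
        imin = within[np.argmin(sc_var[within])]
        t_min = float(sc_grid[imin])
        t_min_since_sep = t_min  # grid time 0 is the separating division
    else:
        t_min_since_sep = float("nan")
    bundle["dalpha_summary"] = {
        "sc_initial_var": _f(sc0),
        "ncrp_plateau_var": _f(plateau),
        "sc_excess_pct": _f(excess_pct),
        "sc_min_time_min": _f(t_min_since_sep),
    }

    # --- grand mean of delta alpha over all pairs and times --------------
    all_deltas = [dalpha[k].deltas for k in ("SC", "NC", "RP")]
    pooled = np.concatenate([d.ravel() for d in all_deltas])
    pooled = pooled[np.isfinite(pooled)]
    grand_mean = float(np.mean(pooled)) if len(pooled) else float("nan")
    stacked = [d for d in all_deltas]

    def _gm(idx_sets):
        vals = []
        for d, idx in zip(stacked, idx_sets):
            if d.shape[0] == 0:
                continue
            sel = d[idx].ravel()
            vals.append(sel[np.isfinite(sel)])
        v = np.concatenate(vals) if vals else np.empty(0)
        return np.mean(v) if len(v) else np.nan

    rng = np.random.default_rng(params.seed + 2)
    reps = []
    if len(pooled) and params.n_boot:
        for _ in range(params.n_boot):
            idx_sets = [rng.integers(0, max(d.shape[0], 1), size=d.shape[0])
                        for d in stacked]
            reps.append(_gm(idx_sets))
    se = float(np.nanstd(np.array(reps))) if reps else float("nan")
    bundle["dalpha_grand_mean"] = {
        "mean": _f(grand_mean),
        "se": _f(se),
        "n_values": int(len(pooled)),
    }

    # --- fluorescence difference variance --------------------------------
    var_f = {}
    for ens in (sc, nc, rp):
        ds = ms.delta_series(ens, "fluor", t_max=params.var_t_max)
        var_f[ens.pair_type] = ms.variance_series(
            ds, smooth_frames=params.smooth_frames_var)
    bundle["var_dfluor"] = {k: _var_dict(v) for k, v in var_f.items()}
    sat_t = var_f["SC"].saturation_time
    # robust rise time: first grid point reaching 90% of the plateau
    sc_f = var_f["SC"]
    above = np.flatnonzero(
        np.isfinite(sc_f.var) & (sc_f.var >= 0.9 * sc_f.saturation_value))
    rise90 = float(sc_f.grid[above[0]]) if len(above) else float("nan")
    bundle["dfluor_summary"] = {
        "sc_saturation_time_min": _f(sat_t),
        "sc_saturation_gen": _f(sat_t / mean_T) if np.isfinite(sat_t) else None,
        "sc_rise90_time_min": _f(rise90),
        "sc_rise90_gen": _f(rise90 / mean_T) if np.isfinite(rise90) else None,
        "rp_over_nc_plateau": _f(
            var_f["RP"].saturation_value / var_f["NC"].saturation_value)
        if var_f["NC"].saturation_value else None,
    }

    # --- average-rate difference spread (SC vs RP) ------------------------
    try:
        summary = ms.pair_rate_difference_summary(
            sc, rp, min_cycles=params.min_cycles_rate_summary)
        bundle["rate_diff_summary"] = {
            "sd_sc": _f(summary.sd_sc), "sd_rp": _f(summary.sd_rp),
            "ratio": _f(summary.ratio),
            "n_sc": int(len(summary.samples_sc)),
            "n_rp": int(len(summary.samples_rp)),
        }
    except ValueError as exc:
        log.warning("rate-difference summary unavailable: %s", exc)
        bundle["rate_diff_summary"] = None

    # --- per-generation variance saturation (T, birth length) -------------
    bundle["var_by_generation"] = {
        prop: {
            ens.pair_type: _var_dict(ms.variance_by_generation(
                ens, prop, g_max=params.g_max))
            for ens in (sc, nc, rp)
        }
        for prop in ("T", "L_birth")
    }
    return bundle


def run_analyze(
    df: pd.DataFrame,
    params: AnalysisParams | None = None,
    out_dir: str | Path | None = None,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Analyze a lineage table and optionally write JSON/TSV outputs."""
    bundle = analyze_dataset(df, params)
    if sim_cfg is not None:
        bundle["provenance"]["sim_config"] = sim_cfg.to_dict()
        bundle["provenance"]["sim_config_hash"] = _config_hash(sim_cfg.to_dict())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(bundle, indent=1, sort_keys=True) + "\n")
        _write_series_tsvs(bundle, out)
        manifest = bundle.get("pair_manifest")
        if manifest:
            pd.DataFrame(manifest).to_csv(
                out / "pairs_manifest.tsv", sep="\t", index=False,
                float_format="%.6g")
    return bundle


def _write_series_tsvs(bundle: dict, out: Path) -> None:
    for name, group in (("t_pcf", bundle.get("t_pcf") or {}),
                        ("var_dalpha", bundle.get("var_dalpha") or {}),
                        ("var_dfluor", bundle.get("var_dfluor") or {})):
        for ptype, d in group.items():
            if not d:
                continue
            cols = {"grid": d["grid"]}
            cols["value"] = d.get("values", d.get("var"))
            if d.get("se"):
                cols["se"] = d["se"]
            pd.DataFrame(cols).to_csv(
                out / f"{name}_{ptype}.tsv", sep="\t", index=False,
                na_rep="NA", float_format="%.8g")
    if bundle.get("size_pcf_sc"):
        d = bundle["size_pcf_sc"]
        pd.DataFrame({"grid": d["grid"], "value": d["values"]}).to_csv(
            out / "size_pcf_SC.tsv", sep="\t", index=False, na_rep="NA",
            float_format="%.8g")
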