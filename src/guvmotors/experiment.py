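"""Orchestration of the four in-silico experiments.

Mirrors the study design: (1) bulk vs GUV-confined motility with a
membrane-permeability control, (2) a fuel sweep over 0-3.4% v/v H2O2,
(3) stratification by GUV size group, (4) stratification by relative
coacervate concentration (crowding). Each experiment is a set of
:class:`ExperimentCondition` runs reduced to ensemble MSD curves, (K,
alpha, D_T) fits, regime labels and pairwise group comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .msd import (
    classify_regime,
    compare_groups,
    ensemble_msd,
    fit_linear,
    fit_power_law,
    fit_trajectories,
    msd_at,
    significance_tier,
    tamsd,
)
from .params import ExperimentCondition, MotorParams, PARTICLE_DIAMETER_UM
from .io import acquisition_from_dict, condition_from_dict
from .simulator import simulate_condition

__all__ = [
    "assign_size_group",
    "sample_guv_diameter",
    "confinement_ratio",
    "run_experiment",
    "SIZE_GROUPS",
]

#: GUV diameter groups (um): small 14-24, medium 25-34, large >34 (cap 50,
#: the upper end of the observed size distribution)
SIZE_GROUPS = {"small": (14.0, 24.0), "medium": (24.0, 34.0),
               "large": (34.0, 50.0)}


def assign_size_group(diameter: float) -> str:
    """Size group of a GUV from its diameter (um)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if diameter < 14.0:
        raise ValueError("diameter below the studied 14-50 um range")
    if diameter <= 24.0:
        return "small"
    if diameter <= 34.0:
        return "medium"
    return "large"


def sample_guv_diameter(group: str, rng: np.random.Generator) -> float:
    """Draw a GUV diameter (um) uniformly within the group's bounds."""
    if group not in SIZE_GROUPS:
        raise ValueError(f"unknown size group {group!r}")
    lo, hi = SIZE_GROUPS[group]
    if group in ("medium", "large"):
        lo = np.nextafter(lo, hi)  # open lower bound
    return float(rng.uniform(lo, hi))


def confinement_ratio(guv_diameter: float,
                      particle_diameter: float = PARTICLE_DIAMETER_UM) -> float:
    """Compartment-to-particle diameter ratio (unitless)."""
    if guv_diameter <= 0 or particle_diameter <= 0:
        raise ValueError("diameters must be positive")
    return guv_diameter / particle_diameter


def _condition_summary(cond: ExperimentCondition, acq) -> dict:
    trajs = simulate_condition(cond, acq=acq)
    ens, fit = fit_trajectories(trajs)
    # per-particle fits for dispersion (reported as mean +/- SD)
    alphas, dts = [], []
    for t in trajs:
        c = tamsd(t)
        try:
            _, a = fit_power_law(c)
            alphas.append(a)
            dts.append(fit_linear(c))
        except ValueError:
            continue
    m10, s10 = msd_at(ens, 10.0)
    return {
        "trajs": trajs, "ens": ens, "fit": fit,
        "alphas": np.array(alphas), "dts": np.array(dts),
        "row": {
            "condition_id": cond.label, "fuel_pct": cond.fuel,
            "guv_diameter": cond.guv_diameter, "n_particles": cond.n_particles,
            "K": fit.K, "alpha": fit.alpha, "D_T": fit.D_T,
            "alpha_sd": float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0,
            "D_T_sd": float(np.std(dts, ddof=1)) if len(dts) > 1 else 0.0,
            "regime": classify_regime(fit.alpha),
            "msd_10s": m10, "msd_10s_sem": s10,
            "r2_alpha": fit.r_squared_alpha, "r2_linear": fit.r_squared_linear,
        },
    }


def run_experiment(config: dict, out_dir=None) -> dict[str, pd.DataFrame]:
    """Run every condition in ``config`` and reduce to summary tables.

    ``config`` holds ``conditions`` (list of condition dicts),
    optional ``acquisition``, optional ``comparisons`` (list of condition
    label pairs to t-test on per-particle D_T). Returns tables
    ``conditions`` (one row per condition: fits, regime, MSD at 10 s),
    ``msd_curves`` (long format) and ``comparisons``; writes CSVs and a
    run log when ``out_dir`` is given. A failing condition is logged and
    skipped; the rest proceed.
    """
    acq_template = config.get("acquisition")
    master_seed = int(config.get("seed", 0))
    results: dict[str, dict] = {}
    rows, curve_rows, errors = [], [], []
    for i, cdict in enumerate(config.get("conditions", [])):
        try:
            cond = condition_from_dict(cdict, default_seed=master_seed + i)
            acq = acquisition_from_dict(acq_template)
            res = _condition_summary(cond, acq)
        except Exception as exc:  # noqa: BLE001 - per-condition isolation
            errors.append(f"{cdict.get('label', f'condition {i}')}: {exc}")
            continue
        results[cond.label] = res
        rows.append(res["row"])
        for lag, m, s, n in zip(res["ens"].lags, res["ens"].msd,
                                res["ens"].sem, res["ens"].n_obs):
            curve_rows.append({"condition_id": cond.label, "lag_s": lag,
                               "msd_um2": m, "sem_um2": s, "n": n})

    comp_rows = []
    for pair in config.get("comparisons", []):
        a, b = pair
        if a in results and b in results:
            t, p = compare_groups(results[a]["dts"], results[b]["dts"])
            comp_rows.append({"group_a": a, "group_b": b, "metric": "D_T",
                              "t_statistic": t, "p_value": p,
                              "significance": significance_tier(p)})

    tables = {
        "conditions": pd.DataFrame(rows),
        "msd_curves": pd.DataFrame(curve_rows),
        "comparisons": pd.DataFrame(
            comp_rows, columns=["group_a", "group_b", "metric", "t_statistic",
                                "p_value", "significance"]),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        log_lines = [f"guvmotors {__version__}", f"seed {master_seed}",
                     f"config_sha256 {cfg_hash}",
                     f"conditions_run {len(rows)}"]
        log_lines += [f"ERROR {e}" for e in errors]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    tables["_results"] = results  # in-memory extras for callers
    tables["_errors"] = errors
    return tables


def size_sweep_conditions(fuels=(0.0, 0.034, 0.85, 3.4), n_per_group: int = 15,
                          seed: int = 0, n_guvs: int = 5,
                          motor: MotorParams | None = None) -> list[dict]:
    """Condition dicts for the size-stratified experiment: for each size
    group and fuel level, ``n_guvs`` GUVs with diameters sampled within
    the group and ``n_per_group`` particles split across them."""
    rng = np.random.default_rng(seed)
    conds = []
    for group in SIZE_GROUPS:
        for fuel in fuels:
            for g in range(n_guvs):
                d = sample_guv_diameter(group, rng)
                conds.append({
                    "label": f"{group}_fuel{fuel}_guv{g}",
                    "fuel": fuel, "guv_diameter": d,
                    "n_particles": max(1, n_per_group // n_guvs),
                    "seed": int(rng.integers(2**31)),
                    **({"motor": asdict(motor)} if motor else {}),
                })
    return conds
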