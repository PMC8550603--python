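"""Linking encoding-model statistics to measured regularity scales.

Given the 45-condition regularity estimates from the full conjoint model
and a table of per-condition wavelet statistics, this module computes
per-parameter Pearson correlations, selects predictors by forward stepwise
regression (partial F-test entry, stop when the smallest entry p exceeds
alpha), and wires the whole pipeline together: stimuli -> simulated or
deposited responses -> model battery -> wavelet statistics ->
correlation / stepwise report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import conjoint, mlcm, stimuli, wavelets
from .conditions import N_CONDITIONS

__all__ = ["CorrelationReport", "RegressionResult", "correlate",
           "stepwise_forward", "run_pipeline"]


@dataclass
class CorrelationReport:
    """Pearson correlations of encoding statistics with regularity."""

    per_parameter: pd.Series
    per_model_mean: pd.Series

    @property
    def mean_r(self) -> float:
        return float(self.per_parameter.mean())


def correlate(parameters: pd.DataFrame, regularity: Sequence[float]
              ) -> CorrelationReport:
    """Correlate each parameter column with the 45 regularity estimates.

    Column names of the form ``<model>_<statistic>`` are also summarised
    as a per-model mean r.
    """
    y = np.asarray(regularity, dtype=float)
    if len(parameters) != len(y):
        raise ValueError("parameter table and regularity estimates must "
                         "cover the same conditions")
    rs = {}
    for col in parameters.columns:
        x = parameters[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"constant predictor {col!r}: correlation "
                          "undefined, reported as NaN", RuntimeWarning)
            rs[col] = np.nan
            continue
        rs[col] = float(stats.pearsonr(x, y)[0])
    per_param = pd.Series(rs)

    def model_of(col: str) -> str:
        matches = [m for m in wavelets.MODEL_NAMES if col.startswith(m + "_")]
        return max(matches, key=len) if matches else col

    groups = per_param.groupby(per_param.index.map(model_of))
    return CorrelationReport(per_parameter=per_param,
                             per_model_mean=groups.mean())


@dataclass
class RegressionResult:
    """Forward-stepwise regression outcome."""

    selected: list[str]
    coefficients: pd.Series          # includes 'intercept'
    r_squared: float
    adj_r_squared: float
    entry_p_values: pd.Series        # per selected predictor, in entry order
    excluded: list[str] = field(default_factory=list)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def stepwise_forward(predictors: pd.DataFrame, target: Sequence[float],
                     alpha: float = 0.05) -> RegressionResult:
    """Forward stepwise linear regression with partial F-test entry.

    At each step the candidate whose addition gives the smallest partial-F
    p-value (F with (1, n - k - 1) df) enters if that p-value is below
    ``alpha``; the procedure stops otherwise.  No removal step.  Ties are
    broken by the canonical column order of ``predictors``; constant
    columns (and a constant target) are excluded with a warning.
    """
    y = np.asarray(target, dtype=float)
    n = len(y)
    if len(predictors) != n:
        raise ValueError("predictors and target must have equal length")
    if np.std(y) == 0:
        raise ValueError("constant target: regression undefined")

    excluded = [c for c in predictors.columns
                if np.std(predictors[c].to_numpy(dtype=float)) == 0]
    for c in excluded:
        warnings.warn(f"constant predictor {c!r} excluded", RuntimeWarning)
    candidates = [c for c in predictors.columns if c not in excluded]

    selected: list[str] = []
    entry_p: dict[str, float] = {}
    Xsel = np.ones((n, 1))
    _, rss0 = _ols_rss(Xsel, y)
    while candidates:
        k = Xsel.shape[1] - 1            # predictors currently in the model
        df_resid = n - (k + 1) - 1
        if df_resid <= 0:
            break
        best = None
        for c in candidates:
            Xc = np.column_stack([Xsel, predictors[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(Xc) <= Xsel.shape[1]:
                continue                 # collinear with current model
            _, rss1 = _ols_rss(Xc, y)
            if rss1 <= 0:
                p = 0.0
            else:
                F = (rss0 - rss1) / (rss1 / df_resid)
                p = float(stats.f.sf(F, 1, df_resid))
            if best is None or p < best[0]:
                best = (p, c, rss1)
        if best is None or best[0] > alpha:
            break
        p, c, rss1 = best
        selected.append(c)
        entry_p[c] = p
        candidates.remove(c)
        Xsel = np.column_stack([Xsel, predictors[c].to_numpy(dtype=float)])
        rss0 = rss1

    beta, rss = _ols_rss(Xsel, y)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    k = len(selected)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    coef = pd.Series(beta, index=["intercept"] + selected)
    return RegressionResult(selected=selected, coefficients=coef,
                            r_squared=r2, adj_r_squared=float(adj),
                            entry_p_values=pd.Series(entry_p),
                            excluded=excluded)


def run_pipeline(config: Mapping) -> dict:
    """End-to-end analysis from a configuration mapping.

    Recognised keys (all optional unless stated):

    ``seed``              master seed for every random stage (default 0)
    ``response_csvs``     list of deposited-format CSV paths; when absent,
                          ``n_observers`` synthetic observers are simulated
    ``n_observers``       number of simulated observers (default 5)
    ``n_reps``            repetitions per pair for simulation (default 4)
    ``observer_means``    45-vector of condition means for the simulated
                          observers (default: the package's synthetic scale)
    ``wavelet_samples``   stimulus samples per condition (default 10)
    ``raster_size``       analysis raster in pixels (default 256)
    ``alpha``             stepwise entry threshold (default 0.05)
    ``group_normalization``  'max_abs' (default) or 'jt5'
    ``out_dir``           directory for CSV/JSON outputs (optional)

    Returns a report dict with the battery tables, group estimates,
    wavelet parameter table, correlation report and stepwise result.
    Reruns with the same configuration are bit-reproducible.
    """
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    pairs = conjoint.enumerate_pairs(N_CONDITIONS)

    # --- responses -------------------------------------------------------
    tables: list[conjoint.PairResponseTable] = []
    if config.get("response_csvs"):
        for path in config["response_csvs"]:
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"stage 'responses': missing input {path}")
            tables.append(conjoint.read_responses(path))
    else:
        n_obs = int(config.get("n_observers", 5))
        n_reps = int(config.get("n_reps", 4))
        means = np.asarray(config.get(
            "observer_means", stimuli.synthetic_observer_means()), dtype=float)
        if means.shape[0] != N_CONDITIONS:
            raise ValueError("stage 'responses': observer_means must have "
                             f"{N_CONDITIONS} entries")
        for i in range(n_obs):
            obs = stimuli.SimulatedObserver(condition_means=means)
            tables.append(stimuli.simulate_observer(
                obs, pairs, n_reps, seed=seed + 1000 + i))

    # --- conjoint battery ------------------------------------------------
    batteries, fits12, one_factor = [], [], []
    for table in tables:
        battery, fits = mlcm.run_comparisons(table)
        batteries.append(battery)
        fits12.append(fits[12])
        one_factor.append(mlcm.one_factor_estimates(table))
    battery_all = pd.concat(
        batteries, keys=[f"obs{i + 1}" for i in range(len(batteries))],
        names=["observer", "effect"])

    group_mode = str(config.get("group_normalization", "max_abs"))
    estimates = [mlcm.full_model_estimates(f) for f in fits12]
    group = mlcm.normalize_group(estimates, anchor=group_mode)
    group_one_factor = mlcm.normalize_group(one_factor, anchor="jt5")

    # --- wavelet statistics ---------------------------------------------
    params = wavelets.condition_parameter_table(
        n_samples=int(config.get("wavelet_samples", 10)),
        seed=seed + 2000,
        raster_size=int(config.get("raster_size", 256)))

    # --- linking ---------------------------------------------------------
    target = group.mean.to_numpy()
    report = correlate(params, target)
    ten = [c for c in params.columns
           if c.startswith(("sf_", "sf_x_ori_"))]
    step = stepwise_forward(params[ten], target, alpha=alpha)

    result = {
        "seed": seed,
        "n_observers": len(tables),
        "battery": battery_all,
        "group_estimates": group,
        "group_one_factor": group_one_factor,
        "wavelet_parameters": params,
        "correlations": report,
        "stepwise": step,
    }

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        battery_all.to_csv(out / "battery.tsv", sep="\t")
        group.per_observer.to_csv(out / "group_estimates_per_observer.csv")
        pd.DataFrame({"mean": group.mean, "se": group.se}).to_csv(
            out / "group_estimates.csv")
        params.to_csv(out / "wavelet_parameters.csv")
        report.per_parameter.to_csv(out / "correlations.csv",
                                    header=["pearson_r"])
        summary = {
            "seed": seed,
            "n_observers": len(tables),
            "stepwise_selected": step.selected,
            "stepwise_r_squared": step.r_squared,
            "stepwise_adj_r_squared": step.adj_r_squared,
            "per_model_mean_r": report.per_model_mean.to_dict(),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return result
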