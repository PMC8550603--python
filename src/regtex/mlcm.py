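"""Three-factor Maximum Likelihood Conjoint Measurement (MLCM).

An observer's choice between two textures is modelled through the
difference of their internal regularity values,

    Delta = R_ijk - R_pqr + eps,      eps ~ N(0, 1),

so the probability of choosing the first stimulus is Phi(R_ijk - R_pqr)
(probit decision rule; the internal noise SD is fixed at 1 for
identifiability, so all estimates are in noise-SD units).

Twelve nested specifications of R define the model battery:

==== ======================================== ==========
 id   R_ijk                                    free params
==== ======================================== ==========
 1    0 (baseline)                                   0
 2    R(spacing_i)                                   2
 3    R(size_j)                                      2
 4    R(jitter_k)                                    4
 5    R(spacing_i) + R(jitter_k)                     6
 6    R(size_j) + R(jitter_k)                        6
 7    R(spacing_i) + R(size_j)                       4
 8    R(spacing_i, jitter_k)                        14
 9    R(size_j, jitter_k)                           14
 10   R(spacing_i, size_j)                           8
 11   all mains + all two-way interactions          28
 12   R(spacing_i, size_j, jitter_k) (full)         44
==== ======================================== ==========

The first level of every factor (and every cell touching level 1 in
models 8-11, and the (1,1,1) cell in model 12) is pinned at 0 so each fit
has a unique solution.  Models are compared by likelihood-ratio tests:
the deviance difference between nested fits is asymptotically chi-square
with df equal to the difference in free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import (N_CONDITIONS, N_JITTER, N_SIZE, N_SPACING,
                         StimulusCondition, all_conditions,
                         condition_from_index)
from .conjoint import PairResponseTable

__all__ = [
    "MODEL_IDS", "FREE_PARAMETER_COUNTS", "ModelSpec", "DesignMatrix",
    "FitResult", "LRTResult", "GroupEstimates", "model_spec",
    "build_design", "fit_probit", "fit_model", "lr_test",
    "run_comparisons", "full_model_estimates", "one_factor_estimates",
    "normalize_group", "interaction_profile", "jitter_effect_ratio",
]

MODEL_IDS = tuple(range(1, 13))

FREE_PARAMETER_COUNTS = {1: 0, 2: 2, 3: 2, 4: 4, 5: 6, 6: 6, 7: 4,
                         8: 14, 9: 14, 10: 8, 11: 28, 12: 44}

#: The seven effect tests of the battery: (name, simple model, complex model).
BATTERY = [
    ("main_spacing", 1, 2),
    ("main_size", 1, 3),
    ("main_jitter", 1, 4),
    ("interaction_spacing_jitter", 5, 8),
    ("interaction_size_jitter", 6, 9),
    ("interaction_spacing_size", 7, 10),
    ("threeway", 11, 12),
]

_TWO_WAY = {"interaction_spacing_jitter", "interaction_size_jitter",
            "interaction_spacing_size"}


def _main_names(factor: str, n_levels: int) -> list[str]:
    return [f"{factor}{lvl}" for lvl in range(2, n_levels + 1)]


def _cell_names(fa: str, na: int, fb: str, nb: int) -> list[str]:
    return [f"{fa}{a}.{fb}{b}"
            for a in range(1, na + 1) for b in range(1, nb + 1)
            if not (a == 1 and b == 1)]


def _interaction_names(fa: str, na: int, fb: str, nb: int) -> list[str]:
    return [f"{fa}{a}:{fb}{b}"
            for a in range(2, na + 1) for b in range(2, nb + 1)]


def _parameter_names(model_id: int) -> list[str]:
    sp, sz, jt = ("sp", N_SPACING), ("sz", N_SIZE), ("jt", N_JITTER)
    if model_id == 1:
        return []
    if model_id == 2:
        return _main_names(*sp)
    if model_id == 3:
        return _main_names(*sz)
    if model_id == 4:
        return _main_names(*jt)
    if model_id == 5:
        return _main_names(*sp) + _main_names(*jt)
    if model_id == 6:
        return _main_names(*sz) + _main_names(*jt)
    if model_id == 7:
        return _main_names(*sp) + _main_names(*sz)
    if model_id == 8:
        return _cell_names(*sp, *jt)
    if model_id == 9:
        return _cell_names(*sz, *jt)
    if model_id == 10:
        return _cell_names(*sp, *sz)
    if model_id == 11:
        return (_main_names(*sp) + _main_names(*sz) + _main_names(*jt)
                + _interaction_names(*sp, *jt) + _interaction_names(*sz, *jt)
                + _interaction_names(*sp, *sz))
    if model_id == 12:
        return [f"sp{i}.sz{j}.jt{k}"
                for i in range(1, N_SPACING + 1)
                for j in range(1, N_SIZE + 1)
                for k in range(1, N_JITTER + 1)
                if (i, j, k) != (1, 1, 1)]
    raise ValueError(f"model_id must be in 1..12, got {model_id}")


def _condition_terms(model_id: int, cond: StimulusCondition) -> list[str]:
    """Parameter names a condition loads on (each with weight +1)."""
    i, j, k = cond.spacing_level, cond.size_level, cond.jitter_level
    terms: list[str] = []
    if model_id in (2, 5, 7, 11) and i > 1:
        terms.append(f"sp{i}")
    if model_id in (3, 6, 7, 11) and j > 1:
        terms.append(f"sz{j}")
    if model_id in (4, 5, 6, 11) and k > 1:
        terms.append(f"jt{k}")
    if model_id == 8 and (i, k) != (1, 1):
        terms.append(f"sp{i}.jt{k}")
    if model_id == 9 and (j, k) != (1, 1):
        terms.append(f"sz{j}.jt{k}")
    if model_id == 10 and (i, j) != (1, 1):
        terms.append(f"sp{i}.sz{j}")
    if model_id == 11:
        if i > 1 and k > 1:
            terms.append(f"sp{i}:jt{k}")
        if j > 1 and k > 1:
            terms.append(f"sz{j}:jt{k}")
        if i > 1 and j > 1:
            terms.append(f"sp{i}:sz{j}")
    if model_id == 12 and (i, j, k) != (1, 1, 1):
        terms.append(f"sp{i}.sz{j}.jt{k}")
    return terms


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameterisation of one battery model."""

    model_id: int
    parameter_names: tuple[str, ...]

    @property
    def free_parameter_count(self) -> int:
        return len(self.parameter_names)

    def condition_row(self, cond: StimulusCondition) -> np.ndarray:
        row = np.zeros(len(self.parameter_names))
        cols = {name: idx for idx, name in enumerate(self.parameter_names)}
        for term in _condition_terms(self.model_id, cond):
            row[cols[term]] = 1.0
        return row

    def condition_matrix(self) -> np.ndarray:
        """(45, p) loading of every condition on the free parameters."""
        return np.vstack([self.condition_row(c) for c in all_conditions()])


def model_spec(model_id: int) -> ModelSpec:
    spec = ModelSpec(model_id, tuple(_parameter_names(model_id)))
    assert spec.free_parameter_count == FREE_PARAMETER_COUNTS[model_id]
    return spec


@dataclass
class DesignMatrix:
    """Difference-coded design over aggregated pairs.

    Row r encodes one unordered condition pair as the loading of its
    first-listed condition minus that of the second (entries -1/0/+1);
    ``successes`` counts trials on which the first condition won out of
    ``totals``.
    """

    spec: ModelSpec
    X: np.ndarray                   # (n_pairs, p)
    successes: np.ndarray           # (n_pairs,)
    totals: np.ndarray              # (n_pairs,)
    pairs: np.ndarray               # (n_pairs, 2) condition indices

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.spec.parameter_names

    def column_rank(self) -> int:
        if self.X.shape[1] == 0:
            return 0
        return int(np.linalg.matrix_rank(self.X))


def build_design(model_id: int, table: PairResponseTable) -> DesignMatrix:
    """Construct the difference-coded probit design for one model.

    Aggregates the trial table over unordered pairs (the grouped-binomial
    likelihood is identical to the Bernoulli per-trial one) and reports an
    explicit singularity error if the design is rank deficient on the
    given data.
    """
    if len(table) == 0:
        raise ValueError("response table is empty")
    spec = model_spec(model_id)
    agg = table.aggregate()
    pairs = np.array(list(agg.index))
    cond_rows = spec.condition_matrix()
    X = cond_rows[pairs[:, 0]] - cond_rows[pairs[:, 1]]
    design = DesignMatrix(spec=spec, X=X,
                          successes=agg["n_first"].to_numpy(dtype=float),
                          totals=agg["n_total"].to_numpy(dtype=float),
                          pairs=pairs)
    if design.column_rank() < spec.free_parameter_count:
        raise np.linalg.LinAlgError(
            f"model {model_id} design is rank deficient on these data "
            f"(rank {design.column_rank()} < "
            f"{spec.free_parameter_count} parameters)")
    return design


@dataclass
class FitResult:
    """Maximum-likelihood probit fit of one model."""

    spec: ModelSpec
    coefficients: pd.Series         # perceived regularity, noise-SD units
    standard_errors: pd.Series
    log_likelihood: float
    residual_deviance: float
    converged: bool
    n_trials: int
    n_iter: int = 0

    @property
    def model_id(self) -> int:
        return self.spec.model_id


_MU_EPS = 1e-12


def _binomial_loglik(successes, totals, mu) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(np.sum(successes * np.log(mu)
                        + (totals - successes) * np.log(1 - mu)))


def _saturated_loglik(successes, totals) -> float:
    p = successes / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (np.where(successes > 0, successes * np.log(p), 0.0)
                 + np.where(totals - successes > 0,
                            (totals - successes) * np.log(1 - p), 0.0))
    return float(terms.sum())


def fit_probit(design: DesignMatrix, *, tol: float = 1e-8,
               max_iter: int = 100,
               separation_bound: float = 10.0) -> FitResult:
    """Grouped-binomial probit fit by iteratively reweighted least squares.

    Convergence is declared when the deviance changes by less than ``tol``;
    runaway coefficients (|beta| above ``separation_bound``) flag complete
    separation and the fit is returned with ``converged=False`` and a
    warning.  Standard errors come from the inverse Fisher information at
    the optimum.
    """
    X, y, n = design.X, design.successes, design.totals
    p = X.shape[1]
    n_trials = int(n.sum())
    sat = _saturated_loglik(y, n)

    if p == 0:
        ll = _binomial_loglik(y, n, np.full(len(y), 0.5))
        return FitResult(design.spec, pd.Series(dtype=float),
                         pd.Series(dtype=float), ll, 2 * (sat - ll),
                         True, n_trials)

    def deviance_of(b):
        return 2 * (sat - _binomial_loglik(y, n, stats.norm.cdf(X @ b)))

    beta = np.zeros(p)
    old_dev = deviance_of(beta)
    converged = False
    n_iter = 0
    info = np.eye(p)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(stats.norm.cdf(eta), _MU_EPS, 1 - _MU_EPS)
        phi = np.maximum(stats.norm.pdf(eta), 1e-300)
        w = n * phi ** 2 / (mu * (1 - mu))
        z = eta + (y / n - mu) / phi
        Xw = X * w[:, None]
        info = X.T @ Xw
        proposal = np.linalg.solve(info, Xw.T @ z)
        # step-halving keeps the deviance monotone through early
        # overshoots of the working-response update
        step = proposal - beta
        dev = deviance_of(proposal)
        for _ in range(10):
            if dev <= old_dev + tol:
                break
            step *= 0.5
            dev = deviance_of(beta + step)
        beta = beta + step
        if abs(old_dev - dev) < tol:
            converged = True
            break
        old_dev = dev

    ll = _binomial_loglik(y, n, stats.norm.cdf(X @ beta))
    if np.max(np.abs(beta), initial=0.0) > separation_bound:
        warnings.warn(
            f"model {design.spec.model_id}: probable complete separation "
            f"(|coefficient| > {separation_bound}); estimates unreliable",
            RuntimeWarning, stacklevel=2)
        converged = False
    elif not converged:
        warnings.warn(
            f"model {design.spec.model_id}: probit IRLS did not converge "
            f"in {n_iter} iterations", RuntimeWarning, stacklevel=2)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    names = list(design.parameter_names)
    return FitResult(design.spec,
                     pd.Series(beta, index=names),
                     pd.Series(se, index=names),
                     ll, 2 * (sat - ll), converged, n_trials, n_iter)


def fit_model(model_id: int, table: PairResponseTable, **kwargs) -> FitResult:
    """Build the design for ``model_id`` on ``table`` and fit it."""
    return fit_probit(build_design(model_id, table), **kwargs)


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested fits."""

    simple_id: int
    complex_id: int
    deviance_difference: float
    degrees_of_freedom: int
    p_value: float


def lr_test(simple: FitResult, complex: FitResult) -> LRTResult:
    """Deviance difference, df and chi-square upper-tail p for nested fits."""
    if simple.n_trials != complex.n_trials:
        raise ValueError("nested fits must use the same data")
    df = complex.spec.free_parameter_count - simple.spec.free_parameter_count
    if df < 0:
        raise ValueError("'complex' model has fewer parameters than 'simple'")
    dev = 2.0 * (complex.log_likelihood - simple.log_likelihood)
    dev = max(dev, 0.0)     # guard tiny negative values at convergence tol
    p = 1.0 if df == 0 and dev == 0.0 else float(stats.chi2.sf(dev, max(df, 1)))
    if df == 0:
        p = 1.0 if dev <= 0 else 0.0
    return LRTResult(simple.model_id, complex.model_id, dev, df, p)


def run_comparisons(table: PairResponseTable, *, alpha: float = 0.05,
                    threeway_alpha: float = 0.01
                    ) -> tuple[pd.DataFrame, dict[int, FitResult]]:
    """Fit all twelve models and run the three-step deviance battery.

    Returns the battery table -- three main effects (models 2/3/4 vs 1),
    three two-way interactions (8 vs 5, 9 vs 6, 10 vs 7; significance
    Bonferroni-corrected across the three tests) and the three-way test
    (12 vs 11, read at the stricter ``threeway_alpha``) -- together with
    the fitted models keyed by id.
    """
    fits = {mid: fit_model(mid, table) for mid in MODEL_IDS}
    rows = []
    for name, simple_id, complex_id in BATTERY:
        res = lr_test(fits[simple_id], fits[complex_id])
        adj = min(res.p_value * 3, 1.0) if name in _TWO_WAY else res.p_value
        crit = threeway_alpha if name == "threeway" else alpha
        rows.append({
            "effect": name,
            "simple_model": simple_id,
            "complex_model": complex_id,
            "deviance": res.deviance_difference,
            "df": res.degrees_of_freedom,
            "p_value": res.p_value,
            "p_adjusted": adj,
            "significant": adj < crit,
        })
    return pd.DataFrame(rows).set_index("effect"), fits


def full_model_estimates(fit: FitResult) -> pd.Series:
    """45-condition regularity estimates from a full-model (12) fit.

    The reference condition (spacing 1, size 1, jitter 1) is 0 by
    construction; values are indexed by canonical condition index.
    """
    if fit.model_id != 12:
        raise ValueError("full_model_estimates requires a model-12 fit")
    values = np.zeros(N_CONDITIONS)
    for cond in all_conditions():
        name = f"sp{cond.spacing_level}.sz{cond.size_level}.jt{cond.jitter_level}"
        if name in fit.coefficients.index:
            values[cond.index] = fit.coefficients[name]
    return pd.Series(values, index=range(N_CONDITIONS), name="regularity")


def one_factor_estimates(table: PairResponseTable) -> pd.Series:
    """Level estimates from the three one-factor models (2, 3, 4).

    Returns a Series over 'sp1'..'jt5' (reference levels at 0), the
    per-observer ingredients of the normalized group scale.
    """
    values: dict[str, float] = {"sp1": 0.0, "sz1": 0.0, "jt1": 0.0}
    for mid in (2, 3, 4):
        fit = fit_model(mid, table)
        values.update(fit.coefficients.to_dict())
    order = (_main_names("sp", N_SPACING) + _main_names("sz", N_SIZE)
             + _main_names("jt", N_JITTER))
    return pd.Series(values).reindex(["sp1", "sz1", "jt1"] + order).dropna()


@dataclass
class GroupEstimates:
    """Per-observer normalized estimates and their across-observer summary."""

    per_observer: pd.DataFrame      # observers x parameters, normalized
    mean: pd.Series
    se: pd.Series
    anchor: str


def normalize_group(per_observer: Sequence[pd.Series],
                    anchor: str = "jt5") -> GroupEstimates:
    """Normalize each observer's estimates to a common anchor and average.

    Each observer's values are divided by the magnitude of that observer's
    estimate at ``anchor`` with the sign convention that the anchor maps to
    -1 (the regularity *decrease* from jitter level 1 to 5 is the unit).
    With ``anchor="max_abs"`` each observer is instead normalized by their
    maximum absolute estimate (keeping sign).  The group mean and the
    across-observer standard error are reported per parameter.
    """
    normed = []
    for est in per_observer:
        if anchor == "max_abs":
            scale = float(np.abs(est).max())
            normed.append(est / scale)
        else:
            if anchor not in est.index:
                raise KeyError(f"anchor {anchor!r} not in estimates")
            a = float(est[anchor])
            if a == 0:
                raise ZeroDivisionError(f"anchor {anchor!r} estimate is 0")
            normed.append(-est / a)
    frame = pd.DataFrame(normed).reset_index(drop=True)
    n_obs = len(frame)
    se = frame.std(ddof=1) / np.sqrt(n_obs) if n_obs > 1 else frame.iloc[0] * 0.0
    return GroupEstimates(per_observer=frame, mean=frame.mean(), se=se,
                          anchor=anchor)


def interaction_profile(fit: FitResult) -> pd.DataFrame:
    """Cell estimates of a two-interactive-factors fit as a level grid.

    For a model-8 fit, rows are spacing levels and columns jitter levels
    (model 9: size x jitter; model 10: spacing x size), with the (1, 1)
    reference cell at 0.
    """
    layout = {8: ("sp", N_SPACING, "jt", N_JITTER),
              9: ("sz", N_SIZE, "jt", N_JITTER),
              10: ("sp", N_SPACING, "sz", N_SIZE)}
    if fit.model_id not in layout:
        raise ValueError("interaction_profile requires a model 8, 9 or 10 fit")
    fa, na, fb, nb = layout[fit.model_id]
    grid = np.zeros((na, nb))
    for a in range(1, na + 1):
        for b in range(1, nb + 1):
            name = f"{fa}{a}.{fb}{b}"
            if name in fit.coefficients.index:
                grid[a - 1, b - 1] = fit.coefficients[name]
    return pd.DataFrame(grid,
                        index=[f"{fa}{a}" for a in range(1, na + 1)],
                        columns=[f"{fb}{b}" for b in range(1, nb + 1)])


def jitter_effect_ratio(profile: pd.DataFrame,
                        level_a: int = 1, level_b: int = 3) -> float:
    """Ratio of the jitter level-1-to-5 regularity drop between two rows
    of a spacing-x-jitter (or size-x-jitter) interaction profile."""
    drop = profile["jt1"] - profile["jt5"]
    return float(drop.iloc[level_a - 1] / drop.iloc[level_b - 1])
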