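"""Covariate-adjusted group comparison of subject-level extrema summaries.

The model is an ordinary least squares ANCOVA:

    outcome ~ intercept + group + age + brain_volume

with a two-level group factor coded 0/1 (alphabetically first level as the
reference) and two continuous covariates. The group effect is tested with a
single-degree-of-freedom F (equal to the squared t of the group contrast);
"estimated marginal means" are model predictions per group with both
covariates fixed at their grand means, with standard errors from the
coefficient covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "AncovaResult",
    "ancova_group_effect",
    "adjusted_group_means",
    "type_one_error_sweep",
]

REQUIRED_COLUMNS = ("group", "age_years", "brain_volume_ml", "outcome")
N_PARAMS = 4  # intercept + group + age + volume


@dataclass(frozen=True)
class AncovaResult:
    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    coefficients: dict
    group_levels: tuple
    adjusted_means: dict  # group -> (mean, se)
    t_group: float
    n: int
    _cov_params: np.ndarray
    _covariate_means: tuple


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    if table[list(REQUIRED_COLUMNS)].isna().any().any():
        bad = table.columns[table[list(REQUIRED_COLUMNS)].isna().any()].tolist()
        raise ValueError(f"missing values among analyzed rows in: {bad}")
    levels = sorted(table["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, found {levels}")
    if len(table) < N_PARAMS + 1:
        raise ValueError(f"need at least {N_PARAMS + 1} subjects, got {len(table)}")
    return table


def _design(table: pd.DataFrame):
    levels = tuple(sorted(table["group"].unique()))
    indicator = (table["group"] == levels[1]).astype(float).to_numpy()
    X = np.column_stack(
        [
            np.ones(len(table)),
            indicator,
            table["age_years"].to_numpy(float),
            table["brain_volume_ml"].to_numpy(float),
        ]
    )
    names = ("intercept", f"group[{levels[1]}]", "age_years", "brain_volume_ml")
    for j, name in enumerate(names[2:], start=2):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant; design matrix is rank deficient")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    return X, names, levels


def ancova_group_effect(table: pd.DataFrame) -> AncovaResult:
    """Fit the ANCOVA and test the group effect.

    The F statistic is the extra-sum-of-squares comparison between the full
    model and the reduced model that drops only the group indicator, on
    (1, n - 4) degrees of freedom.
    """
    table = _validate_table(table)
    X, names, levels = _design(table)
    y = table["outcome"].to_numpy(float)

    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    df_den = len(table) - N_PARAMS
    # a residual sum of squares at rounding-noise level means a perfect fit:
    # the group term explains nothing beyond it, so F is 0 by convention
    noise_floor = 1e-12 * max(float(y @ y), 1.0)
    if full.ssr <= noise_floor:
        f_stat = 0.0
    else:
        f_stat = max(float((reduced.ssr - full.ssr) / (full.ssr / df_den)), 0.0)
    p = float(scipy.stats.f.sf(f_stat, 1, df_den))

    cov_means = (
        float(table["age_years"].mean()),
        float(table["brain_volume_ml"].mean()),
    )
    cov_params = np.asarray(full.cov_params())
    adjusted = {}
    for g, ind in zip(levels, (0.0, 1.0)):
        c = np.array([1.0, ind, cov_means[0], cov_means[1]])
        adjusted[g] = (float(c @ full.params), float(np.sqrt(c @ cov_params @ c)))

    return AncovaResult(
        f_statistic=f_stat,
        df_numerator=1,
        df_denominator=df_den,
        p_value=p,
        coefficients=dict(zip(names, (float(b) for b in full.params))),
        group_levels=levels,
        adjusted_means=adjusted,
        t_group=float(full.tvalues[1]),
        n=len(table),
        _cov_params=cov_params,
        _covariate_means=cov_means,
    )


def adjusted_group_means(table: pd.DataFrame, fit: AncovaResult) -> dict:
    """Estimated marginal means: per-group prediction at grand-mean covariates,
    with SE from the coefficient covariance of the prediction contrast."""
    if len(table) != fit.n or tuple(sorted(table["group"].unique())) != fit.group_levels:
        raise ValueError("fit does not correspond to this cohort table")
    return dict(fit.adjusted_means)


def type_one_error_sweep(
    spec,
    n_replicates: int = 500,
    alpha: float = 0.05,
    *,
    criterion=None,
    outcome: str = "mean_trough_duration_seconds",
    seed: int = 0,
) -> float:
    """Fraction of replicate synthetic cohorts whose group test rejects at alpha.

    With identical group dynamics this measures the type-I error rate of the
    whole pipeline (simulate -> RSS -> extrema -> ANCOVA); with differing
    dynamics it measures power. Reproducible under ``seed``.
    """
    from .extrema import TroughCriterion
    from .pipeline import cohort_outcome_table
    from .synthetic import simulate_cohort

    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must lie in [0, 1]")
    if n_replicates < 20:
        warnings.warn(f"n_replicates={n_replicates} is small; estimate will be noisy")
    if criterion is None:
        criterion = TroughCriterion(0.0, "adjacent-sample")
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rejections = 0
    for rep_seed in seeds:
        subjects, cov_table = simulate_cohort(spec, seed=int(rep_seed))
        table = cohort_outcome_table(subjects, cov_table, criterion, outcome=outcome)
        fit = ancova_group_effect(table)
        if fit.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
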