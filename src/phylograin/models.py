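"""Linear mixed-effects models linking diversity to terrain and competition.

Per spatial grain and life stage the package fits, by REML,

    SR/PD  ~ CI + Elevation + Aspect + Slope + TPI + TRI + Flowdir
    NRI/NTI ~ the same predictors + SR

with a random intercept per group (by default the quadrat's dominant
species, i.e. the species with the largest basal area in the quadrat;
alternatively the 20 m census block).  Predictors are z-scored within
each design so coefficients are comparable effect sizes.  When the
random-intercept variance collapses to the boundary or the mixed fit
fails, the model falls back to ordinary least squares with a warning and
a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Fixed predictors of the SR / PD model, in coefficient order.
EQ2_PREDICTORS: tuple[str, ...] = (
    "ci", "elevation", "aspect", "slope", "tpi", "tri", "flowdir",
)
#: The NRI / NTI model adds species richness to the same set.
EQ3_PREDICTORS: tuple[str, ...] = EQ2_PREDICTORS + ("sr",)

_RESPONSES = {"sr", "pd", "nri", "nti"}

#: Significance tiers as reported in coefficient tables.
_TIERS = ((0.001, "c"), (0.01, "b"), (0.05, "a"))


def significance_tier(p: float) -> str:
    """'c' for p < 0.001, 'b' for p < 0.01, 'a' for p < 0.05, else 'ns'."""
    if np.isnan(p):
        return "ns"
    for cut, tier in _TIERS:
        if p < cut:
            return tier
    return "ns"


@dataclass
class ModelDesign:
    """A ready-to-fit design: z-scored predictors, response, grouping."""

    frame: pd.DataFrame
    response: str
    predictors: tuple[str, ...]
    group_col: str
    scale: float | None = None
    stage: str | None = None
    n_dropped: int = 0


@dataclass
class ModelFit:
    """Coefficients and variance components of one fitted model."""

    design: ModelDesign
    params: pd.Series
    se: pd.Series
    stat: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    n: int
    converged: bool
    method: str  # "mixedlm" or "ols"


def build_design(
    metrics: pd.DataFrame,
    response: str,
    scale: float | None = None,
    stage: str | None = None,
    predictors: tuple[str, ...] | None = None,
    group_col: str = "group",
    include_roughness: bool = False,
    min_rows_per_predictor: int = 10,
) -> ModelDesign:
    """Assemble and standardize the design for one response/scale/stage.

    Rows with an undefined response or any missing predictor (e.g. NRI in
    quadrats below two species) are dropped and counted.  Predictors are
    z-scored within the retained rows.  Fewer than
    ``min_rows_per_predictor`` rows per predictor refuses to fit.
    ``include_roughness`` appends the 3x3 elevation-range covariate to
    the terrain set.
    """
    response = response.lower()
    if response not in _RESPONSES:
        raise ValueError(f"response must be one of {sorted(_RESPONSES)}")
    if predictors is None:
        predictors = EQ3_PREDICTORS if response in {"nri", "nti"} else EQ2_PREDICTORS
        if include_roughness:
            predictors = predictors[:7] + ("roughness",) + predictors[7:]
    sub = metrics
    if scale is not None and "scale" in sub.columns:
        sub = sub[sub["scale"] == scale]
    if stage is not None and "stage" in sub.columns:
        sub = sub[sub["stage"] == stage]
    cols = [response, *predictors, group_col]
    missing = [c for c in cols if c not in sub.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    frame = sub.loc[:, cols].copy()
    n0 = len(frame)
    frame = frame.dropna()
    n_dropped = n0 - len(frame)
    if len(frame) < min_rows_per_predictor * len(predictors):
        raise ValueError(
            f"only {len(frame)} usable rows for {len(predictors)} predictors "
            f"(need >= {min_rows_per_predictor * len(predictors)})"
        )
    for col in predictors:
        vals = frame[col].to_numpy(dtype=float)
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"predictor {col!r} has zero variance in this design")
        frame[col] = (vals - vals.mean()) / sd
    return ModelDesign(
        frame=frame.reset_index(drop=True),
        response=response,
        predictors=tuple(predictors),
        group_col=group_col,
        scale=scale,
        stage=stage,
        n_dropped=n_dropped,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for k in range(1, X.shape[1]):  # skip intercept
        others = np.delete(X, k, axis=1)
        resid = X[:, k] - others @ np.linalg.lstsq(others, X[:, k], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, k])):
            bad.append(names[k])
    return bad


def fit_lmm(design: ModelDesign) -> ModelFit:
    """REML fit of the design's random-intercept mixed model.

    Wald tests per coefficient; a boundary (zero) group variance or
    non-convergence triggers an ordinary-least-squares fallback, flagged
    in ``method`` and by a RuntimeWarning.
    """
    frame = design.frame
    names = ["intercept", *design.predictors]
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in design.predictors]
    )
    y = frame[design.response].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"singular design; collinear predictors: {bad}")
    groups = frame[design.group_col].to_numpy()

    result = None
    if len(np.unique(groups)) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, X, groups=groups)
                result = model.fit(reml=True)
            except (np.linalg.LinAlgError, ValueError):
                result = None
    boundary = result is not None and float(np.asarray(result.cov_re)[0, 0]) < 1e-4 * float(
        result.scale
    )
    if (
        result is not None
        and not boundary
        and np.all(np.isfinite(result.bse[: X.shape[1]]))
    ):
        group_var = float(np.asarray(result.cov_re)[0, 0])
        params = pd.Series(np.asarray(result.params)[: X.shape[1]], index=names)
        se = pd.Series(np.asarray(result.bse)[: X.shape[1]], index=names)
        stat = params / se
        dof = len(y) - X.shape[1]
        pvals = pd.Series(2 * stats.t.sf(np.abs(stat), dof), index=names)
        return ModelFit(
            design=design, params=params, se=se, stat=stat, pvalues=pvals,
            group_var=group_var, resid_var=float(result.scale), n=len(y),
            converged=bool(result.converged), method="mixedlm",
        )

    warnings.warn(
        "random-intercept variance at the zero boundary, singleton grouping, or "
        "non-convergence; falling back to ordinary least squares",
        RuntimeWarning,
        stacklevel=2,
    )
    ols = sm.OLS(y, X).fit()
    params = pd.Series(ols.params, index=names)
    se = pd.Series(ols.bse, index=names)
    stat = params / se
    pvals = pd.Series(ols.pvalues, index=names)
    return ModelFit(
        design=design, params=params, se=se, stat=stat, pvalues=pvals,
        group_var=0.0, resid_var=float(ols.mse_resid), n=len(y),
        converged=True, method="ols",
    )


def coefficient_grid(fits: list[ModelFit]) -> pd.DataFrame:
    """Tidy long-format coefficient table over response x scale x stage.

    One row per fitted term with estimate, SE, p and significance tier
    ('a' p<0.05, 'b' p<0.01, 'c' p<0.001, else 'ns') — the tabular
    analogue of a forest plot.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for fit in fits:
        d = fit.design
        for term in fit.params.index:
            p = float(fit.pvalues[term])
            rows.append(
                {
                    "response": d.response,
                    "scale": d.scale,
                    "stage": d.stage if d.stage is not None else "community",
                    "term": term,
                    "estimate": float(fit.params[term]),
                    "se": float(fit.se[term]),
                    "p": p,
                    "tier": significance_tier(p),
                    "method": fit.method,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
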