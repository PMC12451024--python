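"""Brain-behavior association statistics.

Covers the region-wise statistics run on FA-weighted nodal degree: ANCOVA
group contrasts, covariate-adjusted partial-correlation screening with
Benjamini-Hochberg FDR, Fisher r-to-z comparison of correlations between
groups, and hierarchical regression with per-step R-squared change and
collinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import NodalStrengthTable


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept-plus-covariates design matrix, with a rank check."""
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariates not conformable with data length")
    x = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return x


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


@dataclass
class PartialCorrelationResult:
    region: str
    r: float
    df: int
    p_raw: float
    p_adjusted: float | None
    n: int
    k: int

    @property
    def significant(self) -> bool:
        return self.p_adjusted is not None and self.p_adjusted < 0.05


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    region: str = "",
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (with intercept) by
    least squares; r is the Pearson correlation of the residuals.  The
    two-tailed p comes from t = r*sqrt(df)/sqrt(1-r^2) with df = n - 2 - k,
    where k is the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    design = _design(covariates, n)
    k = design.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        p = 0.0
    else:
        t = r_clipped * np.sqrt(df) / np.sqrt(1 - r_clipped**2)
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        region=region, r=r, df=df, p_raw=p, p_adjusted=None, n=n, k=k
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, with the
    original input order restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def screen_hubs(
    strengths: NodalStrengthTable,
    behavior: Sequence[float],
    covariates: np.ndarray | None = None,
    q: float = 0.05,
) -> list[PartialCorrelationResult]:
    """Region-wise partial-correlation screening with BH-FDR.

    One covariate-adjusted partial correlation per region between its nodal
    strength and the behavioral measure; BH adjustment across the regions
    of this one measure.  Regions with adjusted p below ``q`` are hubs.
    """
    behavior = np.asarray(behavior, dtype=float)
    n, n_regions = strengths.values.shape
    if len(behavior) != n:
        raise ValueError("behavior vector not conformable with strengths")
    design = _design(covariates, n)
    k = design.shape[1] - 1
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    # Residualize everything once; region loop collapses to vector algebra.
    rb = _residualize(behavior, design)
    rs = _residualize(strengths.values, design)
    rb_c = rb - rb.mean()
    rs_c = rs - rs.mean(axis=0)
    denom = np.sqrt((rs_c**2).sum(axis=0) * (rb_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rs_c.T @ rb_c / denom, 0.0)
    df = n - 2 - k
    r_safe = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_safe * np.sqrt(df) / np.sqrt(1 - r_safe**2)
    p_raw = 2 * stats.t.sf(np.abs(t), df)
    p_adj = bh_adjust(p_raw)
    return [
        PartialCorrelationResult(
            region=strengths.region_labels[j],
            r=float(r[j]),
            df=df,
            p_raw=float(p_raw[j]),
            p_adjusted=float(p_adj[j]),
            n=n,
            k=k,
        )
        for j in range(n_regions)
    ]


@dataclass
class AncovaResult:
    region: str
    group_effect: float  # covariate-adjusted mean difference (group coded 0/1)
    t: float
    p_raw: float
    p_adjusted: float | None

    @property
    def f(self) -> float:
        """F statistic of the binary group factor (t squared)."""
        return self.t**2


def ancova_group_effect(
    strengths: NodalStrengthTable,
    group: Sequence[int],
    covariates: np.ndarray | None = None,
) -> list[AncovaResult]:
    """Per-region ANCOVA group contrast on nodal strength.

    Fits value ~ intercept + group + covariates by least squares for every
    region at once and reports the group coefficient's t and p, BH-adjusted
    across regions.  ``group`` is a 0/1 indicator.
    """
    group = np.asarray(group, dtype=float)
    n, n_regions = strengths.values.shape
    if len(group) != n:
        raise ValueError("group vector not conformable with strengths")
    base = _design(covariates, n)
    x = np.column_stack([base, group])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design with group indicator is rank deficient")
    p_params = x.shape[1]
    if n <= p_params:
        raise ValueError("too few subjects for the ANCOVA design")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ strengths.values  # params x regions
    resid = strengths.values - x @ beta
    dof = n - p_params
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[-1] / se, 0.0)
    p_raw = 2 * stats.t.sf(np.abs(t), dof)
    p_adj = bh_adjust(p_raw)
    return [
        AncovaResult(
            region=strengths.region_labels[j],
            group_effect=float(beta[-1, j]),
            t=float(t[j]),
            p_raw=float(p_raw[j]),
            p_adjusted=float(p_adj[j]),
        )
        for j in range(n_regions)
    ]


@dataclass
class FisherComparison:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int
    k: int


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int, k: int = 0
) -> FisherComparison:
    """Fisher r-to-z test for equality of two independent correlations.

    ``k`` covariates partialled out of each correlation shrink the
    effective sample sizes: the variance of atanh(r) is 1/(n - 3 - k).
    Set k = 0 for plain Pearson correlations.
    """
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 - 3 - k <= 0 or n2 - 3 - k <= 0:
        raise ValueError("insufficient sample size for the Fisher comparison")
    se = np.sqrt(1 / (n1 - 3 - k) + 1 / (n2 - 3 - k))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return FisherComparison(z=float(z), p=p, r1=r1, n1=n1, r2=r2, n2=n2, k=k)


@dataclass
class PredictorEstimate:
    name: str
    step: int  # 1-based step at which the predictor entered
    b: float  # unstandardized coefficient (final model)
    se: float
    beta: float  # standardized coefficient
    p: float
    vif: float
    tolerance: float


@dataclass
class RegressionStep:
    step: int
    r2: float
    delta_r2: float
    adjusted_r2: float


@dataclass
class HierarchicalRegressionResult:
    steps: list[RegressionStep]
    predictors: list[PredictorEstimate]
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.predictors])


def _ols(x: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, resid, r2


def hierarchical_regression(
    outcome: Sequence[float],
    step_blocks: Sequence[pd.DataFrame],
) -> HierarchicalRegressionResult:
    """Blockwise (hierarchical) least-squares regression.

    Predictor blocks are entered cumulatively; each step reports R-squared,
    its change over the previous step, and the adjusted R-squared.
    Coefficients (unstandardized B with SE and p, and standardized beta =
    B * sd(x)/sd(y)) come from the final model, as do the collinearity
    diagnostics: the VIF of each predictor is 1/(1 - R^2) of the auxiliary
    regression of that predictor on all other final-model predictors, and
    tolerance is its reciprocal.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    blocks = [pd.DataFrame(b) for b in step_blocks]
    if not blocks:
        raise ValueError("at least one predictor block is required")
    names: list[str] = []
    entry_step: list[int] = []
    for s, b in enumerate(blocks, start=1):
        if len(b) != n:
            raise ValueError("block length does not match outcome")
        names.extend(map(str, b.columns))
        entry_step.extend([s] * b.shape[1])
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names across blocks")

    full = pd.concat(blocks, axis=1).to_numpy(float)
    if n <= full.shape[1] + 1:
        raise ValueError("n must exceed the number of predictors + 1")

    steps: list[RegressionStep] = []
    prev_r2 = 0.0
    ncols = 0
    for s, b in enumerate(blocks, start=1):
        ncols += b.shape[1]
        x = np.column_stack([np.ones(n), full[:, :ncols]])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"design rank deficient at step {s}")
        _, _, r2 = _ols(x, y)
        adj = 1 - (1 - r2) * (n - 1) / (n - ncols - 1)
        steps.append(
            RegressionStep(step=s, r2=r2, delta_r2=r2 - prev_r2, adjusted_r2=adj)
        )
        prev_r2 = r2

    # Final-model coefficients.
    x = np.column_stack([np.ones(n), full])
    beta, resid, _ = _ols(x, y)
    dof = n - x.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sd_y = y.std(ddof=1)
    sd_x = full.std(axis=0, ddof=1)

    predictors: list[PredictorEstimate] = []
    for j, name in enumerate(names):
        others = np.delete(full, j, axis=1)
        if others.shape[1] == 0:
            aux_r2 = 0.0
        else:
            xo = np.column_stack([np.ones(n), others])
            _, _, aux_r2 = _ols(xo, full[:, j])
        tol = 1 - aux_r2
        if tol <= 0:
            raise ValueError(f"predictor {name!r} is perfectly collinear")
        predictors.append(
            PredictorEstimate(
                name=name,
                step=entry_step[j],
                b=float(beta[j + 1]),
                se=float(se[j + 1]),
                beta=float(beta[j + 1] * sd_x[j] / sd_y),
                p=float(pvals[j + 1]),
                vif=1 / tol,
                tolerance=tol,
            )
        )
    return HierarchicalRegressionResult(steps=steps, predictors=predictors, n=n)
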