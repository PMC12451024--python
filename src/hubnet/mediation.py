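"""Single-mediator mediation with bias-corrected bootstrap intervals.

Decomposes the association between a per-subject brain measure X (e.g. a
hub's FA-weighted nodal degree, or a grey-matter feature) and an outcome Y
(character reading) into an indirect path through a mediator M
(phonological awareness) and a direct path, with covariates in both
regressions:

    M = i1 + a*X + covariates
    Y = i2 + c'*X + b*M + covariates

The indirect effect is a*b and the total effect c = c' + a*b (an exact
least-squares identity when both models carry the same covariates).
Significance of a*b is assessed with a nonparametric bootstrap: subjects
are resampled with replacement, both models refit per draw, and the
bias-corrected percentile interval reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y given X
    c_total: float  # X -> Y total
    c_prime: float  # X -> Y direct
    indirect: float  # a * b
    ci_low: float
    ci_high: float
    direct_ci_low: float
    direct_ci_high: float
    n_boot: int
    level: float
    seed: int
    standardized: bool
    covariate_names: list[str] = field(default_factory=list)
    degenerate: bool = False  # bootstrap distribution collapsed / one-sided
    n: int = 0

    @property
    def indirect_significant(self) -> bool:
        return not (self.ci_low <= 0 <= self.ci_high)

    @property
    def direct_significant(self) -> bool:
        return not (self.direct_ci_low <= 0 <= self.direct_ci_high)

    @property
    def verdict(self) -> str:
        """Full / partial / no mediation from the two bootstrap intervals.

        "full" iff the indirect CI excludes 0 while the direct CI includes
        it; "partial" iff both exclude 0; otherwise "no mediation".
        """
        if self.indirect_significant and not self.direct_significant:
            return "full mediation"
        if self.indirect_significant and self.direct_significant:
            return "partial mediation"
        return "no mediation"


def _is_binary(v: np.ndarray) -> bool:
    return np.unique(v).size <= 2


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _fit_paths(xm: np.ndarray, xy: np.ndarray, m: np.ndarray, y: np.ndarray):
    """a, b, c' from the two least-squares fits (column 1 = X, last of xy = M)."""
    beta_m, *_ = np.linalg.lstsq(xm, m, rcond=None)
    beta_y, *_ = np.linalg.lstsq(xy, y, rcond=None)
    return beta_m[1], beta_y[-1], beta_y[1]


def mediate(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    standardized: bool = True,
    covariate_names: Sequence[str] | None = None,
) -> MediationResult:
    """Covariate-adjusted mediation of X on Y through M.

    If ``standardized``, X, M, Y and every continuous covariate are
    z-scored first (binary covariates stay 0/1), so paths are reported as
    standardized coefficients.  The bias-corrected bootstrap interval for
    a*b shifts the percentile bounds by the normal quantile of the fraction
    of bootstrap estimates below the point estimate (ties weighted 1/2);
    the direct-effect interval is the plain percentile interval from the
    same draws.  Resampling is by whole subject row.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not len(m) == len(y) == n:
        raise ValueError("x, m, y must share a length")
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariates not conformable")
    k = c.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if seed is None:
        raise ValueError("a bootstrap seed is required")

    if standardized:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
        c = np.column_stack(
            [ci if _is_binary(ci) else _zscore(ci) for ci in c.T]
        ) if k else c

    xm = np.column_stack([np.ones(n), x, c])
    xy = np.column_stack([np.ones(n), x, c, m])
    if np.linalg.matrix_rank(xy) < xy.shape[1]:
        raise ValueError("mediation design is rank deficient")
    a, b, c_prime = _fit_paths(xm, xy, m, y)
    beta_t, *_ = np.linalg.lstsq(xm, y, rcond=None)
    c_total = beta_t[1]
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bm = xm[idx]  # n_boot x n x (k+2)
    by = xy[idx]
    mm, yy = m[idx], y[idx]

    def _batched_solve(design: np.ndarray, target: np.ndarray) -> np.ndarray:
        gram = design.transpose(0, 2, 1) @ design
        rhs = np.einsum("bnp,bn->bp", design, target)
        try:
            return np.linalg.solve(gram, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return np.einsum("bpn,bn->bp", np.linalg.pinv(design), target)

    boot_a = _batched_solve(bm, mm)[:, 1]
    beta_y_boot = _batched_solve(by, yy)
    boot_b = beta_y_boot[:, -1]
    boot_cprime = beta_y_boot[:, 1]
    boot_ind = boot_a * boot_b

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    degenerate = False

    if np.allclose(boot_ind, boot_ind[0]):
        degenerate = True
        ci_low = ci_high = float(boot_ind[0])
    else:
        below = np.count_nonzero(boot_ind < indirect)
        ties = np.count_nonzero(boot_ind == indirect)
        frac = (below + 0.5 * ties) / n_boot
        clamp = stats.norm.ppf(1 - 1 / n_boot)
        if frac <= 0 or frac >= 1:
            degenerate = True
            z0 = clamp if frac >= 1 else -clamp
        else:
            z0 = float(np.clip(stats.norm.ppf(frac), -clamp, clamp))
        z_crit = stats.norm.ppf(hi_q)
        p_lo = stats.norm.cdf(2 * z0 - z_crit)
        p_hi = stats.norm.cdf(2 * z0 + z_crit)
        ci_low = float(np.quantile(boot_ind, p_lo))
        ci_high = float(np.quantile(boot_ind, p_hi))

    direct_ci = np.quantile(boot_cprime, [lo_q, hi_q])

    return MediationResult(
        a=float(a),
        b=float(b),
        c_total=float(c_total),
        c_prime=float(c_prime),
        indirect=float(indirect),
        ci_low=ci_low,
        ci_high=ci_high,
        direct_ci_low=float(direct_ci[0]),
        direct_ci_high=float(direct_ci[1]),
        n_boot=n_boot,
        level=level,
        seed=seed,
        standardized=standardized,
        covariate_names=list(covariate_names or []),
        degenerate=degenerate,
        n=n,
    )


def mediation_report(result: MediationResult, label: str = "X") -> str:
    """Readable path summary with CIs and the mediation verdict."""
    sig = lambda flag: "*" if flag else "ns"
    lines = [
        f"Mediation model: {label} -> mediator -> outcome "
        f"({'standardized' if result.standardized else 'unstandardized'}, "
        f"n={result.n})",
        f"  a  ({label} -> M)        = {result.a: .4f}",
        f"  b  (M -> Y | {label})    = {result.b: .4f}",
        f"  c  (total effect)       = {result.c_total: .4f}",
        f"  c' (direct effect)      = {result.c_prime: .4f}  "
        f"{100 * result.level:.0f}% CI [{result.direct_ci_low:.4f}, "
        f"{result.direct_ci_high:.4f}] {sig(result.direct_significant)}",
        f"  a*b (indirect effect)   = {result.indirect: .4f}  "
        f"{100 * result.level:.0f}% bias-corrected CI [{result.ci_low:.4f}, "
        f"{result.ci_high:.4f}] {sig(result.indirect_significant)}",
        f"  bootstrap: {result.n_boot} draws, seed {result.seed}"
        + ("  [degenerate bootstrap distribution]" if result.degenerate else ""),
        f"  verdict: {result.verdict}",
    ]
    if result.covariate_names:
        lines.insert(1, f"  covariates: {', '.join(result.covariate_names)}")
    return "\n".join(lines)
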