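"""Inferential layer: one-way ANOVA with Dunnett's many-to-one post-test
against a control group, and two-tailed Welch t-tests.

Dunnett's single-step adjusted p-values require the distribution of the
maximum absolute component of a multivariate t vector with the
product-correlation structure ``rho_ij = lambda_i * lambda_j``,
``lambda_i = sqrt(n_i / (n_i + n_0))`` (``rho = 1/2`` for balanced designs).
That tail probability is evaluated here by deterministic quadrature:
conditioning on the control-group deviate (Gauss-Hermite) and the pooled
scale estimate (generalized Gauss-Laguerre), the components are independent
and the rectangle probability is a product of normal CDF differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, roots_genlaguerre, roots_hermite


@dataclass
class DunnettResult:
    """Per-treatment-group Dunnett comparisons against the control."""

    t: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    significant: np.ndarray
    k: int  # number of treatment groups
    df: int
    alpha: float = 0.05
    degenerate: bool = False
    group_means: np.ndarray = field(default_factory=lambda: np.array([]))


def max_abs_t_cdf(q: float, lambdas: np.ndarray, df: int,
                  n_hermite: int = 64, n_laguerre: int = 64) -> float:
    """``P(max_i |T_i| <= q)`` for the Dunnett multivariate t.

    ``T_i = (lambda_i Z_0 + sqrt(1 - lambda_i^2) Z_i) / S`` with independent
    standard normal Z and ``S^2 ~ chi^2_df / df``. Deterministic quadrature;
    absolute accuracy well below 1e-5 at the default node counts.
    """
    if q <= 0:
        return 0.0
    lambdas = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lambdas ** 2)

    xh, wh = roots_hermite(n_hermite)          # weight exp(-x^2)
    z = np.sqrt(2.0) * xh                      # Z0 nodes
    alpha = df / 2.0 - 1.0
    xl, wl = roots_genlaguerre(n_laguerre, alpha)  # weight x^a exp(-x)
    s = np.sqrt(2.0 * xl / df)                 # S nodes, U ~ Gamma(df/2)

    # product over groups of P(|T_i| <= q | z, s), shape (n_lag, n_herm)
    zs = z[None, :, None]                      # (1, H, 1)
    ss = s[:, None, None]                      # (L, 1, 1)
    lam = lambdas[None, None, :]
    cc = c[None, None, :]
    upper = (q * ss - lam * zs) / cc
    lower = (-q * ss - lam * zs) / cc
    prod = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=2)  # (L, H)

    inner = prod @ wh / np.sqrt(np.pi)         # expectation over Z0
    val = float(wl @ inner * np.exp(-gammaln(df / 2.0)))
    return min(max(val, 0.0), 1.0)


def anova_dunnett(groups: list, control_index: int = 0, alpha: float = 0.05) -> DunnettResult:
    """One-way ANOVA pooled variance with Dunnett's many-to-one comparisons.

    Each treatment group is compared against ``groups[control_index]``;
    adjusted p-values are two-sided and control the family-wise error rate
    at ``alpha`` across the family.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs >= 2 observations")
    ns = np.array([g.size for g in arrays])
    means = np.array([g.mean() for g in arrays])
    df = int(ns.sum() - len(arrays))
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    mse = sse / df

    treat = [i for i in range(len(arrays)) if i != control_index]
    n0 = ns[control_index]
    m0 = means[control_index]
    k = len(treat)

    if mse == 0:
        return DunnettResult(
            t=np.full(k, np.nan), p_adjusted=np.ones(k), p_unadjusted=np.ones(k),
            significant=np.zeros(k, dtype=bool), k=k, df=df, alpha=alpha,
            degenerate=True, group_means=means,
        )

    ni = ns[treat]
    t = (means[treat] - m0) / np.sqrt(mse * (1.0 / ni + 1.0 / n0))
    lambdas = np.sqrt(ni / (ni + n0))
    p_adj = np.array([1.0 - max_abs_t_cdf(abs(ti), lambdas, df) for ti in t])
    p_un = 2.0 * sps.t.sf(np.abs(t), df)
    p_adj = np.maximum(p_adj, p_un)  # adjusted never below unadjusted
    return DunnettResult(
        t=t, p_adjusted=p_adj, p_unadjusted=p_un,
        significant=p_adj < alpha, k=k, df=df, alpha=alpha,
        group_means=means,
    )


def dunnett_critical_value(k: int, df: int, n_per_group: int | None = None,
                           n_control: int | None = None, alpha: float = 0.05) -> float:
    """Two-sided Dunnett critical value ``q`` with ``P(max|T| > q) = alpha``."""
    from scipy.optimize import brentq

    if n_per_group is None:
        lambdas = np.full(k, np.sqrt(0.5))
    else:
        n0 = n_control if n_control is not None else n_per_group
        lambdas = np.full(k, np.sqrt(n_per_group / (n_per_group + n0)))
    return float(brentq(lambda q: max_abs_t_cdf(q, lambdas, df) - (1.0 - alpha), 1e-3, 20.0))


def t_test_two_tailed(a, b) -> float:
    """Two-sided Welch t-test p-value.

    Degenerate (zero-variance) inputs return 1.0 when the means agree and
    0.0 otherwise rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
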