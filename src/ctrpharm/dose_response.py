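"""Response normalization and three-parameter logistic fitting.

The 3PL (Hill slope fixed at unity) is the workhorse for every pEC50/pIC50
and Emax estimate in the pipeline:

``R(C) = bottom + (top - bottom) / (1 + 10**(s * (logEC50 - log10 C)))``

with ``s = +1`` for ascending (agonist) curves and ``s = -1`` for descending
(competition/inhibition) curves.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import ConcentrationResponseCurve, LogisticFit


def normalize_response(raw, zero_ref, max_ref):
    """Normalize a raw readout to internal controls, in percent.

    ``100 * (raw - zero_ref) / (max_ref - zero_ref)`` — e.g. cAMP against
    100 uM forskolin, IP1 against 100 uM ATP, pERK against 10% FBS.
    """
    raw = np.asarray(raw, dtype=float)
    denom = float(max_ref) - float(zero_ref)
    if denom == 0:
        raise ValueError("max_ref equals zero_ref: zero normalization window")
    out = 100.0 * (raw - float(zero_ref)) / denom
    return float(out) if out.ndim == 0 else out


def logistic3(log_c: np.ndarray, bottom: float, top: float, log_ec50: float, sign: float = 1.0) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (sign * (log_ec50 - log_c)))


def fit_logistic3(
    curve: ConcentrationResponseCurve,
    direction: str = "ascending",
) -> LogisticFit:
    """Least-squares 3-parameter logistic fit of one curve.

    Multi-start over logEC50 seeded at the quartiles of the tested log-conc
    range, bottom/top initialized from the data extremes. Non-convergence is
    returned as a flagged fit, never raised.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    if curve.n_distinct_conc < 4:
        raise ValueError("need >= 4 distinct concentrations for a 3PL fit")
    sign = 1.0 if direction == "ascending" else -1.0

    log_c = np.log10(curve.conc)
    y = curve.response
    lo, hi = log_c.min(), log_c.max()

    def model(x, bottom, top, log_ec50):
        return logistic3(x, bottom, top, log_ec50, sign)

    y_min, y_max = float(y.min()), float(y.max())
    starts = [lo + f * (hi - lo) for f in (0.25, 0.5, 0.75)]
    best = None
    for s in starts:
        p0 = [y_min, y_max, s] if sign > 0 else [y_min, y_max, s]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, log_c, y, p0=p0, maxfev=20000)
            sse = float(np.sum((model(log_c, *popt) - y) ** 2))
        except (RuntimeError, ValueError):
            continue
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)

    n = y.size
    if best is None:
        return LogisticFit(
            bottom=np.nan, top=np.nan, log_ec50=np.nan, converged=False,
            not_determined=True, n_points=n, direction=direction,
        )
    popt, pcov, sse = best
    bottom, top, log_ec50 = popt
    dof = max(n - 3, 1)
    residual_sd = float(np.sqrt(sse / dof))
    # asymptotic SEs from the analytic Jacobian; curve_fit's finite-difference
    # covariance degenerates to inf on (near-)exact fits
    with np.errstate(invalid="ignore", over="ignore"):
        w = 1.0 / (1.0 + 10.0 ** (sign * (log_ec50 - log_c)))
        jac = np.column_stack([
            1.0 - w,
            w,
            -(top - bottom) * np.log(10.0) * sign * w * (1.0 - w),
        ])
        cov = residual_sd ** 2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.abs(np.diag(cov)))
    if top < bottom:  # canonical orientation
        bottom, top = top, bottom
        se[[0, 1]] = se[[1, 0]]
    fit = LogisticFit(
        bottom=float(bottom), top=float(top), log_ec50=float(log_ec50),
        se_bottom=float(se[0]), se_top=float(se[1]), se_log_ec50=float(se[2]),
        converged=True, n_points=n, residual_sd=residual_sd, sse=sse,
        direction=direction,
    )
    fit.not_determined = flag_not_determined(fit, curve)
    return fit


def flag_not_determined(fit: LogisticFit, curve: ConcentrationResponseCurve) -> bool:
    """Decide whether a logistic fit is reliable enough to report.

    A fit is not determined (N.D.) when any of the following holds:
    the optimizer did not converge; the fitted span is smaller than three
    residual SDs (no real signal above noise); the midpoint lies more than
    one log unit outside the tested concentration range; or the midpoint
    standard error exceeds one log unit.
    """
    if not fit.converged or not np.isfinite(fit.log_ec50):
        return True
    log_c = np.log10(curve.conc)
    lo, hi = log_c.min(), log_c.max()
    if np.isfinite(fit.residual_sd) and fit.span < 3.0 * fit.residual_sd:
        return True
    if fit.log_ec50 < lo - 1.0 or fit.log_ec50 > hi + 1.0:
        return True
    if not np.isfinite(fit.se_log_ec50) or fit.se_log_ec50 > 1.0:
        return True
    return False
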