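"""Two-sample Mendelian randomization estimators and diagnostics.

Given J harmonized instruments with exposure effects ``beta_exp_j``
(SE ``se_exp_j``) and outcome effects ``beta_out_j`` (SE ``se_out_j``),
the per-SNP Wald ratio is ``theta_j = beta_out_j / beta_exp_j`` and the
estimators implemented here are:

* **IVW** — inverse-variance-weighted mean of the Wald ratios with
  weights ``w_j = beta_exp_j^2 / se_out_j^2``, equivalent to weighted
  least squares of ``beta_out`` on ``beta_exp`` through the origin.
  Fixed-effects SE is ``(sum w_j)^{-1/2}``; the default multiplicative
  random-effects model inflates it by ``max(1, sqrt(Q/(J-1)))``.
* **MR-Egger** — the same weighted regression with a free intercept,
  after orienting every instrument exposure-positive.  The intercept
  estimates average directional pleiotropy; the slope is the causal
  effect under the InSIDE assumption.  Residual variance is floored at
  1 (no deflation below the fixed-effects SE).
* **MR-RAPS** — robust adjusted profile score.  With standardized
  residual ``t_j(b, tau2) = (beta_out_j - b*beta_exp_j) /
  sqrt(se_out_j^2 + b^2 se_exp_j^2 + tau2)``, the simple estimator
  solves ``sum rho'(t_j) dt_j/db = 0`` at ``tau2 = 0``; the
  overdispersed variant additionally profiles out a pleiotropy variance
  ``tau2 >= 0``.  ``rho`` is least squares or Huber (c = 1.345).

Diagnostics: Cochran's Q heterogeneity, instrument-strength F
statistics, per-SNP (single-SNP / forest / funnel) tables,
leave-one-out, and a closed-form binary-outcome power analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from crossmr.harmonize import HarmonizedInstrument

HUBER_C = 1.345
#: E[psi(Z) Z] for the Huber psi under a standard normal — the
#: consistency constant in the overdispersion estimating equation.
HUBER_DELTA = 2 * stats.norm.cdf(HUBER_C) - 1


class MRError(ValueError):
    pass


@dataclass
class MRResult:
    """One estimator's output.

    ``estimate`` is the causal effect of one exposure-SD on the outcome
    (log-odds for binary outcomes).  Egger additionally carries the
    intercept (average directional pleiotropy) and its test;
    heterogeneity fields hold Cochran's Q against the method's own fit.
    """

    method: str
    estimate: float
    se: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    tau2: float | None = None
    converged: bool = True
    notes: list[str] = field(default_factory=list)


@dataclass
class PowerSpec:
    """Inputs for binary-outcome MR power: outcome-study size and case
    fraction, instrument r² on the exposure, alpha, and the OR per
    exposure SD to detect."""

    n_total: int
    case_fraction: float
    r2_exposure: float
    or_detect: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")
        if not (0 < self.r2_exposure < 1):
            raise ValueError("r2_exposure must be in (0,1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (self.or_detect > 0):
            raise ValueError("or_detect must be > 0")


def _as_arrays(insts) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame, a sequence of HarmonizedInstrument, or a
    4-tuple of arrays; return (beta_exp, se_exp, beta_out, se_out)."""
    if isinstance(insts, pd.DataFrame):
        return (insts["beta_exp"].to_numpy(float),
                insts["se_exp"].to_numpy(float),
                insts["beta_out"].to_numpy(float),
                insts["se_out"].to_numpy(float))
    if isinstance(insts, tuple) and len(insts) == 4:
        return tuple(np.asarray(a, float) for a in insts)  # type: ignore
    seq = list(insts)
    if seq and isinstance(seq[0], HarmonizedInstrument):
        return (np.array([i.beta_exp for i in seq]),
                np.array([i.se_exp for i in seq]),
                np.array([i.beta_out for i in seq]),
                np.array([i.se_out for i in seq]))
    raise TypeError("cannot interpret instruments input")


def _snp_ids(insts, n: int) -> list[str]:
    if isinstance(insts, pd.DataFrame) and "snp_id" in insts.columns:
        return list(insts["snp_id"])
    try:
        seq = list(insts)
        if seq and isinstance(seq[0], HarmonizedInstrument):
            return [i.snp_id for i in seq]
    except TypeError:
        pass
    return [f"snp_{j + 1}" for j in range(n)]


def wald_ratio(inst: HarmonizedInstrument | tuple,
               second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with delta-method SE.

    First-order SE (default) is ``se_out/|beta_exp|``; the second-order
    variant adds the exposure-uncertainty term
    ``beta_out^2 se_exp^2 / beta_exp^4`` under the square root.
    """
    if isinstance(inst, HarmonizedInstrument):
        bx, sx, by, sy = inst.beta_exp, inst.se_exp, inst.beta_out, inst.se_out
    else:
        bx, sx, by, sy = inst
    if bx == 0:
        raise MRError("null instrument: beta_exp = 0")
    est = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return est, se


def cochran_q(insts, estimate: float) -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (theta_j - estimate)^2 with IVW weights;
    df = J - 1; P from the chi-square upper tail."""
    bx, _, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 2:
        raise MRError("Cochran's Q requires >= 2 instruments")
    theta = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (theta - estimate) ** 2))
    df = n - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(insts, model: Literal["fixed", "mre"] = "mre") -> MRResult:
    """Inverse-variance-weighted estimate of the causal effect.

    ``model='fixed'`` uses the fixed-effects SE ``(sum w)^{-1/2}``;
    ``'mre'`` (default) multiplies it by ``max(1, sqrt(Q/(J-1)))``, the
    multiplicative random-effects inflation.  A single instrument falls
    back to fixed effects with a note.
    """
    bx, _, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 1:
        raise MRError("IVW requires >= 1 instrument")
    if np.any(bx == 0):
        raise MRError("null instrument: beta_exp = 0")
    w = bx**2 / sy**2
    theta = by / bx
    sw = float(np.sum(w))
    est = float(np.sum(w * theta) / sw)
    se_fixed = sw ** -0.5
    notes = []
    q = q_df = q_p = None
    if n >= 2:
        q, q_df, q_p = cochran_q((bx, np.zeros(n), by, sy), est)
    if model == "mre":
        if n < 2:
            notes.append("single instrument: fell back to fixed effects")
            se = se_fixed
        else:
            se = se_fixed * max(1.0, math.sqrt(q / (n - 1)))
    else:
        se = se_fixed
    p = 2 * stats.norm.sf(abs(est) / se)
    return MRResult(method="ivw", estimate=est, se=se, pvalue=float(p),
                    n_snps=n, q_stat=q, q_df=q_df, q_p=q_p, notes=notes)


def egger(insts) -> MRResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with a free
    intercept, after orienting all instruments exposure-positive.

    The slope is the causal estimate (consistent under InSIDE even with
    directional pleiotropy); the intercept estimates the average
    pleiotropic effect, and ``intercept_p`` is the pleiotropy test.
    SEs use the weighted-regression covariance with residual variance
    floored at 1 (multiplicative random effects).
    """
    bx, sx, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 3:
        raise MRError("Egger requires >= 3 instruments")
    # exposure-positive orientation: negate both betas where beta_exp < 0
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    # weighted normal equations for y = a + b x
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx**2
    if det <= 0:
        raise MRError("degenerate design (no exposure-effect spread)")
    a = (swx2 * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = y - a - b * x
    sigma2 = max(1.0, float((w * resid**2).sum()) / (n - 2))
    var_a = sigma2 * swx2 / det
    var_b = sigma2 * sw / det
    se_a, se_b = math.sqrt(var_a), math.sqrt(var_b)
    # t reference with n-2 df, matching standard MR-Egger practice
    p_b = 2 * stats.t.sf(abs(b) / se_b, n - 2)
    p_a = 2 * stats.t.sf(abs(a) / se_a, n - 2)
    q = float((w * resid**2).sum())
    q_df = n - 2
    return MRResult(method="egger", estimate=float(b), se=se_b,
                    pvalue=float(p_b), n_snps=n,
                    intercept=float(a), intercept_se=se_a,
                    intercept_p=float(p_a),
                    q_stat=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)))


def _raps_t(b: float, tau2: float, bx, sx, by, sy):
    s2 = sy**2 + b**2 * sx**2 + tau2
    s = np.sqrt(s2)
    r = by - b * bx
    t = r / s
    # dt/db = -(bx/s) - r * b * sx^2 / s^3
    dtdb = -(bx / s) - r * b * sx**2 / s**3
    return t, dtdb


def _rho_prime(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return t
    return np.clip(t, -HUBER_C, HUBER_C)


def _raps_score(b: float, tau2: float, bx, sx, by, sy, loss: str) -> float:
    t, dtdb = _raps_t(b, tau2, bx, sx, by, sy)
    return float(np.sum(_rho_prime(t, loss) * dtdb))


def _raps_tau2_eq(tau2: float, b: float, bx, sx, by, sy, loss: str) -> float:
    t, _ = _raps_t(b, tau2, bx, sx, by, sy)
    if loss == "l2":
        return float(np.sum(t**2 - 1))
    return float(np.sum(_rho_prime(t, loss) * t - HUBER_DELTA))


def _solve_score(fun, lo: float = -10.0, hi: float = 10.0,
                 n_grid: int = 81) -> tuple[float, bool]:
    """Find a root of a scalar score on [lo, hi]: scan a grid for a sign
    change, then Brent.  Returns (root, converged)."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([fun(g) for g in grid])
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(grid[i]), True
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            root = optimize.brentq(fun, grid[i], grid[i + 1], xtol=1e-12)
            return float(root), True
    # no sign change: return the grid minimizer of |score|, unconverged
    j = int(np.argmin(np.abs(vals)))
    return float(grid[j]), False


def raps(insts, overdispersed: bool = False,
         loss: Literal["l2", "huber"] = "l2",
         max_iter: int = 100, tol: float = 1e-8) -> MRResult:
    """MR-RAPS: profile-score estimation accounting for exposure-effect
    measurement error, optional overdispersion, and robust loss.

    The simple estimator solves the profile score in ``b`` at
    ``tau2 = 0``.  The overdispersed estimator alternates the score in
    ``b`` with the moment equation for ``tau2`` (floored at 0) until the
    pair stabilizes.  The SE is the empirical sandwich
    ``sqrt(sum psi_j^2) / |d score/db|``.  Non-convergence is reported
    via ``converged=False``, never an exception.
    """
    bx, sx, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 3:
        raise MRError("RAPS requires >= 3 instruments")

    tau2 = 0.0
    converged = True
    if not overdispersed:
        b, converged = _solve_score(
            lambda b_: _raps_score(b_, 0.0, bx, sx, by, sy, loss))
    else:
        b, ok = _solve_score(
            lambda b_: _raps_score(b_, 0.0, bx, sx, by, sy, loss))
        converged = ok
        for _ in range(max_iter):
            # update tau2 given b
            f0 = _raps_tau2_eq(0.0, b, bx, sx, by, sy, loss)
            if f0 <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.max(sy**2 + b**2 * sx**2)) + 1.0
                while _raps_tau2_eq(hi, b, bx, sx, by, sy, loss) > 0:
                    hi *= 4.0
                    if hi > 1e8:
                        converged = False
                        break
                tau2_new = optimize.brentq(
                    _raps_tau2_eq, 0.0, hi, args=(b, bx, sx, by, sy, loss),
                    xtol=1e-12)
            b_new, ok = _solve_score(
                lambda b_: _raps_score(b_, tau2_new, bx, sx, by, sy, loss))
            converged = converged and ok
            if abs(b_new - b) < tol and abs(tau2_new - tau2) < tol:
                b, tau2 = b_new, tau2_new
                break
            b, tau2 = b_new, tau2_new
        else:
            converged = False

    # sandwich SE: Var(b) = sum(psi_j^2) / (d score/db)^2
    t, dtdb = _raps_t(b, tau2, bx, sx, by, sy)
    psi = _rho_prime(t, loss) * dtdb
    h = 1e-6 * max(1.0, abs(b))
    dscore = (_raps_score(b + h, tau2, bx, sx, by, sy, loss)
              - _raps_score(b - h, tau2, bx, sx, by, sy, loss)) / (2 * h)
    if dscore == 0:
        se = float("nan")
        converged = False
    else:
        se = math.sqrt(float(np.sum(psi**2))) / abs(dscore)
    p = 2 * stats.norm.sf(abs(b) / se) if se and not math.isnan(se) else float("nan")
    method = "raps-overdispersed" if overdispersed else "raps"
    return MRResult(method=method, estimate=float(b), se=float(se),
                    pvalue=float(p), n_snps=n,
                    tau2=float(tau2) if overdispersed else None,
                    converged=converged)


def f_statistic(insts=None, mode: Literal["mean-per-snp", "overall-r2"] = "mean-per-snp",
                n_exposure: int | None = None, r2: float | None = None,
                n_snps: int | None = None) -> float:
    """Instrument-strength F statistic.

    ``mean-per-snp``: mean over instruments of ``(beta_exp/se_exp)^2``.
    ``overall-r2``: ``(n - k - 1)/k * r2/(1 - r2)`` with ``k`` the
    instrument count — requires ``n_exposure`` and ``r2``.
    Values well above 10 indicate weak-instrument bias is negligible.
    """
    if mode == "mean-per-snp":
        if insts is None:
            raise ValueError("mean-per-snp mode needs instruments")
        bx, sx, _, _ = _as_arrays(insts)
        return float(np.mean((bx / sx) ** 2))
    if mode == "overall-r2":
        if n_exposure is None or r2 is None:
            raise ValueError("overall-r2 mode needs n_exposure and r2")
        if n_snps is None:
            if insts is None:
                raise ValueError("overall-r2 mode needs n_snps or instruments")
            n_snps = len(_as_arrays(insts)[0])
        k = n_snps
        return float((n_exposure - k - 1) / k * r2 / (1 - r2))
    raise ValueError(f"unknown mode {mode!r}")


def single_snp_table(insts, alpha: float = 0.05,
                     second_order: bool = False) -> pd.DataFrame:
    """Per-SNP Wald estimates with significance flags and funnel-plot
    coordinates (x = estimate, y = 1/SE)."""
    bx, sx, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 1:
        raise MRError("need >= 1 instrument")
    ids = _snp_ids(insts, n)
    rows = []
    for j in range(n):
        est, se = wald_ratio((bx[j], sx[j], by[j], sy[j]),
                             second_order=second_order)
        p = 2 * stats.norm.sf(abs(est) / se)
        rows.append({"snp_id": ids[j], "estimate": est, "se": se,
                     "pvalue": p, "significant": p < alpha,
                     "funnel_x": est, "funnel_y": 1.0 / se})
    return pd.DataFrame(rows)


def leave_one_out(insts, model: Literal["fixed", "mre"] = "mre") -> pd.DataFrame:
    """IVW recomputed with each instrument omitted in turn.

    ``sign_flip`` marks rows whose estimate changes sign relative to the
    all-instrument estimate — candidate influential SNPs.
    """
    bx, sx, by, sy = _as_arrays(insts)
    n = len(bx)
    if n < 2:
        raise MRError("leave-one-out requires >= 2 instruments")
    ids = _snp_ids(insts, n)
    full = ivw((bx, sx, by, sy), model=model)
    rows = []
    for j in range(n):
        keep = np.arange(n) != j
        res = ivw((bx[keep], sx[keep], by[keep], sy[keep]), model=model)
        rows.append({"omitted_snp": ids[j], "estimate": res.estimate,
                     "se": res.se, "pvalue": res.pvalue,
                     "sign_flip": np.sign(res.estimate) != np.sign(full.estimate)})
    return pd.DataFrame(rows)


def plot_data(insts, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: scatter (beta_exp vs beta_out with SEs),
    forest (per-SNP Wald CIs plus pooled rows) and funnel."""
    bx, sx, by, sy = _as_arrays(insts)
    ids = _snp_ids(insts, len(bx))
    single = single_snp_table(insts, alpha=alpha)
    z = stats.norm.ppf(1 - alpha / 2)
    forest = single[["snp_id", "estimate", "se"]].copy()
    forest["ci_low"] = forest["estimate"] - z * forest["se"]
    forest["ci_high"] = forest["estimate"] + z * forest["se"]
    for res in (ivw(insts), egger(insts) if len(bx) >= 3 else None):
        if res is None:
            continue
        forest.loc[len(forest)] = {
            "snp_id": f"All ({res.method})", "estimate": res.estimate,
            "se": res.se, "ci_low": res.estimate - z * res.se,
            "ci_high": res.estimate + z * res.se}
    scatter = pd.DataFrame({"snp_id": ids, "beta_exp": bx, "se_exp": sx,
                            "beta_out": by, "se_out": sy})
    funnel = single[["snp_id", "funnel_x", "funnel_y"]].copy()
    return {"scatter": scatter, "forest": forest, "funnel": funnel}


def power_binary(spec: PowerSpec) -> float:
    """Closed-form power of two-sample MR with a binary outcome.

    With ``b = ln(OR)``, ``v = case_fraction (1 - case_fraction)`` and
    noncentrality ``z = |b| sqrt(n r2 v)``, the two-sided power at level
    alpha is ``Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2})``.
    At OR = 1 this reduces to alpha (the test's size).
    """
    spec.validate()
    b = math.log(spec.or_detect)
    v = spec.case_fraction * (1 - spec.case_fraction)
    z = abs(b) * math.sqrt(spec.n_total * spec.r2_exposure * v)
    za = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(z - za) + stats.norm.cdf(-z - za))


def mr_report(insts, raps_overdispersed: bool = True) -> pd.DataFrame:
    """Run the full estimator battery and return one row per method."""
    results = [ivw(insts), egger(insts), raps(insts)]
    if raps_overdispersed:
        results.append(raps(insts, overdispersed=True))
    rows = []
    for r in results:
        rows.append({
            "method": r.method, "estimate": r.estimate, "se": r.se,
            "pvalue": r.pvalue, "n_snps": r.n_snps,
            "intercept": r.intercept, "intercept_se": r.intercept_se,
            "intercept_p": r.intercept_p, "q_stat": r.q_stat,
            "q_df": r.q_df, "q_p": r.q_p, "tau2": r.tau2,
            "converged": r.converged,
        })
    return pd.DataFrame(rows)
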