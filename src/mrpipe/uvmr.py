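"""Univariable two-sample MR estimators and sensitivity analyses.

All estimators consume a single-exposure :class:`~mrpipe.harmonize.HarmonizedSet`
and return an :class:`MREstimate`.  The primary method is inverse-variance
weighted (IVW) regression — a zero-intercept weighted regression of the
SNP-outcome coefficients on the SNP-exposure coefficients.  Sensitivity
analyses relax the IVW assumptions in different directions:

* MR-Egger frees the intercept; the intercept is a test of directional
  pleiotropy and the slope a pleiotropy-adjusted effect.
* SIMEX-adjusted Egger corrects the Egger slope for regression dilution
  from noise in the exposure betas by simulation-extrapolation.
* The weighted median is consistent when at least half the weight comes
  from valid instruments; the weighted mode when the largest cluster of
  instruments is valid.
* MR-RAPS solves a profile-score estimating equation that is robust to
  weak instruments, optionally with a Huber influence function and a
  multiplicative overdispersion parameter for systematic pleiotropy.
* Steiger filtering removes variants that explain more variance in the
  outcome than in the exposure (likely reversed causal orientation).

Two-sided p-values come from the normal distribution for all estimators
except the Egger family, which uses t with n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from mrpipe.errors import ConfigurationError, DataError, NumericalError
from mrpipe.harmonize import HarmonizedSet

Z95 = stats.norm.ppf(0.975)  # 1.959964
HUBER_K = 1.345


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q (or the exposure-uncertainty-weighted Q_a) with df and p."""

    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class MREstimate:
    """A causal effect estimate with uncertainty and diagnostics.

    ``beta`` is in outcome units per unit of exposure; ``intercept`` is the
    (value, se, pvalue) triple of the Egger intercept when applicable.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: Optional[tuple[float, float, float]] = None
    het: Optional[HeterogeneityStats] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise NumericalError(f"{self.method}: CI does not bracket the estimate")
        if self.n_snps < 1:
            raise DataError(f"{self.method}: no instruments")

    def to_row(self) -> dict:
        row = {
            "method": self.method, "n_snps": self.n_snps, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "intercept": np.nan, "intercept_se": np.nan, "intercept_pvalue": np.nan,
            "Q": np.nan, "Q_df": np.nan, "Q_pvalue": np.nan,
        }
        if self.intercept is not None:
            row["intercept"], row["intercept_se"], row["intercept_pvalue"] = self.intercept
        if self.het is not None:
            row["Q"], row["Q_df"], row["Q_pvalue"] = self.het.Q, self.het.df, self.het.pvalue
        return row


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP approximate F statistics, F_j = (beta_x / se_x)^2."""

    per_snp_f: dict[str, float]
    min_f: float
    mean_f: float
    max_f: float


def _require_univariable(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if h.n_exposures != 1:
        raise ConfigurationError("univariable estimator called on a multi-exposure set")
    if h.n_snps == 0:
        raise DataError("harmonized set has no instruments")
    return h.bx[:, 0], h.sx[:, 0], h.by, h.sy


def _normal_estimate(method: str, beta: float, se: float, n: int,
                     intercept=None, het=None) -> MREstimate:
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    half = Z95 * se
    return MREstimate(method, float(beta), float(se), float(beta - half),
                      float(beta + half), float(p), n, intercept, het)


def ivw(h: HarmonizedSet, variance_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(w bx by) / sum(w bx^2) with w = 1/sy^2 — equivalently a
    zero-intercept weighted regression of by on bx.  The fixed-effect SE is
    sqrt(1 / sum(w bx^2)); under the multiplicative random-effects model
    (the default) it is inflated by sqrt(max(1, Q / (n - 1))), so
    under-dispersion never shrinks the SE.  With one SNP the estimate
    reduces to the Wald ratio by/bx.
    """
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown variance model {variance_model!r}")
    bx, _sx, by, sy = _require_univariable(h)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0.0:
        raise DataError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - beta * bx) ** 2))
    n = len(bx)
    df = n - 1
    se = np.sqrt(1.0 / denom)
    if variance_model == "multiplicative_random" and df > 0:
        se *= np.sqrt(max(1.0, q / df))
    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)) if df > 0 else float("nan"))
    return _normal_estimate("IVW", beta, se, n, het=het)


def _orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip rows so that all exposure betas are non-negative (Egger identifiability)."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def _egger_fit(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Closed-form weighted regression with intercept.

    Returns slope, intercept, their SEs (with multiplicative inflation
    bounded below by 1), and Q with df = n - 2.  ``by`` may be a 2-D array
    of shape (reps, n) for vectorized refits on fixed bx (SIMEX path uses
    the transpose convention with bx varying instead).
    """
    sw = np.sum(w)
    swx = np.sum(w * bx, axis=-1)
    swy = np.sum(w * by, axis=-1)
    swxx = np.sum(w * bx**2, axis=-1)
    swxy = np.sum(w * bx * by, axis=-1)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return slope, intercept, sw, swx, swxx, det


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted least squares of by on bx with free intercept.

    Rows are re-oriented so all exposure betas are non-negative before the
    fit.  The slope is the pleiotropy-adjusted causal estimate; the
    intercept, with its SE and t-based p-value, is the directional-pleiotropy
    test.  Requires at least 3 instruments.
    """
    bx, _sx, by, sy = _require_univariable(h)
    n = len(bx)
    if n < 3:
        raise DataError(f"MR-Egger requires >= 3 instruments, got {n}")
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    slope, intercept, sw, swx, swxx, det = _egger_fit(bx, by, w)
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    df = n - 2
    inflation = max(1.0, q / df)
    se_slope = float(np.sqrt(sw / det * inflation))
    se_int = float(np.sqrt(swxx / det * inflation))
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    half = stats.t.ppf(0.975, df) * se_slope
    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)))
    return MREstimate("Egger", float(slope), se_slope, float(slope - half),
                      float(slope + half), float(p_slope), n,
                      intercept=(float(intercept), se_int, float(p_int)), het=het)


def egger_simex(h: HarmonizedSet, lambdas=(0.0, 0.5, 1.0, 1.5, 2.0),
                reps: int = 200, seed: int = 0) -> MREstimate:
    """Simulation-extrapolation correction of the Egger slope for regression dilution.

    For each lambda in the grid, noise with variance lambda * sx_j^2 is added
    to the exposure betas over ``reps`` replicates and the mean Egger slope
    recorded; a quadratic in lambda is then extrapolated to lambda = -1,
    the zero-measurement-error limit.  The SE comes from a delete-one
    jackknife over replicates.  Row orientation is fixed from the observed
    exposure betas before noise is added.
    """
    lambdas = np.asarray(sorted(set(float(l) for l in lambdas)))
    if len(lambdas) < 3:
        raise ConfigurationError("SIMEX needs a grid of at least 3 lambda values")
    if (lambdas < 0).any():
        raise ConfigurationError("SIMEX lambdas must be non-negative")
    if reps < 100:
        raise ConfigurationError("SIMEX needs reps >= 100")
    bx, sx, by, sy = _require_univariable(h)
    n = len(bx)
    if n < 3:
        raise DataError(f"SIMEX-Egger requires >= 3 instruments, got {n}")
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    # slopes[r, i]: Egger slope of replicate r at lambdas[i]
    slopes = np.empty((reps, len(lambdas)))
    intercepts = np.empty((reps, len(lambdas)))
    for i, lam in enumerate(lambdas):
        if lam == 0.0:
            s0, i0, *_ = _egger_fit(bx, by, w)
            slopes[:, i] = s0
            intercepts[:, i] = i0
        else:
            noisy = bx + np.sqrt(lam) * sx * rng.standard_normal((reps, n))
            s, ic, *_ = _egger_fit(noisy, by, w)
            slopes[:, i] = s
            intercepts[:, i] = ic

    design = np.vander(lambdas, 3, increasing=True)  # 1, lambda, lambda^2

    def extrapolate(values_by_lambda: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, values_by_lambda, rcond=None)
        return float(coef[0] - coef[1] + coef[2])

    est = extrapolate(slopes.mean(axis=0))
    est_int = extrapolate(intercepts.mean(axis=0))

    # delete-one jackknife over replicates
    tot = slopes.sum(axis=0)
    tot_int = intercepts.sum(axis=0)
    jack = np.array([extrapolate((tot - slopes[r]) / (reps - 1)) for r in range(reps)])
    jack_int = np.array([extrapolate((tot_int - intercepts[r]) / (reps - 1)) for r in range(reps)])
    se = float(np.sqrt((reps - 1) / reps * np.sum((jack - jack.mean()) ** 2)))
    se_int = float(np.sqrt((reps - 1) / reps * np.sum((jack_int - jack_int.mean()) ** 2)))
    # with noiseless exposure betas the extrapolation is exact and the jackknife
    # collapses; fall back on the plain Egger SE so the CI stays meaningful
    plain = egger(h)
    if se == 0.0:
        se = plain.se
    if se_int == 0.0:
        se_int = plain.intercept[1]
    df = n - 2
    p = 2.0 * stats.t.sf(abs(est) / se, df) if se > 0 else (0.0 if est else 1.0)
    p_int = 2.0 * stats.t.sf(abs(est_int) / se_int, df) if se_int > 0 else 1.0
    half = stats.t.ppf(0.975, df) * se
    return MREstimate("EggerSIMEX", est, se, est - half, est + half, float(p), n,
                      intercept=(est_int, se_int, float(p_int)), het=plain.het)


def _ratio_weights(bx, sx, by, sy, variant_ids=None):
    zero = bx == 0
    if zero.any():
        which = variant_ids[int(np.argmax(zero))] if variant_ids is not None else "a variant"
        raise DataError(f"exposure beta is exactly zero for {which}; ratio undefined")
    ratios = by / bx
    w = bx**2 / sy**2
    return ratios, w / w.sum()


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[j]) / (cum[j + 1] - cum[j])
    return float(r[j] + frac * (r[j + 1] - r[j]))


def weighted_median(h: HarmonizedSet, boot_reps: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Ratios r_j = by_j / bx_j are weighted by bx_j^2 / sy_j^2 (the inverse
    first-order variance of the ratio); the estimate is the value at
    cumulative standardized weight 0.5, linearly interpolated between the
    bracketing order statistics.  The SE comes from a parametric bootstrap
    resampling (bx_j, by_j) from their observed normal distributions.
    Consistent when valid instruments carry at least half the weight.
    """
    bx, sx, by, sy = _require_univariable(h)
    if len(bx) < 3:
        raise DataError("weighted median requires >= 3 instruments")
    ratios, w = _ratio_weights(bx, sx, by, sy, h.variant_ids)
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for b in range(boot_reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        wb = bxs**2 / sy**2
        boots[b] = _weighted_median(bys / bxs, wb / wb.sum())
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("WeightedMedian", est, se, len(bx))


def _silverman_bandwidth(ratios: np.ndarray, factor: float) -> float:
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad) * n ** (-1 / 5)
    if s == 0:
        s = 0.9 * max(sd, mad, 1e-12) * n ** (-1 / 5)
    return factor * s


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    lo = ratios.min() - 3 * bandwidth
    hi = ratios.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, 512)
    dens = weights @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bandwidth) ** 2)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  boot_reps: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the weighted kernel-smoothed density of per-SNP Wald ratios.

    A normal kernel with bandwidth = ``bandwidth_factor`` times the
    modified Silverman rule (0.9 min(sd, normalized MAD) n^{-1/5}) on the
    ratio distribution; weights as in the weighted median.  Consistent when
    the largest cluster of instruments is valid, even if they carry less
    than half the weight.  SE by parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ConfigurationError("bandwidth_factor must be positive")
    bx, sx, by, sy = _require_univariable(h)
    if len(bx) < 3:
        raise DataError("weighted mode requires >= 3 instruments")
    ratios, w = _ratio_weights(bx, sx, by, sy, h.variant_ids)
    bw = _silverman_bandwidth(ratios, bandwidth_factor)
    est = _mode_estimate(ratios, w, bw)
    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for b in range(boot_reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        rb = bys / bxs
        wb = bxs**2 / sy**2
        wb = wb / wb.sum()
        boots[b] = _mode_estimate(rb, wb, _silverman_bandwidth(rb, bandwidth_factor))
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("WeightedMode", est, se, len(bx))


def _huber_delta() -> float:
    """E[psi_k(Z) Z] for standard normal Z and the Huber influence, k = 1.345."""
    k = HUBER_K
    val, _ = integrate.quad(lambda z: min(max(z, -k), k) * z * stats.norm.pdf(z), -8, 8)
    return val


_HUBER_DELTA = None


def mr_raps(h: HarmonizedSet, loss: str = "huber", overdispersion: bool = True,
            max_iter: int = 200) -> MREstimate:
    """MR-RAPS: robust adjusted profile-score estimation.

    Solves sum_j psi(t_j(theta)) * (-dt_j/dtheta) = 0 where
    t_j = (by_j - theta bx_j) / sqrt(sy_j^2 + theta^2 sx_j^2 + tau2); the
    denominator propagates exposure-beta uncertainty, which is what makes
    the estimator robust to weak instruments.  psi is the identity for the
    l2 loss and the Huber influence (tuning constant 1.345) for the huber
    loss.  With ``overdispersion`` a multiplicative pleiotropy variance
    tau2 is profiled jointly via sum_j (psi(t_j) t_j - delta)/s_j^2 = 0.
    SE by the sandwich formula.
    """
    global _HUBER_DELTA
    if loss not in ("l2", "huber"):
        raise ConfigurationError(f"unknown loss {loss!r}")
    bx, sx, by, sy = _require_univariable(h)
    n = len(bx)
    if n < 3:
        raise DataError("MR-RAPS requires >= 3 instruments")

    if loss == "huber":
        if _HUBER_DELTA is None:
            _HUBER_DELTA = _huber_delta()
        delta = _HUBER_DELTA
        psi = lambda t: np.clip(t, -HUBER_K, HUBER_K)
        rho = lambda t: np.where(np.abs(t) <= HUBER_K, 0.5 * t**2,
                                 HUBER_K * np.abs(t) - 0.5 * HUBER_K**2)
    else:
        delta = 1.0
        psi = lambda t: t
        rho = lambda t: 0.5 * t**2

    def pieces(theta: float, tau2: float):
        s2 = sy**2 + theta**2 * sx**2 + tau2
        s = np.sqrt(s2)
        t = (by - theta * bx) / s
        # -dt/dtheta = bx/s + t * theta * sx^2 / s^2
        mu = bx / s + t * theta * sx**2 / s2
        return s2, t, mu

    def score_theta(theta: float, tau2: float) -> float:
        _s2, t, mu = pieces(theta, tau2)
        return float(np.sum(psi(t) * mu))

    def score_tau(tau2: float, theta: float) -> float:
        s2, t, _mu = pieces(theta, tau2)
        return float(np.sum((psi(t) * t - delta) / s2))

    def loss_at(theta: float, tau2: float) -> float:
        _s2, t, _mu = pieces(theta, tau2)
        return float(np.sum(rho(t)))

    def solve_theta(tau2: float, start: float) -> float:
        # the profiled-likelihood loss sum rho(t_j) has gradient equal to the
        # negated score; minimizing it locally avoids the spurious roots the
        # score equation develops in its flat tails
        half = 1.0
        for _ in range(30):
            res = optimize.minimize_scalar(
                loss_at, bounds=(start - half, start + half), args=(tau2,),
                method="bounded", options={"xatol": 1e-12})
            x = float(res.x)
            if min(x - (start - half), (start + half) - x) > 1e-6 * half:
                return x
            half *= 3.0
        raise NumericalError("MR-RAPS: profile-loss minimum not bracketed")

    start = ivw(h, variance_model="fixed").beta
    theta, tau2 = start, 0.0
    if overdispersion:
        for it in range(max_iter):
            theta_new = solve_theta(tau2, theta)
            f0 = score_tau(0.0, theta_new)
            if f0 <= 0:
                tau2_new = 0.0
            else:
                hi = max(np.max(sy**2), 1e-8)
                while score_tau(hi, theta_new) > 0 and hi < 1e6:
                    hi *= 4
                tau2_new = float(optimize.brentq(score_tau, 0.0, hi,
                                                 args=(theta_new,), xtol=1e-14))
            converged = (abs(theta_new - theta) < 1e-8 * max(1.0, abs(theta_new))
                         and abs(tau2_new - tau2) < 1e-10 * max(1.0, tau2_new))
            theta, tau2 = theta_new, tau2_new
            if converged:
                break
        else:
            raise NumericalError(
                f"MR-RAPS did not converge in {max_iter} iterations "
                f"(theta={theta:.4g}, tau2={tau2:.4g})")
    else:
        theta = solve_theta(0.0, theta)

    # sandwich variance: A^-1 B A^-1 with numerical A
    eps = 1e-6 * max(1.0, abs(theta))
    a = (score_theta(theta + eps, tau2) - score_theta(theta - eps, tau2)) / (2 * eps)
    _s2, t, mu = pieces(theta, tau2)
    b = float(np.sum((psi(t) * mu) ** 2))
    if a == 0:
        raise NumericalError("MR-RAPS: degenerate score derivative")
    se = float(np.sqrt(b) / abs(a))
    return _normal_estimate("RAPS", theta, se, n)


def per_snp_f(h: HarmonizedSet) -> InstrumentStrength:
    """Approximate per-SNP instrument strength, F_j = (bx_j / sx_j)^2.

    The rule of thumb is that mean F above 10 makes weak-instrument bias in
    IVW unlikely.
    """
    bx, sx, _by, _sy = _require_univariable(h)
    if (sx == 0).any():
        raise DataError("per-SNP F undefined where sx = 0")
    f = (bx / sx) ** 2
    return InstrumentStrength(dict(zip(h.variant_ids, f.tolist())),
                              float(f.min()), float(f.mean()), float(f.max()))


def steiger_filter(h: HarmonizedSet, n_exposure: int, n_outcome: int,
                   exposure_binary: bool = False, outcome_binary: bool = False,
                   binary_r2: str = "z_over_sqrt_n") -> tuple[HarmonizedSet, pd.DataFrame]:
    """Directionality filter: keep variants explaining more variance in the exposure.

    Variance explained per variant: for continuous traits
    r^2 = t^2 / (t^2 + n - 2) with t = beta/se; for binary traits the
    default approximation is r = z / sqrt(n) on the observed scale
    (``binary_r2="z_over_sqrt_n"``), with the continuous t-statistic
    formula applied to the log-odds regression available as
    ``binary_r2="t_statistic"``.  The report carries both r^2 values and a
    Steiger z-test p-value (Fisher-z difference of the implied
    correlations) for every variant.

    Returns the filtered set and the per-variant report.
    """
    if not n_exposure or not n_outcome or n_exposure <= 0 or n_outcome <= 0:
        raise ConfigurationError("Steiger filtering requires positive sample sizes")
    if binary_r2 not in ("z_over_sqrt_n", "t_statistic"):
        raise ConfigurationError(f"unknown binary_r2 mode {binary_r2!r}")
    bx, sx, by, sy = _require_univariable(h)

    def r2_of(beta, se, n, binary):
        t2 = (beta / se) ** 2
        if binary and binary_r2 == "z_over_sqrt_n":
            return np.minimum(t2 / n, 1.0 - 1e-12)
        return t2 / (t2 + n - 2)

    r2_exp = r2_of(bx, sx, n_exposure, exposure_binary)
    r2_out = r2_of(by, sy, n_outcome, outcome_binary)
    r_exp = np.sqrt(r2_exp)
    r_out = np.sqrt(r2_out)
    denom = np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / denom
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    keep = r2_exp > r2_out
    report = pd.DataFrame({
        "variant_id": h.variant_ids,
        "r2_exposure": r2_exp,
        "r2_outcome": r2_out,
        "steiger_z": z,
        "steiger_pvalue": pvals,
        "kept": keep,
    })
    return h.subset(keep), report
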