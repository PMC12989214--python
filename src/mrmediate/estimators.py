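"""The two-sample MR estimator battery.

Every estimator consumes a harmonized instrument set and returns an
:class:`MREstimate`.  The inverse-variance weighted (IVW) method is the
primary estimator; MR-Egger, maximum likelihood, simple/weighted median and
simple/weighted mode provide robustness under different pleiotropy
assumptions.  All resampling-based standard errors (median, mode) take an
explicit seed.

Conventions: Wald ratios theta_i = by_i / bx_i with first-order weights
w_i = bx_i^2 / sey_i^2 (exposure-side uncertainty ignored in the weights);
binary-outcome effects are log odds ratios, reported alongside
OR = exp(beta) with 95% CI exp(beta +/- 1.96 se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "max_likelihood",
    "median_estimators",
    "mode_estimators",
    "all_estimates",
    "BATTERY",
]

BATTERY = (
    "IVW",
    "Egger",
    "MaxLik",
    "SimpleMedian",
    "WeightedMedian",
    "SimpleMode",
    "WeightedMode",
)


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect estimate.

    ``beta`` is on the outcome scale (log odds for binary outcomes); ``or_``
    is exp(beta) with a 95% Wald CI on the OR scale.  ``pval`` is computed
    under the method's reference distribution (normal, or Student t with
    k - 2 df for the Egger slope).
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    converged: bool = True

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + 1.959963984540054 * self.se)


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _estimate(method: str, beta: float, se: float, k: int, pval=None, converged=True):
    if pval is None:
        pval = _normal_p(beta, se)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      pval=float(max(pval, np.nextafter(0, 1))), n_snp=k,
                      converged=converged)


def _arrays(insts: Sequence[HarmonizedInstrument]):
    bx = np.array([h.bx for h in insts], dtype=float)
    sex = np.array([h.sex for h in insts], dtype=float)
    by = np.array([h.by for h in insts], dtype=float)
    sey = np.array([h.sey for h in insts], dtype=float)
    return bx, sex, by, sey


def _ratios(insts: Sequence[HarmonizedInstrument]):
    bx, sex, by, sey = _arrays(insts)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("instrument with bx = 0")
    theta = by / bx
    se_theta = sey / np.abs(bx)  # first order
    weights = bx**2 / sey**2
    return theta, se_theta, weights


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE sey/|bx|."""
    if inst.bx == 0:
        raise DegenerateInstrumentError(f"{inst.snp_id}: bx = 0")
    beta = inst.by / inst.bx
    se = inst.sey / abs(inst.bx)
    return _estimate("Wald", beta, se, 1)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    effects_model: str = "auto",
) -> MREstimate:
    """Inverse-variance weighted meta-analysis of the per-SNP Wald ratios.

    ``effects_model``: ``"fixed"``, ``"random"`` (multiplicative SE inflation
    by sqrt(max(1, Q/(k-1)))), or ``"auto"`` which applies the random-effects
    model when Cochran's Q has p < 0.05 and the fixed-effects model otherwise.
    """
    if len(insts) < 2:
        raise InsufficientInstrumentsError("IVW needs at least 2 instruments")
    if effects_model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    theta, _, w = _ratios(insts)
    k = len(insts)
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - beta) ** 2))
    q_pval = float(stats.chi2.sf(q, k - 1))
    inflation = math.sqrt(max(1.0, q / (k - 1)))
    if effects_model == "fixed":
        se, label = se_fixed, "IVW_fixed"
    elif effects_model == "random":
        se, label = se_fixed * inflation, "IVW_random"
    else:
        if q_pval < 0.05:
            se, label = se_fixed * inflation, "IVW_random"
        else:
            se, label = se_fixed, "IVW_fixed"
    return _estimate(label, beta, se, k)


def cochran_q(
    insts: Sequence[HarmonizedInstrument], beta_ref: float | None = None
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic over the per-SNP Wald ratios.

    ``beta_ref`` defaults to the fixed-effects IVW estimate.  Returns
    ``(q, df, pval)`` with df = k - 1 and a chi-square upper-tail p-value.
    """
    if len(insts) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    theta, _, w = _ratios(insts)
    if beta_ref is None:
        beta_ref = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - beta_ref) ** 2))
    df = len(insts) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger(insts: Sequence[HarmonizedInstrument]):
    """MR-Egger: weighted regression of by on bx with an intercept.

    Instruments are first oriented so every bx >= 0; the regression uses
    weights 1/sey^2.  The slope is the pleiotropy-adjusted causal estimate
    (t test, k - 2 df); a nonzero intercept indicates directional pleiotropy.

    Returns ``(slope_estimate, intercept, intercept_se, intercept_pval)``.
    """
    k = len(insts)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, _, by, sey = _arrays(insts)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sey**2
    # closed-form 2x2 weighted normal equations
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    # multiplicative overdispersion (plain WLS residual variance; unlike the
    # random-effects IVW it is not floored at 1, which keeps the intercept
    # test calibrated rather than conservative under mild under-dispersion)
    sigma2 = max(float(np.sum(w * resid**2) / (k - 2)), 1e-300)
    se_slope = math.sqrt(sigma2 * sw / det)
    se_int = math.sqrt(sigma2 * swxx / det)
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, k - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, k - 2))
    est = _estimate("Egger", slope, se_slope, k, pval=p_slope)
    return est, float(intercept), float(se_int), p_int


def max_likelihood(insts: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Maximum-likelihood causal estimate under a bivariate normal model.

    Model: bx_i ~ N(xi_i, sex_i^2), by_i ~ N(beta * xi_i, sey_i^2) with
    per-SNP latent exposure effects xi_i profiled out.  The profile
    log-likelihood in beta is maximized numerically; the SE comes from the
    observed information (numerical second derivative at the optimum).
    """
    if len(insts) < 2:
        raise InsufficientInstrumentsError("maximum likelihood needs at least 2 instruments")
    bx, sex, by, sey = _arrays(insts)

    def negloglik(beta: float) -> float:
        # profiling xi_i gives residual variance sey^2 + beta^2 sex^2
        var = sey**2 + beta**2 * sex**2
        return float(0.5 * np.sum((by - beta * bx) ** 2 / var + np.log(var)))

    # bracket around the IVW point estimate
    w = bx**2 / sey**2
    start = float(np.sum(w * (by / bx)) / np.sum(w))
    span = 10.0 * max(1.0, abs(start))
    res = optimize.minimize_scalar(
        negloglik, bounds=(start - span, start + span), method="bounded",
        options={"xatol": 1e-10},
    )
    beta = float(res.x)
    h = 1e-5 * max(1.0, abs(beta))
    d2 = (negloglik(beta + h) - 2.0 * negloglik(beta) + negloglik(beta - h)) / h**2
    converged = bool(res.success) and d2 > 0
    se = math.sqrt(1.0 / d2) if d2 > 0 else float("nan")
    return _estimate("MaxLik", beta, se, len(insts), converged=converged)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative weight 0.5."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / np.sum(w)
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def _bootstrap_se(point_fn, theta, se_theta, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_theta, size=(n_boot, theta.size))
    ests = np.apply_along_axis(point_fn, 1, draws)
    return float(np.std(ests, ddof=1))


def median_estimators(
    insts: Sequence[HarmonizedInstrument],
    kind: str = "weighted",
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple or weighted median of the per-SNP Wald ratios.

    The simple median is consistent when >50% of instruments are valid; the
    weighted median when >50% of the weight comes from valid instruments.
    SE by seeded parametric bootstrap (``n_boot`` draws of theta_i from
    N(theta_i, se_theta_i)).
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError("median estimators need at least 3 instruments")
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown kind {kind!r}")
    theta, se_theta, w = _ratios(insts)
    if kind == "simple":
        point_fn = lambda t: float(np.median(t))
        label = "SimpleMedian"
    else:
        point_fn = lambda t: _weighted_median(np.asarray(t), w)
        label = "WeightedMedian"
    beta = point_fn(theta)
    se = _bootstrap_se(point_fn, theta, se_theta, n_boot, seed)
    return _estimate(label, beta, se, len(insts))


def _mode_point(theta: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    """Peak of the weighted normal-kernel density of theta on a fine grid."""
    lo, hi = theta.min() - 3 * bandwidth, theta.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / bandwidth) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def _mode_bandwidth(theta: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9 * min(sd, IQR/1.349) * k^(-1/5), scaled."""
    s = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    if spread <= 0:
        spread = max(abs(float(np.mean(theta))) * 1e-8, 1e-12)
    return factor * 0.9 * spread * theta.size ** (-1 / 5)


def mode_estimators(
    insts: Sequence[HarmonizedInstrument],
    kind: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple or weighted mode of the smoothed Wald-ratio density.

    Consistent when the largest group of instruments sharing a causal
    estimate is valid (ZEMPA assumption).  Bandwidth is the modified
    Silverman rule scaled by ``bandwidth_factor``; SE by seeded parametric
    bootstrap.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError("mode estimators need at least 3 instruments")
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown kind {kind!r}")
    theta, se_theta, w = _ratios(insts)
    weights = np.ones_like(theta) if kind == "simple" else w / np.sum(w)
    label = "SimpleMode" if kind == "simple" else "WeightedMode"

    def point_fn(t):
        t = np.asarray(t, dtype=float)
        bw = _mode_bandwidth(t, bandwidth_factor)
        return _mode_point(t, weights, bw)

    beta = point_fn(theta)
    se = _bootstrap_se(point_fn, theta, se_theta, n_boot, seed)
    return _estimate(label, beta, se, len(insts))


def all_estimates(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Run the full seven-method battery on one instrument set.

    IVW uses the auto fixed/random switch on Cochran's Q (p < 0.05).
    Bootstrap-based methods derive their seeds deterministically from
    ``seed`` so the battery is reproducible as a unit.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    out = [ivw(insts, "auto")]
    est, *_ = egger(insts)
    out.append(est)
    out.append(max_likelihood(insts))
    out.append(median_estimators(insts, "simple", n_boot, seeds[0]))
    out.append(median_estimators(insts, "weighted", n_boot, seeds[1]))
    out.append(mode_estimators(insts, "simple", 1.0, n_boot, seeds[2]))
    out.append(mode_estimators(insts, "weighted", 1.0, n_boot, seeds[3]))
    return out
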