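"""Pleiotropy, heterogeneity, outlier, and directionality diagnostics.

An IVW estimate is only as good as the exclusion restriction behind it.  This
module implements the diagnostic battery used to decide whether a nominal
association is robust: Cochran's Q heterogeneity, the MR-Egger intercept,
the MR-PRESSO global/outlier/distortion tests (simulation-based residual sum
of squares), and the Steiger directionality test, combined by
:func:`robustness_gate` into the three-criterion robustness call:
(i) IVW p < 0.05, (ii) a consistent direction of effect across the method
battery, and (iii) no evidence of horizontal pleiotropy (non-significant
Egger intercept and MR-PRESSO global test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, cochran_q, egger, ivw
from .instruments import compute_r2
from .sumstats import HarmonizedInstrument

__all__ = [
    "SensitivityReport",
    "presso_global",
    "presso_outlier",
    "steiger",
    "steiger_filter",
    "robustness_gate",
    "sensitivity_report",
]


@dataclass
class SensitivityReport:
    """Diagnostic battery for one exposure-outcome pair."""

    q: float = float("nan")
    q_pval: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_pval: float = float("nan")
    presso_global_pval: float = float("nan")
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: MREstimate | None = None
    steiger_direction: str = "exposure_to_outcome"
    steiger_pval: float = float("nan")
    robust: bool = False
    failure_reasons: list[str] = field(default_factory=list)


def _loo_ivw_betas(bx, by, sey):
    """Leave-one-out fixed-effect IVW slope for each left-out index, vectorized."""
    w = bx**2 / sey**2
    num, den = np.sum(w * (by / bx)), np.sum(w)
    return (num - w * (by / bx)) / (den - w)


def presso_global(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """MR-PRESSO global test for horizontal pleiotropy.

    The observed residual sum of squares accumulates each SNP's weighted
    squared deviation from the leave-one-out IVW fit,
    RSS = sum_i (by_i - beta_(-i) * bx_i)^2 / sey_i^2.  The null distribution
    comes from ``n_sim`` parametric simulations drawing
    by_i ~ N(beta_(-i) * bx_i, sey_i^2) and bx_i ~ N(bx_i, sex_i^2) and
    recomputing the statistic.  p = (#{RSS_sim >= RSS_obs} + 1)/(n_sim + 1).
    """
    k = len(insts)
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    bx = np.array([h.bx for h in insts])
    sex = np.array([h.sex for h in insts])
    by = np.array([h.by for h in insts])
    sey = np.array([h.sey for h in insts])

    beta_loo = _loo_ivw_betas(bx, by, sey)
    rss_obs = float(np.sum((by - beta_loo * bx) ** 2 / sey**2))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sex, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sey, size=(n_sim, k))
    rss_sim = _sim_rss(bx_sim, by_sim, sey)
    pval = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    return rss_obs, float(pval)


def _sim_rss(bx_sim, by_sim, sey):
    """Global RSS of each simulated dataset, with its own leave-one-out fits."""
    theta = by_sim / bx_sim
    w = bx_sim**2 / sey[None, :] ** 2
    num = np.sum(w * theta, axis=1, keepdims=True)
    den = np.sum(w, axis=1, keepdims=True)
    beta_loo = (num - w * theta) / (den - w)
    return np.sum((by_sim - beta_loo * bx_sim) ** 2 / sey[None, :] ** 2, axis=1)


def presso_outlier(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
) -> tuple[list[str], MREstimate, float]:
    """MR-PRESSO outlier detection, correction, and distortion test.

    Each SNP's observed RSS contribution is compared with its simulated null
    distribution; per-SNP p-values below ``threshold`` (default Bonferroni
    0.05/k) flag outliers.  The corrected estimate is the IVW fit on the
    remaining SNPs.  The distortion p-value compares the observed relative
    change in the estimate with the distribution obtained by removing random
    subsets of the same size (1000 seeded draws).

    Returns ``(outlier_snp_ids, corrected_ivw, distortion_pval)``.
    """
    k = len(insts)
    if k < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    if threshold is None:
        threshold = 0.05 / k
    bx = np.array([h.bx for h in insts])
    sex = np.array([h.sex for h in insts])
    by = np.array([h.by for h in insts])
    sey = np.array([h.sey for h in insts])
    ids = [h.snp_id for h in insts]

    beta_loo = _loo_ivw_betas(bx, by, sey)
    rss_i_obs = (by - beta_loo * bx) ** 2 / sey**2

    # null distribution of each SNP's contribution, with leave-one-out fits
    # recomputed inside every simulated dataset (so estimation noise and the
    # propagation of a contaminated fit are part of the null)
    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sex, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sey, size=(n_sim, k))
    theta_sim = by_sim / bx_sim
    w_sim = bx_sim**2 / sey[None, :] ** 2
    num = np.sum(w_sim * theta_sim, axis=1, keepdims=True)
    den = np.sum(w_sim, axis=1, keepdims=True)
    beta_loo_sim = (num - w_sim * theta_sim) / (den - w_sim)
    rss_i_sim = (by_sim - beta_loo_sim * bx_sim) ** 2 / sey[None, :] ** 2
    pvals = (np.sum(rss_i_sim >= rss_i_obs[None, :], axis=0) + 1.0) / (n_sim + 1.0)

    outliers = [ids[i] for i in range(k) if pvals[i] < threshold]
    keep = [h for h in insts if h.snp_id not in set(outliers)]
    if len(keep) < 2:
        raise InsufficientInstrumentsError("no instruments survive outlier removal")
    uncorrected = ivw(insts, "fixed")
    corrected = ivw(keep, "fixed")

    if not outliers:
        return outliers, corrected, 1.0

    # distortion: is the shift larger than removing a random same-size subset?
    n_out = len(outliers)
    obs_dist = abs(corrected.beta - uncorrected.beta)
    null = np.empty(1000)
    for b in range(1000):
        drop = rng.choice(k, size=n_out, replace=False)
        mask = np.ones(k, dtype=bool)
        mask[drop] = False
        w = bx[mask] ** 2 / sey[mask] ** 2
        beta_b = np.sum(w * (by[mask] / bx[mask])) / np.sum(w)
        null[b] = abs(beta_b - uncorrected.beta)
    distortion_pval = float((np.sum(null >= obs_dist) + 1.0) / (null.size + 1.0))
    return outliers, corrected, distortion_pval


def steiger(
    insts: Sequence[HarmonizedInstrument],
    n_x: int | None = None,
    n_y: int | None = None,
) -> tuple[str, float, float, float]:
    """Steiger directionality test.

    Compares the variance the instrument set explains in the exposure
    (sum of 2*MAF*(1-MAF)*bx^2) with what it explains in the outcome; the
    causal arrow is taken to run from the trait with the larger explained
    variance.  The p-value is a z-test on the difference of Fisher-transformed
    correlations r = sqrt(R^2) across the two (independent) GWAS samples.

    Returns ``(direction, pval, r2_exposure, r2_outcome)``.
    """
    missing = [h.snp_id for h in insts if h.eaf_x is None]
    if missing:
        raise ValueError(f"missing eaf for SNPs: {missing}")
    r2x = float(sum(compute_r2(h.eaf_x, h.bx) for h in insts))
    r2y = float(sum(compute_r2(h.eaf_x, h.by) for h in insts))
    if n_x is None:
        n_x = max((h.n_x for h in insts), default=0)
    if n_y is None:
        n_y = max((h.n_y for h in insts), default=0)
    direction = "exposure_to_outcome" if r2x > r2y else "outcome_to_exposure"
    if n_x > 3 and n_y > 3:
        rx = math.sqrt(min(r2x, 1.0 - 1e-12))
        ry = math.sqrt(min(r2y, 1.0 - 1e-12))
        zx, zy = np.arctanh(rx), np.arctanh(ry)
        z = (zx - zy) / math.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
        pval = float(2.0 * stats.norm.sf(abs(z)))
    else:
        pval = float("nan")
    return direction, pval, r2x, r2y


def steiger_filter(primary, secondary):
    """Per-SNP directionality filter for instrument specificity.

    Keeps records from ``primary`` (summary statistics for the trait being
    instrumented) whose explained variance on that trait exceeds their
    explained variance on ``secondary``.  Used when picking instruments for a
    mediator that sits downstream of an exposure: SNPs acting on the mediator
    through the exposure explain more variance in the exposure and would
    otherwise contaminate the mediator->outcome leg with the exposure's
    direct path.  SNPs absent from ``secondary`` or lacking eaf are kept.
    """
    sec = {r.snp_id: r for r in secondary}
    out = []
    for rec in primary:
        other = sec.get(rec.snp_id)
        if other is None or rec.eaf is None or other.eaf is None:
            out.append(rec)
            continue
        if compute_r2(rec.eaf, rec.beta) > compute_r2(other.eaf, other.beta):
            out.append(rec)
    return out


def robustness_gate(
    estimates: Sequence[MREstimate],
    report: SensitivityReport,
    alpha: float = 0.05,
) -> tuple[bool, list[str]]:
    """The three-criterion robustness call.

    Robust iff (i) the IVW p-value < ``alpha``; (ii) every supplied method's
    effect has the same sign; (iii) the Egger intercept and MR-PRESSO global
    p-values are both >= ``alpha`` (when available), and the Steiger
    direction (when available) is exposure-to-outcome.  Returns the verdict
    and the list of failed clauses.
    """
    ivw_est = next((e for e in estimates if e.method.startswith("IVW")), None)
    if ivw_est is None:
        raise ValueError("estimates must include an IVW entry")
    reasons = []
    if not (ivw_est.pval < alpha):
        reasons.append(f"IVW p = {ivw_est.pval:.3g} >= {alpha:g}")
    signs = {math.copysign(1.0, e.beta) for e in estimates if e.beta != 0}
    if len(signs) > 1:
        reasons.append("direction inconsistent across methods")
    if not math.isnan(report.egger_intercept_pval) and report.egger_intercept_pval < alpha:
        reasons.append(f"Egger intercept p = {report.egger_intercept_pval:.3g} < {alpha:g}")
    if not math.isnan(report.presso_global_pval) and report.presso_global_pval < alpha:
        reasons.append(f"MR-PRESSO global p = {report.presso_global_pval:.3g} < {alpha:g}")
    if report.steiger_direction != "exposure_to_outcome":
        reasons.append("Steiger direction reversed")
    return len(reasons) == 0, reasons


def sensitivity_report(
    insts: Sequence[HarmonizedInstrument],
    estimates: Sequence[MREstimate],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery and the robustness gate.

    MR-PRESSO requires >= 4 instruments and its outlier stage only runs when
    the global test is significant; unavailable diagnostics are reported as
    NaN and do not fail the gate.
    """
    rep = SensitivityReport()
    rep.q, _, rep.q_pval = cochran_q(insts)
    if len(insts) >= 3:
        _, rep.egger_intercept, _, rep.egger_intercept_pval = egger(insts)
    if len(insts) >= 4:
        _, rep.presso_global_pval = presso_global(insts, n_sim=n_sim, seed=seed)
        if rep.presso_global_pval < alpha:
            try:
                rep.presso_outliers, rep.presso_corrected, _ = presso_outlier(
                    insts, n_sim=n_sim, seed=seed
                )
            except InsufficientInstrumentsError:
                pass
    try:
        rep.steiger_direction, rep.steiger_pval, _, _ = steiger(insts)
    except ValueError:
        rep.steiger_pval = float("nan")
    rep.robust, rep.failure_reasons = robustness_gate(estimates, rep, alpha=alpha)
    return rep
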