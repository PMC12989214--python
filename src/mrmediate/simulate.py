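"""Synthetic GWAS summary statistics with known causal and mediation structure.

The generator emulates the three-cohort design of a gut-microbiota ->
blood-metabolite -> sepsis mediation study: three mutually independent
cohorts (exposure, mediator, outcome GWAS), per-SNP additive effects on a
continuous exposure, a linear (or liability/logistic) causal chain
X -> M -> Y with configurable beta1, beta2 and direct effect, an optional
fraction of pleiotropic SNPs, exchangeable-correlation LD blocks, and a
configurable minor-allele-frequency spectrum.

Two SNP panels are simulated: one with effects on the exposure and a second
with direct effects on the mediator, so each MR leg has its own valid
instruments (exposure SNPs instrument X -> M and X -> Y; mediator SNPs
instrument M -> Y).  All three summary-stat tables report every SNP, and the
p-value threshold at selection time picks the right instruments per leg.

All randomness flows from a single seed through named SeedSequence substreams
(one per cohort and stage), so identical truth + seed reproduce identical
tables bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import SimulationError
from .instruments import LDMatrix
from .sumstats import VariantAssociation

__all__ = ["SimulationTruth", "simulate_triplet", "published_mediation_estimates"]

_ALLELES = ("A", "G")  # non-palindromic pair; harmonization is tested elsewhere


@dataclass
class SimulationTruth:
    """Generative parameters for one synthetic triplet of GWAS cohorts.

    Defaults represent a well-powered desk-scale study: 50 exposure SNPs and
    50 mediator SNPs explaining 10% of variance each, three cohorts of
    50,000, a chain beta1 = 0.4, beta2 = 0.5 with direct effect 0.1 (total
    effect 0.3, true mediated proportion 2/3), no pleiotropy, independent
    SNPs (ld_block_size = 1).
    """

    n_snps: int = 50
    n_mediator_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure_cohort: int = 50_000
    n_mediator_cohort: int = 50_000
    n_outcome_cohort: int = 50_000
    exposure_h2: float = 0.10
    mediator_h2: float = 0.10
    snp_effects: list[float] | None = None
    mediator_snp_effects: list[float] | None = None
    beta1: float = 0.4
    beta2: float = 0.5
    direct: float = 0.1
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.1
    balanced_pleiotropy: bool = True
    outcome_type: str = "continuous"
    case_fraction: float = 0.05
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.outcome_type not in ("continuous", "binary"):
            raise SimulationError(f"unknown outcome_type {self.outcome_type!r}")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise SimulationError("pleiotropy_frac must be in [0, 1]")
        if not (0 < self.case_fraction < 1):
            raise SimulationError(f"case_fraction must be in (0, 1), got {self.case_fraction}")
        if self.n_snps < 1 or min(self.n_exposure_cohort, self.n_mediator_cohort,
                                  self.n_outcome_cohort) < 10:
            raise SimulationError("need n_snps >= 1 and cohorts of at least 10")

    @property
    def n_pleiotropic(self) -> int:
        return int(round(self.pleiotropy_frac * self.n_snps))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _draw_genotypes(rng, n, mafs, block_size, rho):
    """Genotypes as two Gaussian-copula haplotypes per individual.

    Within each block of ``block_size`` SNPs, latent normals share an
    exchangeable correlation ``rho``; thresholding at the MAF quantile turns
    each latent value into one allele, and two independent haplotype draws
    sum to the genotype.  With block_size = 1 or rho = 0 this reduces to
    independent Binomial(2, maf) draws.
    """
    k = len(mafs)
    if block_size <= 1 or rho == 0.0:
        return rng.binomial(2, mafs, size=(n, k)).astype(float)
    g = np.zeros((n, k))
    thresholds = stats.norm.ppf(mafs)
    for _ in range(2):  # two haplotypes
        shared = rng.standard_normal((n, (k + block_size - 1) // block_size))
        own = rng.standard_normal((n, k))
        block_of = np.arange(k) // block_size
        latent = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * own
        g += (latent < thresholds[None, :]).astype(float)
    return g


def _generating_ld(mafs, block_size, rho) -> np.ndarray:
    """Pairwise r^2 implied by the generating copula (latent correlation)."""
    k = len(mafs)
    if block_size <= 1 or rho == 0.0:
        return np.eye(k)
    block_of = np.arange(k) // block_size
    same = block_of[:, None] == block_of[None, :]
    r2 = np.where(same, rho**2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def _marginal_linear(g, y):
    """Per-SNP simple linear regression of y on each genotype column."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = gc.T @ yc / sxx
    resid_ss = np.sum(yc**2) - beta**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    pval = 2.0 * stats.t.sf(np.abs(beta) / se, n - 2)
    return beta, se, np.clip(pval, np.nextafter(0, 1), 1.0)


def _marginal_logistic(g, y, max_iter=30, tol=1e-8):
    """Per-SNP logistic regression (intercept + slope), Newton-Raphson.

    All SNPs are fit simultaneously with vectorized Newton steps on the
    2-parameter model; SEs come from the inverse Fisher information.
    """
    n, k = g.shape
    b0 = np.full(k, np.log(y.mean() / (1 - y.mean())))
    b1 = np.zeros(k)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        wv = p * (1 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (r * g).sum(axis=0)
        h00 = wv.sum(axis=0)
        h01 = (wv * g).sum(axis=0)
        h11 = (wv * g * g).sum(axis=0)
        det = h00 * h11 - h01**2
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if max(np.max(np.abs(d0)), np.max(np.abs(d1))) < tol:
            break
    eta = b0[None, :] + g * b1[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    wv = p * (1 - p)
    h00 = wv.sum(axis=0)
    h01 = (wv * g).sum(axis=0)
    h11 = (wv * g * g).sum(axis=0)
    det = h00 * h11 - h01**2
    se = np.sqrt(h00 / det)
    pval = 2.0 * stats.norm.sf(np.abs(b1) / se)
    return b1, se, np.clip(pval, np.nextafter(0, 1), 1.0)


def _scaled_effects(rng, k, h2, mafs, ld) -> np.ndarray:
    """Per-SNP effects drawn N(0,1) and rescaled so the genetic variance is h2."""
    if k == 0:
        return np.zeros(0)
    a = rng.standard_normal(k)
    var_g = 2.0 * mafs * (1.0 - mafs)
    # genetic variance a' S a with S_jk = r_jk sqrt(var_j var_k), r = sqrt(r^2)
    s = np.sqrt(ld) * np.sqrt(np.outer(var_g, var_g))
    total = float(a @ s @ a)
    return a * np.sqrt(h2 / total)


def _records(ids, chrom, pos, mafs, beta, se, pval, n) -> list[VariantAssociation]:
    return [
        VariantAssociation(
            snp_id=ids[j], chrom=chrom[j], pos=int(pos[j]),
            effect_allele=_ALLELES[0], other_allele=_ALLELES[1],
            eaf=float(mafs[j]), beta=float(beta[j]), se=float(se[j]),
            pval=float(pval[j]), n=n,
        )
        for j in range(len(ids))
    ]


def simulate_triplet(truth: SimulationTruth):
    """Simulate three independent GWAS cohorts from the causal chain.

    In every cohort: X = sum_j a_j G_j + e_x (unit variance);
    M = beta1 * X + sum_j d_j G_j + sum_j b_j G_j [pleiotropic] + e_m (unit
    variance); Y = direct * X + beta2 * M + sum_j c_j G_j [pleiotropic] + e_y
    (continuous, unit variance) or Bernoulli through a logistic link whose
    intercept is calibrated to ``case_fraction``.  Per-SNP marginal
    regressions computed separately in the three cohorts give the three
    summary-stat tables (linear, or logistic for a binary outcome).

    Returns ``(exposure_stats, mediator_stats, outcome_stats, ld)`` where the
    stats are lists of :class:`VariantAssociation` covering the full SNP
    panel (exposure SNPs then mediator SNPs) and ``ld`` is the exact
    generating-correlation LD matrix.
    """
    t = truth
    rngs = _substreams(
        t.seed,
        ["mafs", "effects", "pleio", "geno_x", "geno_m", "geno_y",
         "noise_x", "noise_m", "noise_y"],
    )
    k_x, k_m = t.n_snps, t.n_mediator_snps
    k = k_x + k_m
    mafs = rngs["mafs"].uniform(t.maf_range[0], t.maf_range[1], size=k)
    ld_r2 = _generating_ld(mafs, t.ld_block_size, t.ld_rho)

    ids = [f"rs{j + 1:05d}" for j in range(k)]
    chrom = ["1"] * k  # single chromosome keeps window semantics simple
    # blocks 100 kb apart; SNPs within a block 1 kb apart
    pos = np.array(
        [1_000_000 + (j // max(t.ld_block_size, 1)) * 100_000
         + (j % max(t.ld_block_size, 1)) * 1_000 for j in range(k)]
    )

    a = np.zeros(k)
    if t.snp_effects is not None:
        if len(t.snp_effects) != k_x:
            raise SimulationError("snp_effects length must equal n_snps")
        a[:k_x] = np.asarray(t.snp_effects, dtype=float)
    else:
        a[:k_x] = _scaled_effects(rngs["effects"], k_x, t.exposure_h2,
                                  mafs[:k_x], ld_r2[:k_x, :k_x])
    d = np.zeros(k)
    if t.mediator_snp_effects is not None:
        if len(t.mediator_snp_effects) != k_m:
            raise SimulationError("mediator_snp_effects length must equal n_mediator_snps")
        d[k_x:] = np.asarray(t.mediator_snp_effects, dtype=float)
    else:
        d[k_x:] = _scaled_effects(rngs["effects"], k_m, t.mediator_h2,
                                  mafs[k_x:], ld_r2[k_x:, k_x:])

    # pleiotropic exposure SNPs act directly on mediator and outcome
    b = np.zeros(k)
    c = np.zeros(k)
    n_pleio = t.n_pleiotropic
    if n_pleio > 0:
        idx = rngs["pleio"].choice(k_x, size=n_pleio, replace=False)
        if t.balanced_pleiotropy:
            b[idx] = rngs["pleio"].normal(0.0, t.pleiotropy_sd, size=n_pleio)
            c[idx] = rngs["pleio"].normal(0.0, t.pleiotropy_sd, size=n_pleio)
        else:
            # directional: nonzero mean relative to the exposure-increasing
            # allele (sign-aligned with a_j, otherwise arbitrary allele coding
            # would cancel the direction under instrument reorientation)
            align = np.sign(a[idx])
            align[align == 0] = 1.0
            b[idx] = align * rngs["pleio"].normal(t.pleiotropy_sd, t.pleiotropy_sd / 2,
                                                  size=n_pleio)
            c[idx] = align * rngs["pleio"].normal(t.pleiotropy_sd, t.pleiotropy_sd / 2,
                                                  size=n_pleio)

    var_g = 2.0 * mafs * (1.0 - mafs)
    s_full = ld_r2**0.5 * np.sqrt(np.outer(var_g, var_g))

    def _phenotypes(g, rng_noise):
        gc = g - 2.0 * mafs[None, :]
        var_ax = float(a @ s_full @ a)
        e_x = rng_noise.standard_normal(g.shape[0]) * np.sqrt(max(1.0 - var_ax, 1e-6))
        x = gc @ a + e_x
        gm = d + b
        var_gm = float(gm @ s_full @ gm)
        resid_m = 1.0 - t.beta1**2 - var_gm
        if resid_m <= 0:
            raise SimulationError("mediator variance over-committed (beta1^2 + genetics >= 1)")
        m = t.beta1 * x + gc @ gm + rng_noise.standard_normal(g.shape[0]) * np.sqrt(resid_m)
        lin = t.direct * x + t.beta2 * m + gc @ c
        return x, m, lin

    # exposure cohort
    g = _draw_genotypes(rngs["geno_x"], t.n_exposure_cohort, mafs, t.ld_block_size, t.ld_rho)
    x, _, _ = _phenotypes(g, rngs["noise_x"])
    bx, sx, px = _marginal_linear(g, x)
    exposure = _records(ids, chrom, pos, mafs, bx, sx, px, t.n_exposure_cohort)

    # mediator cohort
    g = _draw_genotypes(rngs["geno_m"], t.n_mediator_cohort, mafs, t.ld_block_size, t.ld_rho)
    _, m, _ = _phenotypes(g, rngs["noise_m"])
    bm, sm, pm = _marginal_linear(g, m)
    mediator = _records(ids, chrom, pos, mafs, bm, sm, pm, t.n_mediator_cohort)

    # outcome cohort
    g = _draw_genotypes(rngs["geno_y"], t.n_outcome_cohort, mafs, t.ld_block_size, t.ld_rho)
    _, _, lin = _phenotypes(g, rngs["noise_y"])
    rng_y = rngs["noise_y"]
    if t.outcome_type == "continuous":
        var_lin = float(np.var(lin))
        if var_lin >= 1.0:
            raise SimulationError("outcome variance over-committed (linear predictor var >= 1)")
        y = lin + rng_y.standard_normal(len(lin)) * np.sqrt(1.0 - var_lin)
        by, sy, py = _marginal_linear(g, y)
    else:
        alpha = _calibrate_intercept(lin, t.case_fraction)
        p_case = 1.0 / (1.0 + np.exp(-(alpha + lin)))
        y = (rng_y.uniform(size=len(lin)) < p_case).astype(float)
        if y.sum() < 10 or (1 - y).sum() < 10:
            raise SimulationError("degenerate binary outcome: fewer than 10 cases or controls")
        by, sy, py = _marginal_logistic(g, y)
    outcome = _records(ids, chrom, pos, mafs, by, sy, py, t.n_outcome_cohort)

    ld = LDMatrix(snp_ids=ids, r2=ld_r2, pos=list(pos), chrom=chrom)
    return exposure, mediator, outcome, ld


def _calibrate_intercept(lin: np.ndarray, case_fraction: float) -> float:
    """Solve for the logistic intercept giving the target case fraction."""
    if not (0 < case_fraction < 1):
        raise SimulationError(f"case_fraction must be in (0, 1), got {case_fraction}")

    def mean_p(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lin))))) - case_fraction

    lo, hi = -50.0, 50.0
    if mean_p(lo) > 0 or mean_p(hi) < 0:
        raise SimulationError(f"case_fraction {case_fraction} unreachable")
    return float(optimize.brentq(mean_p, lo, hi, xtol=1e-10))


def published_mediation_estimates() -> pd.DataFrame:
    """Published two-step MR mediation estimates for the gut-microbiota ->
    blood-metabolite -> sepsis axis.

    Returns the 23 exposure/mediator/outcome triples with their printed
    total-effect (beta0), exposure->mediator (beta1), and mediator->outcome
    (beta2) estimates, SEs, indirect effects, and mediated proportions, as a
    DataFrame.  Used as a regression fixture for the mediation arithmetic.
    """
    with resources.files("mrmediate.data").joinpath(
        "sepsis_mediation_published.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_triplet(truth: SimulationTruth, outdir) -> None:
    """Write the three summary-stat tables, the LD matrix, and truth.json."""
    import os

    from .sumstats import CANONICAL_COLUMNS

    exposure, mediator, outcome, ld = simulate_triplet(truth)
    os.makedirs(outdir, exist_ok=True)
    for name, recs in (("exposure", exposure), ("mediator", mediator), ("outcome", outcome)):
        df = pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
                    "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                    "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
                }
                for r in recs
            ],
            columns=list(CANONICAL_COLUMNS),
        )
        df.to_csv(os.path.join(outdir, f"{name}_sumstats.tsv"), sep="\t", index=False)
    ld.to_square_file(os.path.join(outdir, "ld_matrix.tsv"))
    truth.to_json(os.path.join(outdir, "truth.json"))
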