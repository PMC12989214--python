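"""Instrument selection: genome-wide filters, LD pruning, and strength metrics.

The validity of an MR estimate rests on the instruments: each SNP must be
robustly associated with the exposure (suggestive threshold p < 1e-5 for
microbiome and metabolite GWAS), mutually independent (LD r^2 < 0.1 within
500 kb), not directly associated with the outcome (p >= 1e-5), and strong
(F >= 10).  Exposures are analyzed only when at least three SNPs survive and
the instrument set explains at least 0.5% of exposure variance.

Per-SNP variance explained uses R^2 = 2*MAF*(1-MAF)*beta^2 and instrument
strength F = R^2*(n-k-1) / (k*(1-R^2)), with k the size of the instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, NotInstrumentableError
from .sumstats import (
    HarmonizedInstrument,
    RejectedRow,
    VariantAssociation,
    harmonize,
)

__all__ = [
    "LDMatrix",
    "InstrumentMetrics",
    "ScreenConfig",
    "compute_r2",
    "compute_f",
    "ld_prune",
    "select_instruments",
]


@dataclass
class LDMatrix:
    """Pairwise linkage-disequilibrium r^2 for a panel of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    pos: list[int]
    chrom: list[str]

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError(
                f"LD matrix shape {self.r2.shape} does not match {k} SNP ids"
            )
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ConfigurationError("LD matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def pair_r2(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as err:
            raise ConfigurationError(f"SNP {err.args[0]!r} missing from LD matrix") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @classmethod
    def from_square_file(cls, path, pos=None, chrom=None) -> "LDMatrix":
        """Read a square tab-delimited matrix whose header row/index are SNP ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        k = len(ids)
        return cls(
            snp_ids=ids,
            r2=df.to_numpy(dtype=float),
            pos=list(pos) if pos is not None else [0] * k,
            chrom=list(chrom) if chrom is not None else [""] * k,
        )

    @classmethod
    def from_long_file(cls, path, snp_ids=None, pos=None, chrom=None) -> "LDMatrix":
        """Read a long-format three-column (snp_a, snp_b, r2) tab-delimited file.

        Missing pairs default to r^2 = 0; the diagonal is set to 1.
        """
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise ConfigurationError("long-format LD file needs columns snp_a, snp_b, r2")
        a_col, b_col, r_col = df.columns[:3]
        if snp_ids is None:
            snp_ids = sorted(set(df[a_col].astype(str)) | set(df[b_col].astype(str)))
        snp_ids = [str(s) for s in snp_ids]
        idx = {s: i for i, s in enumerate(snp_ids)}
        k = len(snp_ids)
        mat = np.eye(k)
        for a, b, r in zip(df[a_col].astype(str), df[b_col].astype(str), df[r_col]):
            if a in idx and b in idx:
                mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = float(r)
        np.fill_diagonal(mat, 1.0)
        return cls(
            snp_ids=snp_ids,
            r2=mat,
            pos=list(pos) if pos is not None else [0] * k,
            chrom=list(chrom) if chrom is not None else [""] * k,
        )

    def to_square_file(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


@dataclass(frozen=True)
class InstrumentMetrics:
    """Strength summary of an instrument set."""

    k: int
    per_snp_r2: tuple[float, ...]
    total_r2: float
    per_snp_f: tuple[float, ...]
    min_f: float


@dataclass
class ScreenConfig:
    """Thresholds and reproducibility settings for a screening run.

    Defaults follow the study design: suggestive exposure threshold 1e-5,
    outcome-association exclusion at 1e-5, weak-instrument cutoff F = 10,
    at least 3 SNPs, instrument set explaining >= 0.5% of exposure variance,
    LD pruning at r^2 < 0.1 within 500 kb, nominal alpha 0.05.
    """

    p_exposure: float = 1e-5
    p_outcome_exclude: float = 1e-5
    f_min: float = 10.0
    min_snps: int = 3
    min_total_r2: float = 0.005
    ld_r2: float = 0.1
    ld_window_bp: int = 500_000
    alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 0
    bonferroni_groups: dict[str, int] = field(default_factory=dict)
    palindrome_policy: str = "drop_ambiguous"
    ambiguity_band: float = 0.08
    require_robust_for_mediation: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("p_exposure", "p_outcome_exclude", "f_min", "min_total_r2", "ld_r2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_snps < 1 or self.ld_window_bp <= 0:
            raise ConfigurationError("min_snps and ld_window_bp must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def compute_r2(eaf: float, beta: float) -> float:
    """Variance in the trait explained by one SNP: 2*MAF*(1-MAF)*beta^2.

    ``eaf`` may be either allele's frequency; MAF = min(eaf, 1-eaf) is used.
    Assumes the trait has unit variance (standardized GWAS), the convention
    under which this expression is the per-SNP R^2.
    """
    if not (0 <= eaf <= 1):
        raise ValueError(f"eaf must be in [0, 1], got {eaf}")
    maf = min(eaf, 1.0 - eaf)
    return 2.0 * maf * (1.0 - maf) * beta * beta


def compute_f(r2: float, n: int, k: int) -> float:
    """Instrument-strength F statistic: R^2*(n-k-1) / (k*(1-R^2)).

    ``n`` is the exposure GWAS sample size and ``k`` the number of
    instruments in the set.  F < 10 conventionally flags weak instruments.
    """
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def ld_prune(
    snps: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.1,
    window_bp: int = 500_000,
) -> list[VariantAssociation]:
    """Greedy LD pruning in ascending exposure p-value order.

    SNPs are visited from smallest p (ties broken by snp_id); a SNP is kept
    iff its r^2 with every already-kept SNP on the same chromosome within
    ``window_bp`` is below ``r2_threshold``.  Output sorted by (chrom, pos).

    Raises
    ------
    ConfigurationError
        If a SNP is absent from the LD matrix, naming the SNP.
    """
    for rec in snps:
        if rec.snp_id not in ld:
            raise ConfigurationError(f"SNP {rec.snp_id!r} missing from LD matrix")
    order = sorted(snps, key=lambda r: (r.pval, r.snp_id))
    kept: list[VariantAssociation] = []
    for cand in order:
        ok = True
        for ref in kept:
            if ref.chrom != cand.chrom:
                continue
            if abs(ref.pos - cand.pos) > window_bp:
                continue
            if ld.pair_r2(cand.snp_id, ref.snp_id) >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(cand)
    return sorted(kept, key=lambda r: (r.chrom, r.pos, r.snp_id))


def _metrics_for(insts: Sequence[HarmonizedInstrument]) -> InstrumentMetrics:
    k = len(insts)
    r2s = tuple(
        compute_r2(h.eaf_x, h.bx) if h.eaf_x is not None else 0.0 for h in insts
    )
    fs = tuple(
        compute_f(r2, h.n_x, k) if h.eaf_x is not None and h.n_x > k + 1 else float("nan")
        for r2, h in zip(r2s, insts)
    )
    finite = [f for f in fs if np.isfinite(f)]
    return InstrumentMetrics(
        k=k,
        per_snp_r2=r2s,
        total_r2=float(sum(r2s)),
        per_snp_f=fs,
        min_f=float(min(finite)) if finite else float("nan"),
    )


def select_instruments(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LDMatrix | None,
    cfg: ScreenConfig | None = None,
    *,
    proxy_map: Mapping[str, str] | None = None,
    return_log: bool = False,
):
    """Run the full instrument-selection pipeline for one exposure.

    Stages, in order: (1) keep exposure SNPs with p < ``cfg.p_exposure``;
    (2) LD-prune (skipped when ``ld`` is None); (3) harmonize against the
    outcome; (4) drop SNPs directly associated with the outcome
    (p < ``cfg.p_outcome_exclude``); (5) drop SNPs with F < ``cfg.f_min``
    (per-SNP R^2, k = current set size), recomputing metrics once after
    removal; (6) fail the exposure if fewer than ``cfg.min_snps`` SNPs remain
    or total R^2 < ``cfg.min_total_r2``.

    Returns ``(instruments, metrics)``; with ``return_log=True`` also returns
    the per-stage drop log as a list of :class:`RejectedRow`.

    Raises
    ------
    NotInstrumentableError
        With ``gate`` set to the failing stage (``"min_snps"`` or
        ``"min_total_r2"``).
    """
    cfg = cfg or ScreenConfig()
    log: list[RejectedRow] = []

    stage1 = []
    for rec in exposure:
        if rec.pval < cfg.p_exposure:
            stage1.append(rec)
        else:
            log.append(RejectedRow(rec.snp_id, f"exposure p >= {cfg.p_exposure:g}"))

    if ld is not None and stage1:
        pruned = ld_prune(stage1, ld, cfg.ld_r2, cfg.ld_window_bp)
        kept_ids = {r.snp_id for r in pruned}
        log.extend(
            RejectedRow(r.snp_id, "removed by LD pruning")
            for r in stage1
            if r.snp_id not in kept_ids
        )
    else:
        pruned = stage1

    def _fail(gate: str):
        if return_log:
            raise NotInstrumentableError(gate)
        raise NotInstrumentableError(gate)

    if not pruned:
        _fail("min_snps")

    insts, dropped = harmonize(
        pruned,
        outcome,
        palindrome_policy=cfg.palindrome_policy,
        ambiguity_band=cfg.ambiguity_band,
        proxy_map=proxy_map,
        return_dropped=True,
    )
    log.extend(dropped)

    stage4 = []
    for h in insts:
        if h.py < cfg.p_outcome_exclude:
            log.append(
                RejectedRow(h.snp_id, f"outcome-associated (p < {cfg.p_outcome_exclude:g})")
            )
        else:
            stage4.append(h)

    # weak-instrument exclusion with k = current set size, one recomputation
    metrics = _metrics_for(stage4)
    stage5 = []
    for h, f in zip(stage4, metrics.per_snp_f):
        if np.isfinite(f) and f < cfg.f_min:
            log.append(RejectedRow(h.snp_id, f"weak instrument (F = {f:.2f} < {cfg.f_min:g})"))
        else:
            stage5.append(h)
    metrics = _metrics_for(stage5)

    if len(stage5) < cfg.min_snps:
        _fail("min_snps")
    if metrics.total_r2 < cfg.min_total_r2:
        _fail("min_total_r2")

    if return_log:
        return stage5, metrics, log
    return stage5, metrics
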