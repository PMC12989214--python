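"""Study-scale orchestration: exposure-outcome screens and mediation sweeps.

``run_screen`` drives each exposure through instrument selection, the full
estimator battery, the sensitivity battery, and the multiplicity flags;
``build_mediation_candidates`` pairs the screen's hits into candidate
(taxon, metabolite) mediation triples; ``run_mediation_sweep`` estimates the
exposure->mediator leg for each candidate and combines the three legs with
:func:`mrmediate.mediation.two_step`.

Multiplicity follows the per-group Bonferroni scheme: the significance
threshold for a group (e.g. a taxonomic level, or "metabolites") is
alpha divided by the number of tests configured for the group — config data,
not inferred from the inputs, because the tested universe may exceed the
instrumentable exposures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MRMediateError, NotInstrumentableError
from .estimators import MREstimate, all_estimates, ivw
from .instruments import InstrumentMetrics, LDMatrix, ScreenConfig, select_instruments
from .mediation import MediationResult, two_step
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import VariantAssociation

__all__ = [
    "ScreenResult",
    "bonferroni_threshold",
    "run_screen",
    "build_mediation_candidates",
    "run_mediation_sweep",
    "screen_results_frame",
]


@dataclass
class ScreenResult:
    """Outcome of screening one exposure against one outcome."""

    exposure_id: str
    outcome_id: str
    group_label: str = ""
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    metrics: InstrumentMetrics | None = None
    instruments: list = field(default_factory=list)
    passes_nominal: bool = False
    passes_bonferroni: bool = False
    bonferroni_threshold: float = float("nan")
    failed_gate: str | None = None

    @property
    def ivw_estimate(self) -> MREstimate | None:
        return next((e for e in self.estimates if e.method.startswith("IVW")), None)


def bonferroni_threshold(
    group_label: str, groups: Mapping[str, int], alpha: float = 0.05
) -> float:
    """Per-group Bonferroni threshold alpha / (number of tests in the group)."""
    if group_label not in groups:
        raise ConfigurationError(f"unknown multiplicity group {group_label!r}")
    count = groups[group_label]
    if count < 1:
        raise ConfigurationError(f"group {group_label!r} has nonpositive test count")
    return alpha / count


def run_screen(
    exposures: Mapping[str, Sequence[VariantAssociation]],
    outcome: Sequence[VariantAssociation],
    ld: LDMatrix | None,
    cfg: ScreenConfig | None = None,
    *,
    outcome_id: str = "outcome",
    group_labels: Mapping[str, str] | None = None,
    log_path=None,
) -> list[ScreenResult]:
    """Screen every exposure against one outcome.

    Per-exposure failures (not-instrumentable gates, harmonization failures)
    are recorded on the result with ``failed_gate`` set, never silently
    skipped, and never abort the rest of the screen.  Given the same
    ``cfg.seed`` the run is deterministic; each exposure gets an independent
    substream derived from the seed and its position.

    ``group_labels`` maps exposure id -> multiplicity group; exposures whose
    group is missing from ``cfg.bonferroni_groups`` use the nominal alpha.
    """
    cfg = cfg or ScreenConfig()
    group_labels = group_labels or {}
    results: list[ScreenResult] = []
    log_records = []
    children = np.random.SeedSequence(cfg.seed).spawn(max(len(exposures), 1))
    for (exp_id, exp_records), child in zip(exposures.items(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        group = group_labels.get(exp_id, "")
        res = ScreenResult(exposure_id=exp_id, outcome_id=outcome_id, group_label=group)
        try:
            insts, metrics, drop_log = select_instruments(
                exp_records, outcome, ld, cfg, return_log=True
            )
            res.instruments = insts
            res.metrics = metrics
            res.estimates = all_estimates(insts, n_boot=cfg.n_sim, seed=sub_seed)
            res.sensitivity = sensitivity_report(
                insts, res.estimates, n_sim=cfg.n_sim, seed=sub_seed, alpha=cfg.alpha
            )
            ivw_est = res.ivw_estimate
            res.passes_nominal = ivw_est.pval < cfg.alpha
            if group in cfg.bonferroni_groups:
                res.bonferroni_threshold = bonferroni_threshold(
                    group, cfg.bonferroni_groups, cfg.alpha
                )
            else:
                res.bonferroni_threshold = cfg.alpha
            res.passes_bonferroni = ivw_est.pval < res.bonferroni_threshold
            log_records.append(
                {
                    "exposure": exp_id,
                    "outcome": outcome_id,
                    "seed": sub_seed,
                    "k": metrics.k,
                    "dropped": [
                        {"snp": d.snp_id, "reason": d.reason} for d in drop_log
                    ],
                }
            )
        except NotInstrumentableError as err:
            res.failed_gate = err.gate
            log_records.append(
                {"exposure": exp_id, "outcome": outcome_id, "seed": sub_seed,
                 "failed_gate": err.gate}
            )
        except MRMediateError as err:
            res.failed_gate = type(err).__name__
            log_records.append(
                {"exposure": exp_id, "outcome": outcome_id, "seed": sub_seed,
                 "error": str(err)}
            )
        results.append(res)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    return results


def build_mediation_candidates(
    gm_hits: Sequence[ScreenResult],
    met_hits: Sequence[ScreenResult],
    outcome_id: str,
    *,
    require_robust: bool = False,
) -> list[tuple[str, str]]:
    """Cartesian candidate (taxon, metabolite) pairs for one outcome.

    Both members must pass the nominal IVW screen for the given outcome
    (additionally the three-criterion robustness gate when
    ``require_robust=True``).  The exposure->mediator leg of each pair still
    has to prove significant before a mediation decomposition is attempted;
    that gate lives in :func:`run_mediation_sweep`.
    """

    def _ok(r: ScreenResult) -> bool:
        if r.outcome_id != outcome_id or not r.passes_nominal:
            return False
        if require_robust:
            return r.sensitivity is not None and r.sensitivity.robust
        return True

    taxa = [r.exposure_id for r in gm_hits if _ok(r)]
    mets = [r.exposure_id for r in met_hits if _ok(r)]
    return [(t, m) for t in taxa for m in mets]


def run_mediation_sweep(
    candidates: Sequence[tuple[str, str]],
    gm_results: Mapping[str, ScreenResult],
    met_results: Mapping[str, ScreenResult],
    gm_sumstats: Mapping[str, Sequence[VariantAssociation]],
    met_sumstats: Mapping[str, Sequence[VariantAssociation]],
    ld: LDMatrix | None,
    cfg: ScreenConfig | None = None,
    *,
    outcome_id: str = "outcome",
    delta: str = "exact",
) -> list[MediationResult]:
    """Estimate the exposure->mediator leg per candidate and decompose.

    beta0 comes from the taxon's screen against the outcome, beta2 from the
    metabolite's screen (univariable mediator->outcome MR), and beta1 from a
    fresh taxon->metabolite MR run here.  Only candidates whose three legs
    are all significant at ``cfg.alpha`` (the all-three-significant gate)
    yield a reported row; candidates failing instrumentation on the beta1
    leg are skipped.
    """
    cfg = cfg or ScreenConfig()
    out: list[MediationResult] = []
    for taxon, metabolite in candidates:
        gm_res = gm_results[taxon]
        met_res = met_results[metabolite]
        b0_est = gm_res.ivw_estimate
        b2_est = met_res.ivw_estimate
        if b0_est is None or b2_est is None:
            continue
        try:
            insts, _ = select_instruments(
                gm_sumstats[taxon], met_sumstats[metabolite], ld, cfg
            )
            b1_est = ivw(insts, "auto")
        except MRMediateError:
            continue
        if not (b1_est.pval < cfg.alpha):
            continue
        res = two_step(
            b0_est.beta, b0_est.se, b1_est.beta, b1_est.se, b2_est.beta, b2_est.se,
            exposure_id=taxon, mediator_id=metabolite, outcome_id=outcome_id,
            alpha=cfg.alpha, delta=delta,
        )
        if res.gated:
            out.append(res)
    return out


def screen_results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format screen summary (one row per exposure-outcome pair).

    Full-precision columns; suitable for round-tripping and for rendering
    heatmap-style summaries (exposure, outcome, OR, p, pass flags).
    """
    rows = []
    for r in results:
        ivw_est = r.ivw_estimate
        rows.append(
            {
                "exposure": r.exposure_id,
                "outcome": r.outcome_id,
                "group": r.group_label,
                "n_snp": ivw_est.n_snp if ivw_est else 0,
                "method": ivw_est.method if ivw_est else "",
                "beta": ivw_est.beta if ivw_est else float("nan"),
                "se": ivw_est.se if ivw_est else float("nan"),
                "pval": ivw_est.pval if ivw_est else float("nan"),
                "or": ivw_est.or_ if ivw_est else float("nan"),
                "ci_low": ivw_est.ci_low if ivw_est else float("nan"),
                "ci_high": ivw_est.ci_high if ivw_est else float("nan"),
                "total_r2": r.metrics.total_r2 if r.metrics else float("nan"),
                "min_f": r.metrics.min_f if r.metrics else float("nan"),
                "passes_nominal": r.passes_nominal,
                "passes_bonferroni": r.passes_bonferroni,
                "bonferroni_threshold": r.bonferroni_threshold,
                "robust": r.sensitivity.robust if r.sensitivity else False,
                "failed_gate": r.failed_gate or "",
            }
        )
    return pd.DataFrame(rows)
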