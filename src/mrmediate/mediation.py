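"""Two-step mediation MR: indirect effects, SEs, and mediation proportions.

The two-step design estimates three effects by separate two-sample MR
analyses: the total effect of exposure on outcome (beta0), the effect of
exposure on mediator (beta1), and the effect of mediator on outcome (beta2).
When all three are significant, the indirect (mediated) effect is
beta1 * beta2, the proportion mediated is (beta1 * beta2) / beta0, and the
SE of the product comes from the delta method.

The default SE is the exact variance of a product of independent normals,
sqrt(beta1^2 se2^2 + beta2^2 se1^2 + se1^2 se2^2); the first-order
(two-term) approximation is available via ``delta="first_order"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MediationResult", "two_step", "mediation_gate", "mediation_table"]


@dataclass(frozen=True)
class MediationResult:
    """One exposure -> mediator -> outcome mediation decomposition."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta0: float
    se0: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    indirect_se: float
    indirect_pval: float
    proportion: float | None
    gated: bool
    sign_consistent: bool = True

    @property
    def p0(self) -> float:
        return _normal_p(self.beta0, self.se0)

    @property
    def p1(self) -> float:
        return _normal_p(self.beta1, self.se1)

    @property
    def p2(self) -> float:
        return _normal_p(self.beta2, self.se2)


def _normal_p(beta: float, se: float) -> float:
    # clipped away from exact 0 (norm.sf underflows near |z| ~ 38) so the
    # strict (0, 1] p-value contract holds for arbitrarily strong effects
    tiny = float(np.nextafter(0, 1))
    if se == 0:
        return 1.0 if beta == 0 else tiny
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), tiny))


def product_se(beta1: float, se1: float, beta2: float, se2: float,
               delta: str = "exact") -> float:
    """Delta-method SE of the product beta1 * beta2.

    ``"exact"`` includes the se1^2 * se2^2 cross term (the exact variance of
    a product of independent normals); ``"first_order"`` is the two-term
    Taylor approximation.
    """
    v = beta1**2 * se2**2 + beta2**2 * se1**2
    if delta == "exact":
        v += se1**2 * se2**2
    elif delta != "first_order":
        raise ValueError(f"unknown delta variant {delta!r}")
    return math.sqrt(v)


def two_step(
    beta0: float,
    se0: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    *,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    alpha: float = 0.05,
    delta: str = "exact",
) -> MediationResult:
    """Combine the three MR legs into a mediation decomposition.

    indirect = beta1 * beta2; proportion = indirect / beta0 (None when
    beta0 = 0, never infinity); the indirect p-value is the normal test of
    indirect / indirect_se.  ``gated`` records whether all three legs are
    individually significant at ``alpha`` (strict inequality).  The
    proportion is not clamped: an out-of-range or sign-inconsistent value is
    reported as-is with ``sign_consistent=False``.
    """
    if se0 <= 0 or se1 <= 0 or se2 <= 0:
        raise ValueError("all SEs must be > 0")
    indirect = beta1 * beta2
    ise = product_se(beta1, se1, beta2, se2, delta=delta)
    ipval = _normal_p(indirect, ise)
    proportion = None if beta0 == 0 else indirect / beta0
    p0, p1, p2 = (_normal_p(beta0, se0), _normal_p(beta1, se1), _normal_p(beta2, se2))
    gated = mediation_gate(p0, p1, p2, alpha)
    sign_ok = proportion is not None and 0 <= proportion <= 1
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta0=beta0, se0=se0, beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        indirect=indirect,
        indirect_se=ise,
        indirect_pval=ipval,
        proportion=proportion,
        gated=gated,
        sign_consistent=sign_ok,
    )


def mediation_gate(p0: float, p1: float, p2: float, alpha: float = 0.05) -> bool:
    """All-three-significant gate: every leg's p strictly below ``alpha``."""
    for p in (p0, p1, p2):
        if not (0 < p <= 1):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return p0 < alpha and p1 < alpha and p2 < alpha


def _pm(beta: float, se: float) -> str:
    return f"{beta:.3f} ± {se:.3f}"


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Render mediation results as a table with 3-decimal display columns.

    Display columns show "beta ± SE" strings and a 3-decimal proportion
    (``NA(beta0=0)`` when undefined); full-precision numeric columns are
    retained alongside for round-tripping.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome_id,
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "beta0_se": _pm(r.beta0, r.se0),
                "beta1_se": _pm(r.beta1, r.se1),
                "beta2_se": _pm(r.beta2, r.se2),
                "indirect_se_display": _pm(r.indirect, r.indirect_se),
                "proportion_display": (
                    "NA(beta0=0)" if r.proportion is None else f"{r.proportion:.3f}"
                ),
                "beta0": r.beta0, "se0": r.se0,
                "beta1": r.beta1, "se1": r.se1,
                "beta2": r.beta2, "se2": r.se2,
                "indirect": r.indirect,
                "indirect_se_full": r.indirect_se,
                "indirect_pval": r.indirect_pval,
                "proportion": float("nan") if r.proportion is None else r.proportion,
                "gated": r.gated,
            }
        )
    columns = [
        "outcome", "exposure", "mediator", "beta0_se", "beta1_se", "beta2_se",
        "indirect_se_display", "proportion_display", "beta0", "se0", "beta1",
        "se1", "beta2", "se2", "indirect", "indirect_se_full", "indirect_pval",
        "proportion", "gated",
    ]
    return pd.DataFrame(rows, columns=columns)
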