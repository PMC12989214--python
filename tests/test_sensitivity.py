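"""MR-PRESSO, Steiger directionality, and the robustness gate."""

import math

import numpy as np
import pytest

from mrmediate import (
    InsufficientInstrumentsError,
    MREstimate,
    SensitivityReport,
    ivw,
    presso_global,
    presso_outlier,
    robustness_gate,
    sensitivity_report,
    steiger,
)

from conftest import make_instruments


def _clean_insts(rng, k=20, beta=0.3, sey_val=0.01):
    bx_true = rng.uniform(0.05, 0.3, k)
    sex = np.full(k, 0.005)
    sey = np.full(k, sey_val)
    bx = rng.normal(bx_true, sex)
    by = rng.normal(beta * bx_true, sey)
    return make_instruments(bx, by, sex=sex, sey=sey)


class TestPressoGlobal:
    def test_deterministic_under_fixed_seed(self):
        insts = _clean_insts(np.random.default_rng(0))
        _, p1 = presso_global(insts, n_sim=300, seed=5)
        _, p2 = presso_global(insts, n_sim=300, seed=5)
        assert p1 == p2

    def test_planted_outlier_detected(self):
        insts = _clean_insts(np.random.default_rng(1))
        h = insts[3]
        insts[3] = type(h)(snp_id=h.snp_id, bx=h.bx, sex=h.sex,
                           by=h.by + 10 * h.sey, sey=h.sey, px=h.px, py=h.py,
                           eaf_x=h.eaf_x, n_x=h.n_x, n_y=h.n_y)
        _, p = presso_global(insts, n_sim=1000, seed=5)
        assert p < 0.01

    def test_p_monotone_in_displacement(self):
        """Larger planted displacement never yields a larger p-value."""
        pvals = []
        for shift in (0.0, 5.0, 10.0):
            insts = _clean_insts(np.random.default_rng(2))
            h = insts[0]
            insts[0] = type(h)(snp_id=h.snp_id, bx=h.bx, sex=h.sex,
                               by=h.by + shift * h.sey, sey=h.sey, px=h.px,
                               py=h.py, eaf_x=h.eaf_x, n_x=h.n_x, n_y=h.n_y)
            pvals.append(presso_global(insts, n_sim=500, seed=9)[1])
        assert pvals[0] >= pvals[1] >= pvals[2]

    def test_insufficient_instruments(self):
        insts = _clean_insts(np.random.default_rng(3), k=3)
        with pytest.raises(InsufficientInstrumentsError):
            presso_global(insts)


class TestPressoOutlier:
    def test_planted_outlier_recovered(self):
        """The displaced SNP is flagged in every seeded run; spurious extra
        flags stay within the family-wise budget the Bonferroni threshold
        concedes (~5% of runs)."""
        detected = 0
        extra_flag_runs = 0
        n_runs = 100
        for rep in range(n_runs):
            rng = np.random.default_rng(100 + rep)
            insts = _clean_insts(rng, k=21)
            h = insts[7]
            insts[7] = type(h)(snp_id=h.snp_id, bx=h.bx, sex=h.sex,
                               by=h.by + 10 * h.sey, sey=h.sey, px=h.px,
                               py=h.py, eaf_x=h.eaf_x, n_x=h.n_x, n_y=h.n_y)
            outliers, _, _ = presso_outlier(insts, n_sim=500, seed=rep)
            detected += insts[7].snp_id in outliers
            extra_flag_runs += len(set(outliers) - {insts[7].snp_id}) > 0
        assert detected / n_runs >= 0.95
        assert extra_flag_runs / n_runs <= 0.10

    def test_no_outliers_is_noop(self):
        insts = _clean_insts(np.random.default_rng(4))
        outliers, corrected, _ = presso_outlier(insts, n_sim=300, seed=1)
        assert outliers == []
        assert corrected.beta == pytest.approx(ivw(insts, "fixed").beta, abs=1e-12)

    def _planted_pair_runs(self, signs, n_runs=30, true_beta=0.3):
        for rep in range(n_runs):
            rng = np.random.default_rng(200 + rep)
            insts = _clean_insts(rng, k=22, beta=true_beta)
            for idx, sign in zip((2, 9), signs):
                h = insts[idx]
                insts[idx] = type(h)(snp_id=h.snp_id, bx=h.bx, sex=h.sex,
                                     by=h.by + sign * 10 * h.sey, sey=h.sey,
                                     px=h.px, py=h.py, eaf_x=h.eaf_x,
                                     n_x=h.n_x, n_y=h.n_y)
            outliers, corrected, _ = presso_outlier(insts, n_sim=500, seed=rep)
            uncorrected = ivw(insts, "fixed")
            planted = {insts[2].snp_id, insts[9].snp_id}
            yield planted <= set(outliers), abs(corrected.beta - true_beta), \
                abs(uncorrected.beta - true_beta)

    def test_two_opposite_outliers_flagged_and_error_reduced(self):
        """Opposite-direction outliers are both flagged; their individual
        biases partly cancel in the uncorrected IVW, so the correction gain
        shows in the average error, not in every single run."""
        flagged, err_c, err_u = zip(*self._planted_pair_runs((+1, -1)))
        assert sum(flagged) / len(flagged) >= 0.95
        assert np.mean(err_c) <= np.mean(err_u)

    def test_same_direction_outliers_corrected_toward_truth(self):
        """Same-direction outliers bias the IVW; removal moves the estimate
        toward truth in nearly every run."""
        results = list(self._planted_pair_runs((+1, +1)))
        closer = sum(f and (c <= u) for f, c, u in results)
        assert closer / len(results) >= 0.9


class TestSteiger:
    def test_null_outcome_gives_forward_direction(self):
        insts = make_instruments([0.1, 0.2, 0.15], [0.0, 0.0, 0.0])
        direction, _, r2x, r2y = steiger(insts)
        assert direction == "exposure_to_outcome"
        assert r2y == pytest.approx(0.0)
        assert r2x > 0

    def test_swapping_traits_reverses_direction(self):
        bx, by = [0.2, 0.25, 0.3], [0.02, 0.03, 0.025]
        fwd = make_instruments(bx, by)
        rev = make_instruments(by, bx)
        d1, p1, _, _ = steiger(fwd)
        d2, p2, _, _ = steiger(rev)
        assert d1 == "exposure_to_outcome" and d2 == "outcome_to_exposure"
        assert p1 == pytest.approx(p2)

    def test_scaling_invariance_of_direction(self):
        bx, by = [0.2, 0.25, 0.3], [0.02, 0.03, 0.025]
        d1, _, _, _ = steiger(make_instruments(bx, by))
        d2, _, _, _ = steiger(make_instruments([3 * b for b in bx],
                                               [3 * b for b in by]))
        assert d1 == d2

    def test_missing_eaf_errors_with_snp_list(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.05], eaf=0.3)
        broken = [type(h)(snp_id=h.snp_id, bx=h.bx, sex=h.sex, by=h.by,
                          sey=h.sey, px=h.px, py=h.py, eaf_x=None,
                          n_x=h.n_x, n_y=h.n_y) for h in insts]
        with pytest.raises(ValueError, match="rs1"):
            steiger(broken)


def _est(method="IVW_fixed", beta=0.2, se=0.05, pval=0.01):
    return MREstimate(method=method, beta=beta, se=se, pval=pval, n_snp=5)


def _clean_report(**overrides):
    rep = SensitivityReport(
        q=1.0, q_pval=0.5, egger_intercept=0.001, egger_intercept_pval=0.5,
        presso_global_pval=0.5, steiger_direction="exposure_to_outcome",
    )
    for key, val in overrides.items():
        setattr(rep, key, val)
    return rep


class TestRobustnessGate:
    def test_all_clauses_pass(self):
        ests = [_est(), _est("Egger", 0.25, 0.1, 0.04), _est("WeightedMedian", 0.18)]
        robust, reasons = robustness_gate(ests, _clean_report())
        assert robust and reasons == []

    def test_direction_clause(self):
        ests = [_est(), _est("Egger", -0.001)]
        robust, reasons = robustness_gate(ests, _clean_report())
        assert not robust
        assert any("direction" in r for r in reasons)

    def test_ivw_p_clause(self):
        ests = [_est(pval=0.2), _est("Egger")]
        robust, reasons = robustness_gate(ests, _clean_report())
        assert not robust
        assert any("IVW" in r for r in reasons)

    @pytest.mark.parametrize(
        "overrides,fragment",
        [
            ({"egger_intercept_pval": 0.01}, "Egger intercept"),
            ({"presso_global_pval": 0.02}, "MR-PRESSO"),
            ({"steiger_direction": "outcome_to_exposure"}, "Steiger"),
        ],
    )
    def test_pleiotropy_and_direction_clauses(self, overrides, fragment):
        ests = [_est(), _est("Egger")]
        robust, reasons = robustness_gate(ests, _clean_report(**overrides))
        assert not robust
        assert any(fragment in r for r in reasons)

    def test_monotone_in_clause_repair(self):
        """Fixing the single failing clause flips the verdict to robust."""
        ests = [_est(), _est("Egger")]
        bad = _clean_report(presso_global_pval=0.01)
        assert not robustness_gate(ests, bad)[0]
        fixed = _clean_report(presso_global_pval=0.5)
        assert robustness_gate(ests, fixed)[0]

    def test_requires_an_ivw_estimate(self):
        with pytest.raises(ValueError):
            robustness_gate([_est("Egger")], _clean_report())


def test_sensitivity_report_end_to_end():
    """On clean simulated data the full battery reports a robust forward
    effect in the large majority of replicates (each diagnostic spends its
    nominal 5% type-I budget, so an occasional non-robust verdict is part of
    correct behavior)."""
    from conftest import leg_instruments
    from mrmediate import SimulationTruth, all_estimates, simulate_triplet

    robust_count = 0
    n_reps = 5
    for rep_i in range(n_reps):
        truth = SimulationTruth(seed=40 + rep_i, n_exposure_cohort=20_000,
                                n_mediator_cohort=200, n_outcome_cohort=20_000,
                                n_mediator_snps=0)
        exposure, _, outcome, _ = simulate_triplet(truth)
        insts = leg_instruments(exposure, outcome)
        ests = all_estimates(insts, n_boot=200, seed=1)
        rep = sensitivity_report(insts, ests, n_sim=300, seed=1)
        assert rep.steiger_direction == "exposure_to_outcome"
        assert not math.isnan(rep.q_pval)
        robust_count += rep.robust
    assert robust_count >= 3
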