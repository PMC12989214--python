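import numpy as np
import pytest

from mrmediate import (
    HarmonizedInstrument,
    SimulationTruth,
    VariantAssociation,
    simulate_triplet,
)


def make_variant(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, pval=1e-8,
                 eaf=0.3, chrom="1", pos=1_000_000, n=20_000):
    return VariantAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_instruments(bx, by, sex=None, sey=None, eaf=0.3, n_x=20_000, n_y=20_000):
    """Build a harmonized instrument set from effect arrays."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    sex = np.full_like(bx, 0.01) if sex is None else np.asarray(sex, float)
    sey = np.full_like(bx, 0.01) if sey is None else np.asarray(sey, float)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{i + 1}", bx=float(bx[i]), sex=float(sex[i]),
            by=float(by[i]), sey=float(sey[i]), px=1e-8, py=0.5,
            eaf_x=eaf, n_x=n_x, n_y=n_y,
        )
        for i in range(len(bx))
    ]


def leg_instruments(stats_x, stats_y, p_threshold=1e-5):
    """Harmonize one MR leg and keep instruments significant for its exposure."""
    from mrmediate import harmonize

    insts = harmonize(stats_x, stats_y)
    return [h for h in insts if h.px < p_threshold]


@pytest.fixture(scope="session")
def chain_triplet():
    """One simulated exposure->mediator->outcome triplet at default settings."""
    truth = SimulationTruth(seed=7)
    exposure, mediator, outcome, ld = simulate_triplet(truth)
    return truth, exposure, mediator, outcome, ld


@pytest.fixture(scope="session")
def small_triplet():
    """A faster triplet (20k per cohort) for tests that only need signal."""
    truth = SimulationTruth(
        seed=11, n_exposure_cohort=20_000, n_mediator_cohort=20_000,
        n_outcome_cohort=20_000,
    )
    exposure, mediator, outcome, ld = simulate_triplet(truth)
    return truth, exposure, mediator, outcome, ld
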