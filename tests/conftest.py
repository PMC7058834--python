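import numpy as np
import pytest

from cpgmr.sumstats import AssociationRecord, HarmonizedSet, LDMatrix


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.02,
    **kwargs,
):
    return AssociationRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        **kwargs,
    )


def make_harmonized(beta_exp, se_exp, beta_out, se_out, n_exp=846, n_out=50_000):
    beta_exp = np.asarray(beta_exp, dtype=float)
    return HarmonizedSet(
        snps=[f"rs{i + 1}" for i in range(len(beta_exp))],
        beta_exposure=beta_exp,
        se_exposure=np.asarray(se_exp, dtype=float),
        beta_outcome=np.asarray(beta_out, dtype=float),
        se_outcome=np.asarray(se_out, dtype=float),
        n_exposure=n_exp,
        n_outcome=n_out,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20200220)


@pytest.fixture
def toy_harmonized():
    """Six instruments with unequal strengths and outcome precisions."""
    return make_harmonized(
        beta_exp=[0.45, 0.30, 0.62, 0.25, 0.51, 0.38],
        se_exp=[0.05, 0.04, 0.06, 0.05, 0.04, 0.05],
        beta_out=[-0.040, -0.022, -0.061, -0.018, -0.050, -0.035],
        se_out=[0.008, 0.012, 0.007, 0.015, 0.009, 0.011],
    )


@pytest.fixture
def identity_ld():
    def _build(snps):
        return LDMatrix(tuple(snps), np.eye(len(snps)))

    return _build
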