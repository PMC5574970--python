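import numpy as np
import pandas as pd
import pytest

from ivmr import InstrumentSet, SimulationTruth, harmonize, paper_like, simulate


def make_associations(snp_ids, alleles, betas, ses, eafs=None, pvals=None):
    """Build a canonical association frame from parallel lists."""
    n = len(snp_ids)
    return pd.DataFrame(
        dict(
            snp_id=snp_ids,
            effect_allele=[a[0] for a in alleles],
            other_allele=[a[1] for a in alleles],
            eaf=eafs if eafs is not None else [np.nan] * n,
            beta=betas,
            se=ses,
            pvalue=pvals if pvals is not None else [np.nan] * n,
        )
    )


@pytest.fixture(scope="session")
def paper_like_dataset():
    """One paper-like synthetic dataset (122 instruments, balanced pleiotropy)."""
    return simulate(paper_like(seed=11))


@pytest.fixture(scope="session")
def paper_like_instruments(paper_like_dataset):
    iset, _ = harmonize(paper_like_dataset.exposure, paper_like_dataset.outcome)
    return iset


@pytest.fixture
def small_instruments():
    """A tiny hand-made instrument set for exact-arithmetic checks."""
    table = pd.DataFrame(
        dict(
            snp_id=["rs1", "rs2", "rs3", "rs4"],
            bx=[0.10, 0.08, 0.05, 0.12],
            sx=[0.01, 0.01, 0.008, 0.012],
            by=[0.004, 0.0035, 0.0018, 0.0055],
            sy=[0.003, 0.0028, 0.0025, 0.0031],
            eaf=[0.3, 0.2, 0.45, 0.15],
        )
    )
    return InstrumentSet(table)


def strong_instrument_truth(seed, **overrides):
    """No-pleiotropy, strong-instrument generating conditions."""
    base = dict(
        n_snps=100,
        beta_true=0.05,
        pleiotropy_model="none",
        gamma_sd=0.09,
        seed=seed,
    )
    base.update(overrides)
    return SimulationTruth(**base)
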