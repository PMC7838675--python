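import numpy as np
import pytest

from triogxe.trio_data import SnpMeta, TrioDataset


def make_dataset(
    g_child,
    g_mother,
    g_father,
    exposure=None,
    sra=None,
    n_snps=None,
    sex=None,
):
    """Small in-memory TrioDataset from genotype lists."""
    gc = np.atleast_2d(np.asarray(g_child))
    gm = np.atleast_2d(np.asarray(g_mother))
    gf = np.atleast_2d(np.asarray(g_father))
    n, m = gc.shape
    snps = [
        SnpMeta(f"snp{j}", "1", 100 * (j + 1), "A", "C", minor_allele="b")
        for j in range(m)
    ]
    if exposure is None:
        exposure = np.zeros(n)
    if sra is None:
        sra = np.array(["European"] * n, dtype=object)
    return TrioDataset(
        [f"t{i}" for i in range(n)],
        snps,
        gc,
        gm,
        gf,
        np.asarray(exposure, dtype=float),
        np.asarray(sra, dtype=object),
        child_sex=sex,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_cohort():
    """A deterministic 500-trio structured cohort shared across tests."""
    from triogxe.synthetic_cohort import simulate_cohort, spurious_gxe_scenario

    truth, structure = spurious_gxe_scenario(n_trios=500, seed=99)
    return simulate_cohort(truth, structure)
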