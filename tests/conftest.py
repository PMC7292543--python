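import numpy as np
import pandas as pd
import pytest

from fnlqtl.simulate import (
    BulkConfig,
    CrossConfig,
    TraitModel,
    make_bulks,
    simulate_f2,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cross():
    """A light F2 cross shared by fast tests."""
    cross = CrossConfig(n_markers=40, n_f2=300, chrom_length_bp=20_000_000,
                        cm_per_mb=5.0, seed=11)
    markers = cross.marker_table()
    genotypes = simulate_f2(cross)
    return cross, markers, genotypes


@pytest.fixture(scope="session")
def default_trait():
    return TraitModel()


@pytest.fixture(scope="session")
def study_cross():
    """The default study-scale cross: 1231 F2, 2000 markers, QTL at 12 Mb."""
    cross = CrossConfig(seed=7)
    markers = cross.marker_table()
    genotypes = simulate_f2(cross)
    trait = TraitModel()
    phenotypes = simulate_phenotypes(genotypes, trait, markers, seed=7)
    return cross, markers, genotypes, trait, phenotypes


def make_counts_table(seed=0, n_sites=200, qtl=False):
    """Small oriented bulk-counts table used by qtlseq unit tests."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), n_sites, replace=False))
    f_ln = np.full(n_sites, 0.5)
    f_sn = np.full(n_sites, 0.5)
    if qtl:
        f_ln[n_sites // 2:] = 0.9
        f_sn[n_sites // 2:] = 0.1
    dl = rng.poisson(61, n_sites)
    ds = rng.poisson(52, n_sites)
    p_ln = rng.binomial(dl, f_ln)
    p_sn = rng.binomial(ds, f_sn)
    return pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "p_ln": p_ln, "m_ln": dl - p_ln,
        "p_sn": p_sn, "m_sn": ds - p_sn,
    })
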