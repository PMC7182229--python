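"""Shared fixtures: tiny hand-built matrices and simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from snpqc import (
    GenotypeMatrix,
    LocusInfo,
    SampleInfo,
    SimConfig,
    simulate_parents,
    simulate_replicates,
    HOM_REF,
    HOM_ALT,
    HET,
    MISSING,
)

R, A, H, M = HOM_REF, HOM_ALT, HET, MISSING


def make_gm(calls, chroms=None, positions=None, sample_ids=None, populations=None):
    """Build a GenotypeMatrix from a nested list of codes (loci x samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_samples = calls.shape
    loci = [
        LocusInfo(
            allele_id=f"L{i + 1:03d}",
            chromosome=None if chroms is None else chroms[i],
            position=None if positions is None else positions[i],
        )
        for i in range(n_loci)
    ]
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(n_samples)]
    samples = [
        SampleInfo(
            sample_id=sid,
            population=None if populations is None else populations[j],
        )
        for j, sid in enumerate(sample_ids)
    ]
    return GenotypeMatrix(loci=loci, samples=samples, calls=calls)


@pytest.fixture
def toy_gm():
    """3 loci x 2 samples with one missing cell."""
    return make_gm(
        [[R, A], [H, H], [A, M]],
        chroms=["Chr01", "Chr01", "Chr02"],
        positions=[100, 5000, 42],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240424)


@pytest.fixture(scope="session")
def structured_parents():
    """4 populations x 50 samples, diploid sampling so the diploid
    estimators are unbiased; used by several statistics tests."""
    cfg = SimConfig(
        populations=tuple((p, 50) for p in ("P1", "P2", "P3", "P4")),
        loci_per_chromosome=20,
        target_fst=0.10,
        ploidy=2,
        missing_rate=0.03,
        seed=11,
    )
    gm, truth = simulate_parents(cfg)
    return gm, truth, cfg


@pytest.fixture(scope="session")
def replicate_dataset():
    """40 genotypes x 3 stages with 20% injected mislabeling."""
    cfg = SimConfig(
        populations=(("G", 40),),
        loci_per_chromosome=20,
        target_fst=0.30,
        ploidy=6,
        missing_rate=0.02,
        genotype_error_rate=0.005,
        mislabel_fraction=0.20,
        seed=5,
    )
    base, _ = simulate_parents(cfg)
    gm, truth = simulate_replicates(base, cfg)
    return gm, truth


def random_calls(rng, n_loci, n_samples, missing_rate=0.1):
    codes = rng.choice([R, A, H], size=(n_loci, n_samples))
    mask = rng.random((n_loci, n_samples)) < missing_rate
    codes[mask] = M
    return codes.astype(np.int8)
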