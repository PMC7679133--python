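import numpy as np
import pytest

from hhquant import CH_CI, CH_PTC, AlignedProfileSet, align_profiles, simulate_disc_set
from hhquant.simulate import GENOTYPES, SimParams


@pytest.fixture(scope="session")
def clean_params() -> SimParams:
    """Default kinetic parameters with all noise and jitter off."""
    return SimParams(noise_sd_frac=0.0, offset_sd=0.0, scale_sd_frac=0.0)


@pytest.fixture(scope="session")
def clean_additive_params() -> SimParams:
    return SimParams(mode="additive", noise_sd_frac=0.0, offset_sd=0.0, scale_sd_frac=0.0)


def aligned_genotypes(params: SimParams, names, n_discs: int = 3, seed: int = 0):
    """Simulate and align one disc set per genotype, sharing one RNG stream."""
    rng = np.random.default_rng(seed)
    return {
        name: align_profiles(simulate_disc_set(params, GENOTYPES[name], n_discs, rng=rng))
        for name in names
    }


@pytest.fixture(scope="session")
def clean_aligned(clean_params):
    return aligned_genotypes(clean_params, ["WT", "S849A", "P13A"])


@pytest.fixture(scope="session")
def clean_additive_aligned(clean_additive_params):
    return aligned_genotypes(clean_additive_params, ["WT", "S849A", "P13A"])


def make_aligned_set(
    grid,
    mean_ci,
    genotype: str = "synthetic",
    mean_ptc=None,
    sem_ci=None,
) -> AlignedProfileSet:
    """Hand-build a minimal aligned set for arithmetic-level tests."""
    grid = np.asarray(grid, dtype=float)
    mean = {CH_CI: np.asarray(mean_ci, dtype=float)}
    sem = {CH_CI: np.asarray(sem_ci, dtype=float) if sem_ci is not None else np.zeros_like(grid)}
    if mean_ptc is not None:
        mean[CH_PTC] = np.asarray(mean_ptc, dtype=float)
        sem[CH_PTC] = np.zeros_like(grid)
    return AlignedProfileSet(
        genotype=genotype,
        grid=grid,
        per_disc={},
        mean=mean,
        sem=sem,
        n=np.full(grid.shape, 3, dtype=int),
    )
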