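import numpy as np
import pytest

from msapdiv import (
    BinaryMarkerMatrix,
    Distribution,
    MarkerType,
    SampleMeta,
    SynthConfig,
    simulate_dataset,
)
from msapdiv.calibration import synthetic_diversity_table

#: desk-scale version of the paired 7-genus design used across the suite
DESK = dict(
    n_genera=7,
    populations_per_species=3,
    individuals_per_population=12,
    n_aflp_loci=120,
    n_msap_epiloci=100,
)


def build_matrix(
    values,
    populations=None,
    marker_type=MarkerType.AFLP,
    species="sp1",
    distribution=Distribution.RESTRICTED,
    replicate_of=None,
):
    """Construct a small matrix from a 2-D 0/1 array with minimal metadata."""
    values = np.asarray(values, dtype=np.uint8)
    k, n = values.shape
    populations = populations or ["pop1"] * k
    replicate_of = replicate_of or [None] * k
    samples = [
        SampleMeta(
            individual_id=f"ind{i + 1:02d}",
            genus="g1",
            species=species,
            population=populations[i],
            distribution=distribution,
            replicate_of=replicate_of[i],
        )
        for i in range(k)
    ]
    return BinaryMarkerMatrix(
        samples=samples,
        locus_ids=[f"L{j + 1:03d}" for j in range(n)],
        values=values,
        marker_type=marker_type,
    )


@pytest.fixture
def matrix_factory():
    return build_matrix


@pytest.fixture(scope="session")
def desk_dataset():
    """One seeded synthetic dataset at desk scale, with replicates."""
    return simulate_dataset(SynthConfig(seed=42, replicate_fraction=0.1, **DESK))


@pytest.fixture(scope="session")
def desk_table():
    """Diversity table from a seeded desk-scale null dataset (42 pops x 3)."""
    return synthetic_diversity_table(
        SynthConfig(seed=424, replicate_fraction=0.0, **DESK)
    )
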