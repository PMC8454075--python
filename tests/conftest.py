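import numpy as np
import pandas as pd
import pytest

from umscan import (
    CohortSpec,
    IntensityMatrices,
    ProbePatternSpec,
    simulate_cohort,
    simulate_probe,
)


@pytest.fixture(scope="session")
def cohort852():
    """Benchmark-scale twin cohort: 426 pairs, 852 samples."""
    return simulate_cohort(CohortSpec(n_pairs=426, seed=1))


@pytest.fixture(scope="session")
def cohort400():
    """400-pair cohort used for allele-frequency and noise-control checks."""
    return simulate_cohort(CohortSpec(n_pairs=400, seed=3))


def probe_rows_to_intensities(probes, sample_ids) -> IntensityMatrices:
    """Stack SimulatedProbe rows into an IntensityMatrices container."""
    idx = pd.Index([p.probe_id for p in probes], name="probe_id")
    cols = pd.Index(sample_ids, name="sample_id")
    stack = lambda attr: pd.DataFrame(
        np.vstack([getattr(p, attr) for p in probes]), index=idx, columns=cols
    )
    return IntensityMatrices(
        U=stack("u"), M=stack("m"), sigma_U=stack("sigma_u"), sigma_M=stack("sigma_m")
    )


def simulate_probe_matrix(pattern, cohort, factors, seed, n_probes=1, **kw):
    """n_probes simulated rows of one pattern as an IntensityMatrices."""
    rng = np.random.default_rng(seed)
    spec = ProbePatternSpec(pattern=pattern, **kw)
    probes = [
        simulate_probe(spec, cohort, factors, rng, probe_id=f"cg{i:05d}")
        for i in range(n_probes)
    ]
    return probe_rows_to_intensities(probes, cohort.sample_ids), probes
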