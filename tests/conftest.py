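import warnings

import numpy as np
import pytest

from cffrag.synthetic_cohort import build_reference, generate_cohort

# generator warnings (fragmentation-only signal, empty filters) are expected
# in several simulations and would otherwise clutter -W error runs
warnings.filterwarnings("ignore", message=".*fragmentation-only signal.*")


@pytest.fixture(scope="session")
def toy_genome():
    """Two 1 Mb contigs; enough for IO, end-motif and binning tests."""
    return build_reference(n_contigs=2, contig_length=1_000_000, seed=11)


@pytest.fixture(scope="session")
def tf_genome():
    """One 100 Mb contig (200 bins) for tumor-fraction recovery runs."""
    return build_reference(n_contigs=1, contig_length=100_000_000, seed=1)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Small end-to-end synthetic cohort shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    info = generate_cohort(out, n_healthy=6, n_cancer=6, samples_per_subject=2,
                           depth=300, seed=11)
    return info


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
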