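import pytest
from hypothesis import settings

import nitrocodon as nc

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code():
    return nc.STANDARD_CODE


@pytest.fixture(scope="session")
def mollicute_code():
    return nc.MOLLICUTE_CODE


def make_table(sel_n=0.0, mut_m=1.0, variant="selection_mutation", code=nc.STANDARD_CODE):
    """Model codon-probability table at given parameters."""
    return nc.codon_probs(
        nc.ModelParams(variant=variant, sel_n=sel_n, mut_m=mut_m), code=code
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny three-group synthetic study reused across pipeline tests."""
    truth = nc.SyntheticTruth(
        n_orthogroups=30, n_species_per_group=3, mean_gene_length=120, seed=42
    )
    return nc.generate_synthetic_dataset(truth)
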