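import numpy as np
import pytest

from refbias.synth import (
    make_diploid_sample,
    make_reference,
    make_variant_panel,
)
from refbias.vargraph import build_graph


@pytest.fixture(scope="session")
def small_ref():
    return make_reference({"chr1": 30_000}, gc_fraction=0.41, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_ref):
    return make_variant_panel(
        small_ref, n_snps=40, n_indels=10, indel_len_max=18, min_spacing=150, seed=5
    )


@pytest.fixture(scope="session")
def small_graph(small_ref, small_panel):
    return build_graph(small_ref, small_panel)


@pytest.fixture(scope="session")
def small_diploid(small_ref, small_panel):
    return make_diploid_sample(small_ref, small_panel, het_rate=0.5, hom_alt_rate=0.25, seed=3)
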