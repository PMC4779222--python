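import numpy as np
import pandas as pd
import pytest

from gutdiverge.io_formats import ExpressionTable
from gutdiverge.simulate import SimConfig, generate


def make_expression_table(
    gene_ids,
    count_tissue,
    count_whole,
    length_bp=1000,
    library_size_tissue=1_000_000,
    library_size_whole=1_000_000,
    species="toy",
):
    n = len(gene_ids)
    lengths = [length_bp] * n if np.isscalar(length_bp) else list(length_bp)
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "length_bp": lengths,
            "count_tissue": list(count_tissue),
            "count_whole": list(count_whole),
        }
    )
    return ExpressionTable(
        species_label=species,
        data=df,
        library_size_tissue=library_size_tissue,
        library_size_whole=library_size_whole,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic two-species bundle shared across tests."""
    return generate(SimConfig(size_factor=0.1, seed=1))


@pytest.fixture(scope="session")
def desk_bundle():
    """Quarter-scale default bundle: the desk-scale study conditions."""
    return generate(SimConfig(size_factor=0.25, seed=1))
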