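import pytest

from mirnod.interactions import InteractionRecord, build_union_db
from mirnod.synthetic import write_bundle


def make_records(pairs, source, evidence):
    return [InteractionRecord(m, g, source, evidence) for m, g in pairs]


@pytest.fixture
def toy_db():
    """5 edges, 2 miRNAs, 4 genes; g2 is shared, the rest exclusive."""
    validated = [
        make_records(
            [("hsa-mir-1", "G1"), ("hsa-mir-1", "G2"), ("hsa-mir-1", "G3")],
            "vsrc", "validated",
        ),
        make_records([("hsa-mir-2", "G2"), ("hsa-mir-2", "G4")], "vsrc2", "validated"),
    ]
    return build_union_db(validated, [])


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Scaled-down but complete synthetic input bundle (shared across tests)."""
    out = tmp_path_factory.mktemp("bundle")
    truth = write_bundle(
        out,
        seed=11,
        n_mirnas_db=80,
        n_genes=1200,
        n_mirnas_expr=60,
        mean_targets=12.0,
        exclusive_fraction=0.05,
        ppi_mean_degree=6.0,
        n_gene_sets=20,
        gene_set_size_range=(10, 60),
    )
    return out, truth
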