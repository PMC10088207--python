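import numpy as np
import pytest

import porebench as pb


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """A small simulated benchmark dataset shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    paths = pb.make_fixture_dataset(
        out,
        n_species=3,
        genome_length=20_000,
        n_reads=60,
        model=pb.ErrorModel(homopolymer_distortion=0.3),
        seed=7,
    )
    return paths


@pytest.fixture(scope="session")
def planted_cluster_genomes():
    """12 synthetic genomes in 3 composition clusters (GC 0.30/0.50/0.70)."""
    genomes = {}
    cluster_of = {}
    rng = np.random.default_rng(11)
    for i in range(12):
        cluster = i % 3
        gc = [0.30, 0.50, 0.70][cluster]
        name = f"sp{i:02d}"
        ref = pb.generate_reference(
            30_000, gc_fraction=gc, seed=int(rng.integers(2**31)), ref_id=name
        )
        genomes[name] = [ref.sequence]
        cluster_of[name] = cluster
    return genomes, cluster_of


def make_alignment(ops, query, ref, **kw):
    return pb.Alignment(
        read_id=kw.pop("read_id", "r"),
        ref_id=kw.pop("ref_id", "ref"),
        ops=ops,
        query_aligned=query,
        ref_aligned=ref,
        **kw,
    )
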