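"""Shared fixtures: small synthetic datasets generated once per session."""

import logging

import pytest

from nlrmeth import SyntheticConfig, generate_dataset

logging.disable(logging.WARNING)


def small_config(**overrides) -> SyntheticConfig:
    """A fast one-species study: 10 + 10 genes on a 240 kb chromosome."""
    base = dict(
        n_species=1,
        chrom_length=240_000,
        n_genes_typeI=10,
        n_genes_typeII=10,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_species(small_dataset):
    return small_dataset.species[0]


@pytest.fixture(scope="session")
def small_cytosine_records(small_species):
    """The small species' methylome as parsed-style records."""
    from nlrmeth import CytosineRecord
    from nlrmeth.synthetic_data import CONTEXT_NAMES

    cyt = small_species.cytosines
    return [
        CytosineRecord(
            chrom=cyt.chrom,
            pos=int(cyt.pos[i]),
            strand="+" if cyt.strand[i] == 0 else "-",
            m=int(cyt.m[i]),
            u=int(cyt.u[i]),
            context=CONTEXT_NAMES[cyt.context[i]],
        )
        for i in range(len(cyt))
    ]


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """A two-species dataset written to disk for file-based pipeline tests."""
    from nlrmeth import write_dataset

    ds = generate_dataset(small_config(n_species=2), seed=13)
    out = tmp_path_factory.mktemp("dataset")
    write_dataset(ds, out)
    return out
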