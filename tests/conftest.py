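import numpy as np
import pytest

from paleoallom.datasets import load_dinosaur_taxa, reference_model_sets
from paleoallom.records import ExtantSpeciesRecord, TraitDataset
from paleoallom.simulate import GroupLawSpec, generate_extant_dataset


@pytest.fixture(scope="session")
def dinosaur_taxa():
    return load_dinosaur_taxa()


@pytest.fixture(scope="session")
def recovered_models():
    """CM/ACM model sets recovered from published per-taxon estimates."""
    return reference_model_sets()


@pytest.fixture
def tiny_dataset():
    """Five species, two groups (3 birds, 2 crocodiles), hand-checkable."""
    records = [
        ExtantSpeciesRecord("sp1", "bird", BM=1.0, EM=0.05, CS=4, CY=2),
        ExtantSpeciesRecord("sp2", "bird", BM=2.0, EM=0.08, CS=5, CY=1),
        ExtantSpeciesRecord("sp3", "bird", BM=4.0, EM=0.12, CS=6, CY=1),
        ExtantSpeciesRecord("sp4", "crocodile", BM=100.0, EM=0.07, CS=40, CY=1),
        ExtantSpeciesRecord("sp5", "crocodile", BM=300.0, EM=0.09, CS=45, CY=1),
    ]
    return TraitDataset(records)


def make_group(
    group="bird",
    trait="EM",
    c=0.01,
    b=0.7,
    sigma=0.1,
    n=50,
    bm_range=(1.0, 1000.0),
):
    return GroupLawSpec(
        group_label=group,
        trait=trait,
        c_true=c,
        b_true=b,
        sigma_log10=sigma,
        n=n,
        BM_range=bm_range,
    )


@pytest.fixture
def law_dataset():
    """Single-group dataset drawn from a known power law (seeded)."""
    spec = make_group(n=100, sigma=0.15)
    return spec, generate_extant_dataset([spec], seed=42)
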