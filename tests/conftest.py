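import pytest

import metabolink as ml
from metabolink import io as mio


def bundle_to_dataset(bundle: ml.FixtureBundle) -> mio.Dataset:
    return mio.Dataset(
        compounds=[*bundle.drugs, *bundle.metabolites],
        signatures=bundle.signatures,
        microbes=bundle.microbes,
        pathway_annotations=bundle.pathway_annotations,
        drug_annotations=bundle.drug_annotations,
    )


@pytest.fixture(scope="session")
def small_bundle() -> ml.FixtureBundle:
    """Small deterministic universe shared by read-only tests."""
    return ml.generate_bundle(
        ml.FixtureConfig(seed=7, n_drugs=12, n_metabolites=20, n_microbes=6,
                         n_genes=60, frac_identical=0.2, frac_analog=0.3)
    )


@pytest.fixture(scope="session")
def small_dataset(small_bundle) -> mio.Dataset:
    return bundle_to_dataset(small_bundle)


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    pairs, summary = ml.score_all_pairs(
        small_dataset.metabolites, small_dataset.drugs, small_dataset.signatures
    )
    return pairs, summary
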