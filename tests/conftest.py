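import pytest

from genelinker.fixtures import (build_profile_library, default_families,
                                 generate_dataset, standard_plant_specs)
from genelinker.pipeline import run_pipeline
from genelinker.presets import load_preset

SEED = 20260905
N_GENOMES = 20


@pytest.fixture(scope="session")
def families():
    return default_families(SEED)


@pytest.fixture(scope="session")
def ta_requirements():
    return load_preset("TA").requirements


@pytest.fixture(scope="session")
def dataset(families):
    """20 genomes, one plant of every verdict class per genome (340 plants)."""
    return generate_dataset(N_GENOMES, standard_plant_specs(N_GENOMES),
                            families, seed=SEED)


@pytest.fixture(scope="session")
def profile_library(families, tmp_path_factory):
    return build_profile_library(families, tmp_path_factory.mktemp("profiles"),
                                 hit_family_names=["fam100", "famS", "famL"])


@pytest.fixture(scope="session")
def hit_only_library(families, tmp_path_factory):
    """A single-profile library (fam100 only)."""
    return build_profile_library(families,
                                 tmp_path_factory.mktemp("profiles_one"),
                                 hit_family_names=["fam100"])


@pytest.fixture(scope="session")
def pipeline_result(dataset, profile_library, ta_requirements):
    preset = load_preset("TA")
    return run_pipeline(dataset.genomes, profile_library, ta_requirements,
                        min_bitscore=preset.min_bitscore)
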