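import pytest

import ehraudit as ea


@pytest.fixture(scope="session")
def benchmark():
    return ea.load_benchmarks()


@pytest.fixture(scope="session")
def registry():
    return ea.default_disease_registry()


@pytest.fixture(scope="session")
def bank():
    return ea.default_prompt_bank()


@pytest.fixture(scope="session")
def model_meta():
    return ea.load_model_meta()


@pytest.fixture(scope="session")
def gender_schema():
    return ea.AttributeSchema(categories={"gender": ("male", "female")})


def make_config(disease="Lupus", **kwargs):
    """Small two-attribute generation config used across tests."""
    defaults = dict(
        disease=disease,
        model_label="test-model",
        n_records=400,
        p_irrelevant=0.1,
        p_missing={"gender": 0.05, "race": 0.1},
        category_dist={
            "gender": {"female": 0.7, "male": 0.3},
            "race": {"White": 0.5, "Black": 0.2, "Hispanic": 0.2, "Asian": 0.1},
        },
        seed=42,
    )
    defaults.update(kwargs)
    return ea.GenerationConfig(**defaults)


@pytest.fixture()
def small_corpus():
    cfg = make_config()
    records, truths = ea.generate_corpus(cfg)
    return cfg, records, truths
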