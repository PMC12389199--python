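import pytest

from pgxeval import (
    build_paper_fixture,
    load_allele_definitions,
    load_knowledge_base,
    run_pipeline,
)


@pytest.fixture(scope="session")
def defs():
    return load_allele_definitions()


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_cohort, kb):
    """Full pipeline run over the reconstructed study cohort."""
    return run_pipeline(fixture_cohort, kb)
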