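import pytest

from stratomics import RunConfig, load_knowledge_base, run_pipeline
from stratomics.synthetic import CaseSpec, CohortSpec, generate_case, generate_cohort


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def cohort(kb):
    """Default labeled 4-subtype reference cohort (30 samples per subtype)."""
    return generate_cohort(CohortSpec(seed=7), kb)


def _case_fixture(tmp_path_factory, kb, template, seed):
    outdir = tmp_path_factory.mktemp(template)
    manifest = generate_case(CaseSpec(template, seed=seed), outdir, kb=kb)
    return manifest


@pytest.fixture(scope="session")
def case2(tmp_path_factory, kb):
    return _case_fixture(tmp_path_factory, kb, "case2_tamoxifen", seed=1)


@pytest.fixture(scope="session")
def case3(tmp_path_factory, kb):
    return _case_fixture(tmp_path_factory, kb, "case3_immuno", seed=2)


def _run_case(manifest, cohort, **overrides):
    files = manifest["files"]
    config = RunConfig(
        clinical=files["clinical"], expression=files["expression"],
        somatic_vcf=files["somatic_vcf"], germline_vcf=files["germline_vcf"],
        seg=files["seg"], methylation=files["methylation"],
        seed=3, n_perm=300, **overrides)
    return run_pipeline(config, cohort=cohort)


@pytest.fixture(scope="session")
def case2_report(case2, cohort):
    return _run_case(case2, cohort)


@pytest.fixture(scope="session")
def case3_report(case3, cohort):
    return _run_case(case3, cohort)
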