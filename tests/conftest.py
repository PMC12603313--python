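import pytest

from auxinmir.config import PipelineConfig
from auxinmir.pipeline import RunPaths, run_all
from auxinmir.references import load_references
from auxinmir.synthetic import SynthConfig, gen_bundle

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def refs():
    return load_references()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One synthetic input bundle shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    truth = gen_bundle(SynthConfig(), BUNDLE_SEED, out)
    return out, truth


@pytest.fixture(scope="session")
def run_output(bundle_dir, cfg, tmp_path_factory):
    """One full pipeline run on the shared bundle."""
    bdir, truth = bundle_dir
    out = tmp_path_factory.mktemp("run")
    paths = RunPaths(
        transcripts=str(bdir / "transcripts.fasta"),
        mirnas=str(bdir / "mirnas.fasta"),
        degradome=str(bdir / "degradome.tsv"),
        mirna_rpm=str(bdir / "mirna_rpm.tsv"),
        transcript_fpkm=str(bdir / "transcript_fpkm.tsv"),
        qpcr=str(bdir / "qpcr.tsv"),
    )
    report = run_all(paths, cfg, out)
    return out, truth, report
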