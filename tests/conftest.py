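import json

import pytest

from wikiread.cli import RunConfig, run_pipeline
from wikiread.synth import CorpusSpec, generate_snapshot


@pytest.fixture(scope="session")
def small_spec() -> CorpusSpec:
    """A quarter-scale corpus with short articles for fast structural tests."""
    return CorpusSpec().scaled(articles=0.25, sentences=0.3, seed=11)


@pytest.fixture(scope="session")
def small_snapshot(tmp_path_factory, small_spec):
    out = tmp_path_factory.mktemp("snapshot")
    generate_snapshot(small_spec, out)
    return out


@pytest.fixture(scope="session")
def small_manifest(small_snapshot):
    with open(small_snapshot / "manifest.json", encoding="utf-8") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_pipeline(small_snapshot, tmp_path_factory):
    out = tmp_path_factory.mktemp("reports")
    return run_pipeline(RunConfig(snapshot_dir=small_snapshot, out_dir=out))
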