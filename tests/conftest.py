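import json
from pathlib import Path

import pytest
import yaml

from momnet.pipeline import PipelineConfig, run_pipeline
from momnet.synthetic_data import SERIAL_GROUP, SERIAL_KIND, SyntheticConfig, generate_bundle


def write_pipeline_config(bundle_dir: Path, **overrides) -> Path:
    """Write a pipeline YAML pointing at a generated bundle directory."""
    config = {
        "gene_sets": "kb.gmt",
        "interactions": "kb.sif",
        "ptm_table": "ptm_quant.tsv",
        "function_map": "function_map.tsv",
        "out_dir": "out",
        "datasets": [
            {
                "path": f"dataset_{serial}.tsv",
                "serial": serial,
                "kind": SERIAL_KIND[serial],
                "group": SERIAL_GROUP[serial],
            }
            for serial in sorted(SERIAL_KIND)
        ],
    }
    config.update(overrides)
    path = bundle_dir / "config.yaml"
    path.write_text(yaml.safe_dump(config), encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    kb, truth = generate_bundle(SyntheticConfig(seed=1), outdir)
    return outdir, kb, truth


@pytest.fixture(scope="session")
def pipeline_run(default_bundle):
    """Full pipeline executed once on the default bundle."""
    outdir, kb, truth = default_bundle
    config_path = write_pipeline_config(outdir)
    report = run_pipeline(PipelineConfig.from_yaml(config_path))
    return outdir / "out", report, truth
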