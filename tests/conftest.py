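import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from immgene import pipeline, synthetic_data as sd


def random_protein(rng: np.random.Generator, n: int) -> str:
    from immgene.io_formats import AA20
    return "".join(rng.choice(list(AA20), size=n))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 4 species, 6 families, 200 background
    proteins per species, zero substitution noise, seed 0."""
    return sd.generate_dataset(sd.default_config(seed=0))


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_run")
    cfg = pipeline.PipelineConfig(
        proteome_paths={sp: "" for sp in default_dataset.proteomes},
        reference_species="refsp", query_set_path="", rules_path="",
        domain_alignment_paths={}, output_dir=str(out), seed=0)
    return pipeline.run_annotate(cfg, dataset=default_dataset)


@pytest.fixture(scope="session")
def default_metrics(default_dataset, default_run):
    return pipeline.verify(default_run.accepted, default_dataset.truth,
                           default_run.copy_numbers)
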