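import pathlib

import pandas as pd
import pytest

from ltscope import report_cli, synthio


@pytest.fixture(scope="session")
def default_collection(tmp_path_factory):
    """The standard 20-genome scenario with ground truth, generated once."""
    root = tmp_path_factory.mktemp("collection")
    spec = synthio.SyntheticSpec.default_scenario(rng_seed=1)
    paths, truth = synthio.generate_collection(spec, root)
    return spec, paths, truth


@pytest.fixture(scope="session")
def pipeline_result(default_collection, tmp_path_factory):
    """Full pipeline run over the default collection."""
    _, paths, _ = default_collection
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = report_cli.PipelineConfig(input_dir=str(paths.root), output_dir=str(out))
    return cfg, report_cli.run_pipeline(cfg)


@pytest.fixture(scope="session")
def truth_partition(default_collection):
    """Ground-truth family partition as a set of frozensets of protein ids."""
    _, _, truth = default_collection
    parts: dict[str, set[str]] = {}
    for prot, fam in truth.family_members.items():
        parts.setdefault(fam, set()).add(prot)
    return parts


@pytest.fixture(scope="session")
def collection_genes(default_collection) -> pd.DataFrame:
    _, paths, _ = default_collection
    return pd.read_csv(paths.genes, sep="\t")


@pytest.fixture(scope="session")
def gene_coords(collection_genes):
    return {
        g: (int(s), int(e))
        for g, s, e in collection_genes[["gene_id", "start", "end"]].itertuples(index=False)
    }
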