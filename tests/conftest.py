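import numpy as np
import pandas as pd
import pytest

import embryostage as es


def make_sheet(sample_ids, stages, condition="invivo", species="pig", stage_order=None):
    reps = {}
    rows = []
    for sid, st in zip(sample_ids, stages):
        reps[st] = reps.get(st, 0) + 1
        rows.append((sid, st, condition, species, reps[st]))
    return es.SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "stage", "condition", "species", "replicate"]
        ),
        stage_order=tuple(stage_order) if stage_order else es.DEFAULT_STAGE_ORDER,
    )


def make_counts(array, gene_ids=None, sample_ids=None, stages=None, **kw):
    array = np.asarray(array)
    n_genes, n_samples = array.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    stages = stages or ["oocyte"] * n_samples
    sheet = make_sheet(sample_ids, stages, **kw)
    return es.CountMatrix(pd.DataFrame(array, index=gene_ids, columns=sample_ids), sheet)


@pytest.fixture
def two_gene_counts():
    return make_counts([[5, 0], [3, 2]], gene_ids=["ga", "gb"], sample_ids=["A", "B"])


@pytest.fixture
def annotation():
    def build(gene_ids, lengths=None):
        lengths = lengths if lengths is not None else [1000] * len(gene_ids)
        return es.GeneAnnotation(pd.Series(lengths, index=gene_ids))

    return build


@pytest.fixture(scope="session")
def default_study():
    """One modest simulated default study shared by read-only tests."""
    return es.generate(es.GeneratorConfig(n_genes=2000, seed=42))
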