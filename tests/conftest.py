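import numpy as np
import pytest

from transqtl.pipeline import CohortData, run_discovery
from transqtl.simulate import (
    build_panel,
    default_config,
    plant_crossmap_artifact,
    simulate_expression,
    simulate_genotypes,
)

# canonical demo seed used across the suite
STUDY_SEED = 2026


def make_cohorts(config, expression, genotypes):
    return [
        CohortData(
            c,
            genotypes[c],
            expression[c],
            (np.arange(genotypes[c].n_samples) % 2).astype(float),
        )
        for c in config.cohort_ids
    ]


@pytest.fixture(scope="session")
def default_study():
    """The packaged desk-scale study: planted trans network plus a
    contamination locus, three cohorts of 200 samples."""
    config = default_config(STUDY_SEED)
    genotypes = simulate_genotypes(config)
    expression, truth = simulate_expression(genotypes, config)
    expression, crossmap = plant_crossmap_artifact(expression, config)
    _, genes = build_panel(config)
    annotation = {g.gene_id: g for g in genes}
    return {
        "config": config,
        "genotypes": genotypes,
        "expression": expression,
        "truth": truth,
        "crossmap": crossmap,
        "annotation": annotation,
        "cohorts": make_cohorts(config, expression, genotypes),
    }


@pytest.fixture(scope="session")
def discovery_filtered(default_study):
    return run_discovery(
        default_study["cohorts"],
        default_study["annotation"],
        default_study["crossmap"],
    )


@pytest.fixture(scope="session")
def discovery_unfiltered(default_study):
    return run_discovery(
        default_study["cohorts"],
        default_study["annotation"],
        None,
    )
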