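"""Shared fixtures: worked toy tree, small synthetic tables."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from floranat import (
    PhyloContext,
    SpeciesTable,
    SyntheticConfig,
    default_config,
    simulate_table,
    standardize,
)

WORKED_NEWICK = "((A:1,N1:1):1,(N2:1,N3:1):1);"


@pytest.fixture
def worked_ctx():
    """4-tip tree with one alien (A) and three natives; all pairwise
    distances computable by hand."""
    tree = dendropy.Tree.get(data=WORKED_NEWICK, schema="newick")
    return PhyloContext(
        tree=tree,
        natives=frozenset({"N1", "N2", "N3"}),
        aliens=frozenset({"A"}),
        native_occurrence={"N1": 1, "N2": 1, "N3": 1},
    )


@pytest.fixture
def worked_ctx_weighted():
    tree = dendropy.Tree.get(data=WORKED_NEWICK, schema="newick")
    return PhyloContext(
        tree=tree,
        natives=frozenset({"N1", "N2", "N3"}),
        aliens=frozenset({"A"}),
        native_occurrence={"N1": 18, "N2": 1, "N3": 1},
    )


def tiny_config(seed=0, n=1400, a=0.4, b=0.3, c=1.6, theta=1.0, **kw):
    """Single continuous exposure, no tree: the minimal mediation design."""
    return SyntheticConfig(
        n_species=n,
        traits={"x": (0.0, 1.0)},
        mediator_coef={"x": a},
        outcome_coef={"x": b},
        mediator_intercept=5.0,
        theta=theta,
        outcome_intercept=-0.6,
        mediator_effect=c,
        seed=seed,
        **kw,
    )


@pytest.fixture
def tiny_table():
    table, truth = simulate_table(tiny_config(seed=11), n_oracle=50_000)
    tstd, _ = standardize(table, ["x"], {"x": "log10"})
    return tstd, truth


@pytest.fixture(scope="session")
def study_table():
    """Study-regime synthetic table (1,407 species, tree-derived PD)."""
    table, truth = simulate_table(default_config(seed=7), n_oracle=50_000)
    cont = ["native_range_size", "seed_mass", "height", "sla", "pd_mean", "pd_min"]
    # heavy-tailed traits enter models on the log scale (the generative
    # covariates are standardized log-traits); PD indices stay raw
    transforms = {c: "log10" for c in cont[:4]}
    tstd, params = standardize(table, cont, transforms=transforms)
    return table, tstd, truth


@pytest.fixture
def three_row_table():
    df = pd.DataFrame(
        {
            "species_id": ["Acacia saligna", "Pinus radiata", "Ricinus communis"],
            "naturalized": [1, 0, 1],
            "origin_europe": [0, 0, 1],
            "native_range_size": [12, 3, 44],
            "gf_woody": [1, 1, 0],
            "seed_mass": [25.0, np.nan, 101.5],
            "height": [6.0, 30.0, 3.5],
            "sla": [8.1, 4.2, 15.0],
            "pd_mean": [210.0, 300.0, 180.0],
            "pd_min": [35.0, 120.0, 12.0],
            "suitability": [420, 13, 977],
        }
    )
    return SpeciesTable(df)
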