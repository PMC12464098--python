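"""One-command orchestration of the full analysis chain.

``run_analysis`` goes: read table -> (optionally) compute PD indices from a
tree -> standardize -> univariate naturalization screen -> full models with
and without suitability -> suitability-association screen -> mediation
candidate gate -> bootstrap mediation -> write every report table as CSV
plus a structured run log (seed, versions, row counts, decisions).

``run_simulate`` wraps the synthetic generator: it writes a species table,
the simulated tree with its occurrence counts, and the oracle truth table.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .glm import (
    fits_to_frame,
    full_models,
    nagelkerke_r2,
    suitability_screen,
    univariate_screen,
)
from .mediation import mediation_table, select_candidates
from .phylo import PhyloContext, relatedness_table
from .simulate import SyntheticConfig, TreeSpec, default_config, simulate_table
from .table import (
    CONTINUOUS_TRAITS,
    ColumnMapping,
    SpeciesTable,
    naturalization_summary,
    read_species_table,
    standardize,
)


@dataclass
class RunConfig:
    """Configuration of an analysis run (usually loaded from YAML)."""

    species_table: str
    out_dir: str = "floranat_out"
    tree: str | None = None
    occurrence: str | None = None
    columns: dict[str, str] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    percentiles: tuple[float, float] = (10.0, 90.0)
    predictors: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "percentiles" in raw:
            raw["percentiles"] = tuple(raw["percentiles"])
        return cls(**raw)

    @property
    def mapping(self) -> ColumnMapping:
        return ColumnMapping(columns=dict(self.columns), transforms=dict(self.transforms))


def _ensure_pd_columns(table: SpeciesTable, cfg: RunConfig) -> SpeciesTable:
    """Join tree-derived PD columns when the CSV does not carry them."""
    have_pd = {"pd_mean", "pd_min"} <= set(table.df.columns)
    if have_pd:
        return table
    if cfg.tree is None or cfg.occurrence is None:
        raise ConfigurationError(
            "the species table has no pd_mean/pd_min columns; either include "
            "them in the CSV or supply a Newick tree (tree:) plus native "
            "occurrence counts (occurrence:) so they can be computed"
        )
    ctx = PhyloContext.from_files(
        cfg.tree, cfg.occurrence, aliens=table.df["species_id"].tolist()
    )
    rel = relatedness_table(ctx)
    df = table.df.copy()
    df["_join"] = df["species_id"].str.strip().str.replace(" ", "_").str.casefold()
    merged = df.merge(
        rel.rename(columns={"species_id": "_join"}), on="_join", how="left"
    ).drop(columns=["_join", "nearest_native"])
    return SpeciesTable(merged, dict(table.provenance))


def run_analysis(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full two-step analysis and write all report tables.

    Returns the run report (also written as ``run_log.yaml``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "n_boot": cfg.n_boot,
        "percentiles": list(cfg.percentiles),
        "versions": {
            "floranat": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    table = read_species_table(cfg.species_table, cfg.mapping)
    log["stages"]["read"] = {"rows": len(table), "source": str(cfg.species_table)}

    table = _ensure_pd_columns(table, cfg)
    summary = naturalization_summary(table)
    log["stages"]["summary"] = {
        "n_total": summary.n_total,
        "n_naturalized": summary.n_naturalized,
        "fraction": summary.fraction,
    }
    pd.DataFrame([summary._asdict()]).to_csv(out / "naturalization_summary.csv", index=False)

    # standardize every continuous characteristic except the raw mediator
    # count (it must stay a count as the NB response; the GLM layer z-scores
    # it internally when it enters as a predictor)
    cont = [
        c
        for c in CONTINUOUS_TRAITS
        if c in table.df.columns and c not in ("suitability", "pd_wmean")
    ]
    tstd, std_params = standardize(table, cont, transforms=cfg.transforms)
    std_params.to_file(out / "standardization_params.txt")
    log["stages"]["standardize"] = {"variables": cont}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        screen_y = univariate_screen(tstd)
        screen_m = suitability_screen(tstd)
        full = full_models(tstd, predictors=cfg.predictors)
        candidates = select_candidates(screen_y, screen_m, alpha=cfg.alpha)
        med = mediation_table(
            tstd,
            candidates,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
            percentiles=cfg.percentiles,
            alpha=cfg.alpha,
        )
    log["warnings"] = sorted({str(w.message) for w in caught})

    fits_to_frame(screen_y).to_csv(out / "univariate_naturalization.csv", index=False)
    fits_to_frame(screen_m).to_csv(out / "suitability_associations.csv", index=False)
    full.with_suitability.to_frame().to_csv(out / "full_model_with_suitability.csv", index=False)
    full.without_suitability.to_frame().to_csv(
        out / "full_model_without_suitability.csv", index=False
    )
    comparison = pd.DataFrame(
        [
            {
                "model": "with_suitability",
                "k": full.with_suitability.k_params,
                "loglik": full.with_suitability.loglik,
                "aic": full.with_suitability.aic,
                "nagelkerke_r2": nagelkerke_r2(full.with_suitability),
                "n_used": full.with_suitability.n_used,
            },
            {
                "model": "without_suitability",
                "k": full.without_suitability.k_params,
                "loglik": full.without_suitability.loglik,
                "aic": full.without_suitability.aic,
                "nagelkerke_r2": nagelkerke_r2(full.without_suitability),
                "n_used": full.without_suitability.n_used,
            },
        ]
    )
    comparison.to_csv(out / "model_comparison.csv", index=False)
    med.to_csv(out / "mediation_table.csv", index=False)

    log["stages"]["screens"] = {
        "univariate_fits": len(screen_y),
        "suitability_fits": len(screen_m),
        "full_model_n_used": full.with_suitability.n_used,
        "delta_aic": full.delta_aic,
        "delta_r2": full.delta_r2,
    }
    log["stages"]["mediation"] = {
        "candidates": candidates,
        "rows": len(med),
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    return log


def _sim_config_from_yaml(path: str | Path) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not raw:
        return default_config()
    if "tree" in raw and raw["tree"] is not None:
        raw["tree"] = TreeSpec(**raw["tree"])
    if "traits" in raw:
        raw["traits"] = {k: tuple(v) for k, v in raw["traits"].items()}
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SyntheticConfig(**raw)


def run_simulate(
    config: SyntheticConfig | str | Path | None,
    out_dir: str | Path = "floranat_sim",
    seed: int | None = None,
    n_species: int | None = None,
) -> dict[str, str]:
    """Generate a synthetic study (table + tree + truth) and write it out."""
    if config is None:
        cfg = default_config()
    elif isinstance(config, SyntheticConfig):
        cfg = config
    else:
        cfg = _sim_config_from_yaml(config)
    if seed is not None:
        cfg.seed = seed
    if n_species is not None:
        cfg.n_species = n_species
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, truth = simulate_table(cfg)
    paths = {"species_table": str(out / "species_table.csv")}
    table.to_csv(paths["species_table"])
    truth.to_csv(out / "truth.csv")
    paths["truth"] = str(out / "truth.csv")

    ctx = table.provenance.get("tree")
    if ctx is not None:
        tree_path = out / "tree.nwk"
        ctx.tree.write(path=str(tree_path), schema="newick")
        occ = pd.DataFrame(
            sorted(ctx.native_occurrence.items()), columns=["tip", "occurrence"]
        )
        occ.to_csv(out / "native_occurrence.csv", index=False)
        paths["tree"] = str(tree_path)
        paths["occurrence"] = str(out / "native_occurrence.csv")

    meta = {
        "seed": cfg.seed,
        "n_species": cfg.n_species,
        "theta": cfg.theta,
        "mediator_effect": cfg.mediator_effect,
        "characteristics": cfg.characteristics,
    }
    (out / "sim_log.json").write_text(json.dumps(meta, indent=2))
    return paths
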