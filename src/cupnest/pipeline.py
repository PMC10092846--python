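"""End-to-end orchestration: assemble the analysis table, apply the
transform conventions, run the model suite, emit summaries.

The analysis table has one row per measurement record and joins three
sources keyed by species:

* nest volumes and dimensions (from :mod:`cupnest.geometry`),
* life-history fields (body mass, clutch size, nest-location flags,
  nest height, migratory status, builder identity, nestling period),
* geographic/climatic summaries (from :mod:`cupnest.geospatial`).

Only complete cases enter each model.  Standing exclusions: obligate
cavity nesters leave all outer-dimension models (their outer size is
cavity-constrained); male-built nests are excluded throughout (too few
species); builder-contrast models keep only species with biparental
care, comparing female/mainly-female versus biparental building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import bpmm, geometry
from .bpmm import MCMCSettings, ModelSpec, ModelSummary, PosteriorSample, PriorSpec
from .errors import DesignError
from .synthetic import SyntheticScenario, simulate_traits, simulate_tree

__all__ = [
    "AnalysisTable", "ModelDefinition", "assemble", "apply_transforms",
    "default_suite", "run_suite", "SuiteResult", "synthetic_study",
]

#: transform conventions: sizes/durations log; precipitation and absolute
#: latitude square-root; temperature signed square-root (breeding-season
#: means can be below zero)
DEFAULT_TRANSFORMS: dict[str, str] = {
    "outer_volume": "log", "inner_volume": "log", "full_volume": "log",
    "outer_diameter": "log", "inner_diameter": "log",
    "outer_height": "log", "inner_height": "log", "rim_thickness": "log",
    "body_mass": "log", "clutch_size": "log", "nest_height": "log",
    "nestling_period": "log",
    "mean_precipitation": "sqrt", "abs_latitude": "sqrt",
    "mean_temperature": "signed_sqrt",
}

#: fixed-effect schema shared by the nest-dimension models
_COMMON_TERMS: dict[str, str] = {
    "source_literature": "binary",
    "body_mass": "continuous",
    "clutch_size": "continuous",
    "nest_ground": "binary",
    "nest_vegetation": "binary",
    "nest_cliff": "binary",
    "nest_height": "continuous",
    "migratory": "binary",
    "mean_temperature": "continuous",
    "mean_precipitation": "continuous",
    "abs_latitude": "continuous",
    "hemisphere_south": "binary",
    "insular": "binary",
}


@dataclass
class AnalysisTable:
    """Joined record-level table plus a log of row/species counts."""

    data: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_species(self) -> int:
        return self.data["species_id"].nunique()


@dataclass
class ModelDefinition:
    """A ModelSpec plus its row-subset rule and aggregation level."""

    spec: ModelSpec
    #: row filter applied before complete-case dropping
    subset: Optional[Callable[[pd.DataFrame], pd.Series]] = None
    #: collapse to one row per species (mean response) before fitting
    species_level: bool = False


def assemble(
    measurements: pd.DataFrame,
    life_history: pd.DataFrame,
    geo_summaries: pd.DataFrame,
) -> AnalysisTable:
    """Join measurement records with species-level predictors.

    ``measurements`` must carry ``species_id``, ``source``, ``site_label``
    and the volume/dimension columns; the other two tables are
    species-level and keyed by ``species_id``.
    """
    dup = measurements.duplicated(subset=["species_id", "site_label"])
    if dup.any():
        keys = measurements.loc[dup, ["species_id", "site_label"]].values.tolist()
        raise DesignError(f"duplicate (species, site) keys: {keys[:5]}")
    for name, df in [("life_history", life_history), ("geo_summaries", geo_summaries)]:
        if df["species_id"].duplicated().any():
            raise DesignError(f"duplicate species_id in {name}")
    merged = measurements.merge(life_history, on="species_id", how="left")
    merged = merged.merge(geo_summaries, on="species_id", how="left")
    missing_lh = sorted(set(measurements["species_id"]) - set(life_history["species_id"]))
    missing_geo = sorted(set(measurements["species_id"]) - set(geo_summaries["species_id"]))

    merged["source_literature"] = (merged["source"] == "literature").astype(float)
    if "midpoint_lat" in merged.columns:
        merged["abs_latitude"] = merged["midpoint_lat"].abs()
        merged["hemisphere_south"] = (merged["midpoint_lat"] < 0).astype(float)
    log = {
        "n_records_in": len(measurements),
        "n_species_in": measurements["species_id"].nunique(),
        "species_missing_life_history": missing_lh,
        "species_missing_geo": missing_geo,
    }
    return AnalysisTable(data=merged, log=log)


def apply_transforms(
    table: pd.DataFrame, spec: ModelSpec, std_ddof: int = 0
) -> pd.DataFrame:
    """Model-ready columns: transform per the spec's transform map, then
    mean-centre and scale continuous predictors to unit SD."""
    out = table.copy()
    cols = [spec.response, *spec.fixed_terms]
    for col in cols:
        tr = spec.transform_map.get(col, "none")
        out[col] = bpmm.apply_transform(out[col].to_numpy(dtype=float), tr, col)
    if spec.standardize:
        for col, kind in spec.fixed_terms.items():
            if kind == "continuous":
                v = out[col].to_numpy(dtype=float)
                sd = v.std(ddof=std_ddof)
                if sd == 0:
                    raise DesignError(f"constant predictor {col!r}")
                out[col] = (v - v.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# the model suite

def _not_cavity(df: pd.DataFrame) -> pd.Series:
    if "cavity_obligate" in df.columns:
        return df["cavity_obligate"].fillna(0) == 0
    return pd.Series(True, index=df.index)


def _not_male_built(df: pd.DataFrame) -> pd.Series:
    if "builder" in df.columns:
        return df["builder"].fillna("") != "male"
    return pd.Series(True, index=df.index)


def _biparental_care(df: pd.DataFrame) -> pd.Series:
    keep = _not_male_built(df)
    if "care_system" in df.columns:
        keep &= df["care_system"] == "biparental"
    if "builder" in df.columns:
        keep &= df["builder"].isin(["female", "mainly_female", "both"])
    return keep


def default_suite(terms: Mapping[str, str] | None = None) -> dict[str, ModelDefinition]:
    """The named models of the analysis: eight nest-dimension responses,
    the builder contrast, and the nestling-period model.

    ``terms`` overrides the shared fixed-effect schema (useful for reduced
    or synthetic datasets); exclusion rules are unaffected.
    """
    common = dict(_COMMON_TERMS if terms is None else terms)

    def _dimension_spec(response: str) -> ModelSpec:
        return ModelSpec(response=response, fixed_terms=dict(common),
                         transform_map=dict(DEFAULT_TRANSFORMS))

    suite: dict[str, ModelDefinition] = {}
    outer_responses = ["outer_volume", "full_volume", "outer_diameter",
                       "outer_height", "rim_thickness"]
    inner_responses = ["inner_volume", "inner_diameter", "inner_height"]
    for resp in outer_responses:
        suite[resp] = ModelDefinition(
            spec=_dimension_spec(resp),
            subset=lambda df: _not_cavity(df) & _not_male_built(df),
        )
    for resp in inner_responses:
        suite[resp] = ModelDefinition(
            spec=_dimension_spec(resp),
            subset=_not_male_built,
        )
    builder_terms = dict(common)
    builder_terms["builder_both"] = "binary"
    suite["builder_contrast"] = ModelDefinition(
        spec=ModelSpec(response="outer_volume", fixed_terms=builder_terms,
                       transform_map=dict(DEFAULT_TRANSFORMS)),
        subset=lambda df: _not_cavity(df) & _biparental_care(df),
    )
    nestling_terms = dict(common)
    nestling_terms["outer_volume"] = "continuous"
    suite["nestling_period"] = ModelDefinition(
        spec=ModelSpec(response="nestling_period", fixed_terms=nestling_terms,
                       transform_map=dict(DEFAULT_TRANSFORMS),
                       random_terms=frozenset({"phylogeny"})),
        subset=lambda df: _not_cavity(df) & _biparental_care(df),
        species_level=True,
    )
    return suite


@dataclass
class SuiteResult:
    summary: ModelSummary
    sample: PosteriorSample
    vif: pd.Series
    n_records: int
    n_species: int


def _prepare_model_table(
    table: AnalysisTable, definition: ModelDefinition
) -> pd.DataFrame:
    df = table.data
    if definition.subset is not None:
        df = df[definition.subset(df)]
    spec = definition.spec
    cols = ["species_id", *([c for c in ["site_label", "source"] if c in df.columns]),
            spec.response, *spec.fixed_terms]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise DesignError(f"columns missing for model: {missing_cols}")
    df = df[cols].dropna(subset=[spec.response, *spec.fixed_terms])
    if definition.species_level:
        # predictors are species-level already; average the response
        agg = {spec.response: "mean", **{c: "first" for c in spec.fixed_terms}}
        df = df.groupby("species_id", as_index=False).agg(agg)
    return df


def run_suite(
    table: AnalysisTable,
    suite: Mapping[str, ModelDefinition],
    priors: PriorSpec,
    settings: MCMCSettings,
    trees: Sequence[dendropy.Tree],
    log: Optional[Callable[[str], None]] = None,
) -> dict[str, SuiteResult]:
    """Fit every model in the suite over the tree sample.

    Each model gets its exclusion subset and complete-case filter, a
    multi-tree pooled posterior, the summary/diagnostic suite and a VIF
    report; runs whose worst PSRF reaches 1.1 are flagged non-converged
    rather than dropped.
    """
    results: dict[str, SuiteResult] = {}
    for name, definition in suite.items():
        df = _prepare_model_table(table, definition)
        if log:
            log(f"{name}: {len(df)} records, {df['species_id'].nunique()} species")
        transformed = apply_transforms(df, definition.spec)
        # transforms/standardization already applied above
        flat_spec = ModelSpec(
            response=definition.spec.response,
            fixed_terms=definition.spec.fixed_terms,
            random_terms=definition.spec.random_terms,
            transform_map={}, standardize=False,
        )
        sample = bpmm.multi_tree_run(transformed, flat_spec, priors, settings, trees)
        design = bpmm.build_design(transformed, flat_spec, trees[0])
        summary = bpmm.summarize(sample, design.X)
        vif_report = bpmm.vif(pd.DataFrame(design.X[:, 1:], columns=design.fixed_names[1:]))
        results[name] = SuiteResult(
            summary=summary, sample=sample, vif=vif_report,
            n_records=len(df), n_species=df["species_id"].nunique(),
        )
        if log:
            log(f"{name}: R2={summary.conditional_r2:.3f} "
                f"converged={summary.converged}")
    return results


# ---------------------------------------------------------------------------
# fully synthetic studies (measurement records with raw dimensions)

def _dims_from_volumes(full: float, inner: float, rng: np.random.Generator) -> geometry.NestDimensions:
    """Back out plausible raw dimensions reproducing the two volumes.

    Nest shape is fixed at height = 0.6 * diameter, so
    V = (2/3) pi (D/2)^2 (0.6 D) = 0.1 pi D^3; replicate diameters get
    +/-2% jitter around the mean (mean preserved in expectation)."""
    def pair(volume: float, n_d: int, n_h: int) -> tuple[list[float], list[float]]:
        D = (volume / (0.1 * np.pi)) ** (1.0 / 3.0)
        H = 0.6 * D
        jit = rng.uniform(-0.02, 0.02, size=n_d)
        jit -= jit.mean()
        return list(D * (1 + jit)), [H] * n_h
    Ds, Hs = pair(full, 4, 2)
    ds, hs = pair(inner, 4, 2)
    return geometry.NestDimensions(outer_diameters=Ds, outer_heights=Hs,
                                   inner_diameters=ds, inner_heights=hs)


def synthetic_study(
    scenario: SyntheticScenario, inner_fraction: float = 0.35,
) -> tuple[list[geometry.MeasurementRecord], pd.DataFrame, AnalysisTable, dendropy.Tree]:
    """A complete synthetic study in the real-data formats.

    The generated record-level response is interpreted as log outer nest
    volume; raw dimensions are backed out so that the geometry module
    reproduces the volumes, exercising the whole ingest path.  Returns
    (measurement records, record-level truth table, assembled analysis
    table, tree).
    """
    tree = simulate_tree(scenario)
    data, truth = simulate_traits(tree, scenario)
    rng = np.random.default_rng(scenario.seed + 3)

    records = []
    for _, row in data.iterrows():
        outer = float(np.exp(row["response"]))
        inner = outer * inner_fraction / (1.0 - inner_fraction)
        dims = _dims_from_volumes(outer + inner, inner, rng)
        records.append(geometry.MeasurementRecord(
            species_id=row["species_id"], source=row["source"],
            dimensions=dims, site_label=row["site_label"]))
    measured = geometry.add_volume_columns(records)

    per_species = data.groupby("species_id").first().reset_index()
    life_cols = [c for c in per_species.columns
                 if c not in ("site_label", "source", "response")]
    life_history = per_species[life_cols]
    geo = pd.DataFrame({"species_id": sorted(data["species_id"].unique())})
    table = assemble(measured, life_history, geo)
    return records, data, table, tree
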