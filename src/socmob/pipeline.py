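"""End-to-end pipeline: generate/read -> aging scores -> SES indices ->
mobility -> association models -> diagonal reference model.

The pipeline is driven by a single YAML config. Every output (aging
measures, SES scores, mobility table, long effect-size table, DRM summary)
is written as delimited text or JSON together with a run manifest recording
the seed, the config, and library versions, so a fixed seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioage, drm as drm_mod, models, origins as origins_mod, wealth as wealth_mod
from .mobility import build_mobility_table
from .synthetic import SyntheticConfig, generate_cohort, generate_reference_panel

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "PipelineResults", "run_pipeline", "compute_scores",
    "read_cohort", "read_wealth", "forest_plot",
]

# column dictionary for the subject table: name -> (dtype kind, required)
COHORT_SCHEMA = {
    "subject_id": ("int", True),
    "household_id": ("int", True),
    "birth_year": ("int", True),
    "age_at_draw": ("float", True),
    "sex": ("str", True),
    "race": ("str", True),
    "hispanic": ("int", True),
    "chd_family_finances": ("float", True),
    "chd_father_occupation": ("float", True),
    "chd_hardship": ("float", True),
    "chd_parent_education": ("float", True),
    "father_education_years": ("float", False),
    "mother_education_years": ("float", False),
    "education_years": ("float", True),
    "phenoage_clock": ("float", False),
    "grimage_clock": ("float", False),
    "dunedin_poam": ("float", False),
}
WEALTH_SCHEMA = {
    "subject_id": ("int", True),
    "household_id": ("int", False),
    "year": ("int", True),
    "net_worth_nominal": ("float", True),
}


def _validate_table(df: pd.DataFrame, schema: dict, what: str) -> pd.DataFrame:
    missing = [c for c, (_, req) in schema.items() if req and c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        # biomarker panels are open-ended, so unknown columns are tolerated
        log.warning("%s: ignoring unknown column(s): %s", what, extra)
    for col, (kind, _) in schema.items():
        if col not in df.columns or kind == "str":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(
                f"{what}: non-numeric value(s) in column {col!r} at file "
                f"line(s) {lines}")
        df[col] = coerced
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject table (delimited text, empty = missing)."""
    return _validate_table(pd.read_csv(path), COHORT_SCHEMA, f"cohort file {path}")


def read_wealth(path: str | Path) -> pd.DataFrame:
    return _validate_table(pd.read_csv(path), WEALTH_SCHEMA, f"wealth file {path}")


@dataclass
class PipelineConfig:
    """Single configuration object for a full run.

    With ``simulate=True`` (the default) the synthetic-data module generates
    the cohort, wealth table, and reference panel; otherwise the three input
    paths are read and validated.
    """

    seed: int = 1
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort_path: str | None = None
    wealth_path: str | None = None
    reference_path: str | None = None
    cpi_path: str | None = None
    output_dir: str = "socmob_output"
    reference_n: int = 10_000
    exposures: tuple[str, ...] = ("origins", "attainment", "resid_change",
                                  "diff_score", "edu_mobility")
    outcomes: tuple[str, ...] = bioage.ADVANCEMENT_COLUMNS
    subgroups: tuple[str, ...] = ()          # subset of {"sex", "race_bw"}
    interaction_modifiers: tuple[str, ...] = ()  # e.g. ("sex", "race_bw", "origins_z")
    run_drm: bool = False
    drm_outcome: str = "kdm_adv"
    drm_k: int = 3
    drm_n_boot: int = 200
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if syn:
            cfg.synthetic = dataclasses.replace(SyntheticConfig(), **syn)
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["biomarker_specs"] = [
            list(dataclasses.astuple(s)) if dataclasses.is_dataclass(s) else list(s)
            for s in self.synthetic.biomarker_specs]
        return d


def compute_scores(
    subjects: pd.DataFrame,
    wealth: pd.DataFrame,
    reference: pd.DataFrame,
    cpi: pd.Series | None = None,
) -> pd.DataFrame:
    """Score everything: six advancement outcomes, SES indices, mobility.

    Returns one analysis row per subject (identifiers and demographics
    included) ready for the association models.
    """
    model = bioage.train_reference_model(reference)
    blood = bioage.score_all(subjects, model, age_col="age_at_draw")
    measures = pd.concat(
        [blood, subjects[[c for c in ("phenoage_clock", "grimage_clock",
                                      "dunedin_poam") if c in subjects.columns]]],
        axis=1)
    advancement = bioage.age_adjust(measures, subjects["age_at_draw"])

    origins_scores = origins_mod.build_origins_index(subjects)
    attainment = wealth_mod.build_attainment_index(subjects, wealth, cpi)
    mobility = build_mobility_table(origins_scores, attainment, subjects)

    out = pd.concat([
        subjects[["subject_id", "household_id", "birth_year", "age_at_draw",
                  "sex", "race", "hispanic"]],
        advancement,
        origins_scores[["z_score", "percentile_rank"]].rename(columns={
            "z_score": "origins_z", "percentile_rank": "origins_pct"}),
        attainment[["z_score", "percentile_rank", "constant_dollar_wealth"]]
        .rename(columns={"z_score": "attainment_z",
                         "percentile_rank": "attainment_pct"}),
        mobility,
    ], axis=1)
    return out


@dataclass
class PipelineResults:
    analysis: pd.DataFrame
    effect_table: pd.DataFrame
    interaction_table: pd.DataFrame | None
    drm_summary: dict | None
    manifest: dict


def _effect_exposures(names) -> dict:
    return {n: models.DEFAULT_EXPOSURES[n] for n in names}


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run the full analysis and write the results bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(syn)
        subjects, wealth = cohort.subjects, cohort.wealth
        reference = generate_reference_panel(syn, n=config.reference_n)
        cpi = wealth_mod.default_cpi_table()
    else:
        for name in ("cohort_path", "wealth_path", "reference_path"):
            if getattr(config, name) is None:
                raise ValueError(f"simulate=False requires {name}")
        subjects = read_cohort(config.cohort_path)
        wealth = read_wealth(config.wealth_path)
        reference = pd.read_csv(config.reference_path)
        cpi = (wealth_mod.load_cpi(config.cpi_path)
               if config.cpi_path else wealth_mod.default_cpi_table())

    analysis = compute_scores(subjects, wealth, reference, cpi)

    subgroup_masks = {}
    if "sex" in config.subgroups:
        subgroup_masks["women"] = analysis["sex"] == "female"
        subgroup_masks["men"] = analysis["sex"] == "male"
    if "race_bw" in config.subgroups:
        subgroup_masks["Black"] = analysis["race"] == "Black"
        subgroup_masks["White"] = analysis["race"] == "White"

    effect_table = models.run_effect_table(
        analysis, outcomes=tuple(config.outcomes),
        exposures=_effect_exposures(config.exposures),
        subgroups=subgroup_masks or None)

    interaction_table = None
    if config.interaction_modifiers:
        rows = []
        for modifier in config.interaction_modifiers:
            for outcome in config.outcomes:
                spec = models.ModelSpec(outcome=outcome,
                                        exposure="resid_change_z",
                                        modifier=modifier)
                est = models.fit_interaction_model(analysis, spec)
                row = est.to_dict()
                row["modifier"] = modifier
                rows.append(row)
        interaction_table = pd.DataFrame(rows)

    drm_summary = None
    if config.run_drm:
        o_cat, d_cat = drm_mod.categorize_status(
            analysis["origins_z"], analysis["attainment_z"], k=config.drm_k)
        keep = (analysis[config.drm_outcome].notna()
                & o_cat.notna() & d_cat.notna())
        y = analysis.loc[keep, config.drm_outcome].to_numpy(float)
        y = (y - y.mean()) / y.std()
        fit, effect = drm_mod.drm_mobility_effect(
            y, o_cat[keep], d_cat[keep],
            households=analysis.loc[keep, "household_id"].to_numpy(),
            n_boot=config.drm_n_boot, seed=config.seed)
        drm_summary = {"outcome": config.drm_outcome, "k": config.drm_k,
                       "fit": fit.to_dict(), "mobility_effect": effect.to_dict()}

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": int(len(analysis)),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    analysis.to_csv(outdir / "analysis_table.csv", index=False)
    effect_table.to_csv(outdir / "effect_table.csv", index=False)
    if interaction_table is not None:
        interaction_table.to_csv(outdir / "interaction_table.csv", index=False)
    if drm_summary is not None:
        (outdir / "drm_summary.json").write_text(
            json.dumps(drm_summary, indent=1, default=float))
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str))
    if config.make_plot:
        forest_plot(effect_table, outdir / "effect_sizes.png")
    return PipelineResults(analysis, effect_table, interaction_table,
                           drm_summary, manifest)


def forest_plot(effect_table: pd.DataFrame, path: str | Path) -> None:
    """Simple forest plot of the standardized effect sizes with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = effect_table[effect_table["subgroup"] == "all"]
    labels = [f"{r.exposure} → {r.outcome}" for r in sub.itertuples()]
    y = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(sub) + 1.5))
    ax.errorbar(sub["beta"], y,
                xerr=[sub["beta"] - sub["ci_low"], sub["ci_high"] - sub["beta"]],
                fmt="o", ms=3, lw=1)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y, labels, fontsize=6)
    ax.set_xlabel("standardized effect (SD outcome per SD exposure)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
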