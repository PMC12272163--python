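"""End-to-end orchestration: simulate -> measure -> aggregate -> fit -> report.

``run_pipeline`` drives the whole analysis on a synthetic cohort (or a
user-supplied per-fibre area table), producing person-level CSVs, model
coefficient tables mirroring the study layouts (covariate-ladder OLS for
the person averages, compositional log-ratio and g-ratio location-scale
models), diagnostic figures and a JSON manifest with the seeds and the
record counts at every filtering stage.  A single global seed fans out to
per-stage child seeds through ``numpy.random.SeedSequence`` so stages are
individually reproducible; report generation itself touches no RNG.

``sensitivity_suite`` re-runs the core age associations under the three
exclusion rules (g-ratio = 1; fibre diameter < 1 um; axon diameter <
0.8 um) and tabulates the coefficients side by side.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import aggregation, morphometry, stat_models, synthetic
from .config import CohortConfig, load_config
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityRule", "RunConfig", "DEFAULT_RULES",
    "run_pipeline", "sensitivity_suite", "ols_ladder",
]


@dataclass(frozen=True)
class SensitivityRule:
    """A pure exclusion predicate on the per-fibre metrics table.

    ``keep`` returns a boolean keep-mask; it must not mutate its input.
    """
    name: str
    keep: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)


DEFAULT_RULES = [
    SensitivityRule("exclude_g_equal_1",
                    lambda df: df["g_ratio"].to_numpy() < 1.0),
    SensitivityRule("exclude_fibre_lt_1um",
                    lambda df: df["fibre_diameter_um"].to_numpy() >= 1.0),
    SensitivityRule("exclude_axon_lt_0.8um",
                    lambda df: df["axon_diameter_um"].to_numpy() >= 0.8),
]

_LADDER = [
    ("ref", []),
    ("model1", ["hypertension"]),
    ("model2", ["hypertension", "smoking"]),
    ("model3", ["hypertension", "smoking", "bmi"]),
    ("model4", ["hypertension", "smoking", "bmi", "n_vascular"]),
    ("model5", ["hypertension", "smoking", "bmi", "n_vascular", "gfr"]),
]

_PERSON_METRICS = ["mean_fibre_diameter_um", "mean_axon_diameter_um",
                   "mean_myelin_thickness_um", "mean_g_ratio"]


@dataclass
class RunConfig:
    """Pipeline controls; see the field comments for the stage toggles."""
    cohort: CohortConfig | str | None = None   # config object or YAML path
    use_rendering: bool = False    # render/measure a demo section per run
    direct_tables: bool = True     # analyse generator tables directly
    subsample_seed: int = 20240101
    n_subsample: int = 100
    sensitivity: bool = True
    write_fibres: bool = True
    make_figures: bool = True
    out_dir: str | Path = "results"
    log_level: str = "INFO"

    def resolve_cohort(self) -> CohortConfig:
        if isinstance(self.cohort, CohortConfig):
            return self.cohort.validate()
        return load_config(self.cohort)


def ols_ladder(person: pd.DataFrame,
               outcomes: list[str] = _PERSON_METRICS) -> pd.DataFrame:
    """The covariate-ladder OLS table: age effect on each person-average.

    Every model adjusts for sex; successive models add hypertension,
    smoking, BMI, vascular-disease count and GFR.  Returns one row per
    (outcome, model) with the age estimate, SE and p-value.
    """
    rows = []
    base = person.copy()
    base["sex"] = (base["sex"] == "female").astype(float)
    for outcome in outcomes:
        for model_name, extras in _LADDER:
            X = base[["age_at_death", "sex"] + extras].astype(float)
            fit = stat_models.fit_ols(base[outcome], X)
            rows.append({
                "outcome": outcome, "model": model_name,
                "estimate": fit.params["age_at_death"],
                "se": fit.bse["age_at_death"],
                "p": fit.pvalues["age_at_death"],
                "intercept": fit.params["intercept"],
                "n": fit.n,
            })
    return pd.DataFrame(rows)


def _interaction_model(person: pd.DataFrame,
                       outcome: str = "mean_fibre_diameter_um") -> pd.DataFrame:
    df = person.copy()
    df["sex"] = (df["sex"] == "female").astype(float)
    df["age_x_sex"] = df["age_at_death"] * df["sex"]
    fit = stat_models.fit_ols(df[outcome],
                              df[["age_at_death", "sex", "age_x_sex"]])
    return pd.DataFrame({"term": fit.params.index,
                         "estimate": fit.params.to_numpy(),
                         "se": fit.bse.to_numpy(),
                         "p": fit.pvalues.to_numpy()})


def _hetero_table(fit: "stat_models.HeteroFit") -> pd.DataFrame:
    rows = [{"submodel": "mean", "term": t, "estimate": fit.beta[t],
             "se": fit.se_beta[t], "p": fit.p_beta[t]}
            for t in fit.beta.index]
    rows += [{"submodel": "log_sd", "term": t, "estimate": fit.gamma[t],
              "se": fit.se_gamma[t], "p": fit.p_gamma[t]}
             for t in fit.gamma.index]
    rows.append({"submodel": "random", "term": "tau2", "estimate": fit.tau2,
                 "se": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def _figures(fibres: pd.DataFrame, person: pd.DataFrame, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    specs = [("fibre_diameter_um", "Fibre diameter (um)", (0, 16)),
             ("axon_diameter_um", "Axon diameter (um)", (0, 12)),
             ("myelin_thickness_um", "Myelin thickness (um)", (0, 5)),
             ("g_ratio", "g-ratio", (0, 1))]
    for ax, (col, label, rng) in zip(axes.ravel(), specs):
        ax.hist(fibres[col], bins=80, range=rng, color="#4878a8")
        ax.set_xlabel(label)
        ax.set_ylabel("fibres")
    fig.tight_layout()
    p = out / "fig_distributions.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    made.append(p)

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (col, label, _) in zip(
            axes.ravel(),
            [(f"mean_{c}" if not c.startswith("g") else "mean_g_ratio", l, r)
             for c, l, r in specs]):
        ax.scatter(person["age_at_death"], person[col], s=12, alpha=0.7)
        b, a = np.polyfit(person["age_at_death"], person[col], 1)
        xs = np.array([person["age_at_death"].min(), person["age_at_death"].max()])
        ax.plot(xs, a + b * xs, color="crimson")
        ax.set_xlabel("age at death (years)")
        ax.set_ylabel(label)
    fig.tight_layout()
    p = out / "fig_age_scatter.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    made.append(p)
    return made


def run_pipeline(run_config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Writes (under ``out_dir``): ``person.csv``, ``composition.csv``,
    ``ols_ladder.csv``, ``age_sex_interaction.csv``, ``density_model.csv``,
    ``spline_fit.json``, ``alr_model.csv``, ``gratio_model.csv``,
    ``dispersion_test.csv``, optional ``fibres.csv``, sensitivity tables,
    figures, and ``manifest.json``.  Deterministic for a fixed config.
    """
    if not (run_config.direct_tables or run_config.use_rendering):
        raise ConfigurationError("all pipeline stage toggles are off")
    cohort_cfg = run_config.resolve_cohort()
    out = Path(run_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=run_config.log_level)

    manifest: dict = {
        "seed": cohort_cfg.seed,
        "subsample_seed": run_config.subsample_seed,
        "n_participants": cohort_cfg.n_participants,
        "stages": {},
    }

    # --- simulate
    participants, gt_fibres = synthetic.sample_cohort_fibres(cohort_cfg)
    areas = synthetic.fibres_to_area_table(gt_fibres)
    manifest["stages"]["simulate"] = {"n_fibres": int(len(gt_fibres))}

    # --- optional render/measure demo on one small field
    if run_config.use_rendering:
        rng = np.random.default_rng(
            np.random.SeedSequence([cohort_cfg.seed, 7]))
        demo = gt_fibres.head(60)
        section, _ = synthetic.render_section(
            demo, pixel_size_um=0.1, field_um=(120.0, 120.0), rng=rng,
            participant_id=str(demo["participant_id"].iloc[0]))
        measured = morphometry.extract_from_masks(section)
        measured.to_csv(out / "rendered_demo_fibres.csv", index=False)
        manifest["stages"]["render"] = {
            "n_rendered": int(len(demo)),
            "n_measured": int(len(measured)),
        }

    # --- measure + filter
    metrics = morphometry.fibre_metrics_table(areas)
    kept, n_excluded = morphometry.validity_filter(metrics)
    manifest["stages"]["measure"] = {
        "n_segmented": int(len(metrics)),
        "n_valid": int(len(kept)),
        "n_excluded": int(n_excluded),
    }
    if run_config.write_fibres:
        kept.to_csv(out / "fibres.csv", index=False, float_format="%.6g")

    # --- aggregate
    person = aggregation.person_averages(kept, participants)
    comp = aggregation.bin_composition(kept)
    person = person.merge(comp.drop(columns=["n_fibres"]), on="participant_id")
    sub = aggregation.subsample_fibres(kept, run_config.n_subsample,
                                       seed=run_config.subsample_seed)
    person.to_csv(out / "person.csv", index=False, float_format="%.6g")
    comp.to_csv(out / "composition.csv", index=False, float_format="%.6g")
    sub.to_csv(out / "subsample.csv", index=False, float_format="%.6g")
    manifest["stages"]["aggregate"] = {
        "n_person": int(len(person)),
        "n_subsampled": int(len(sub)),
        "n_zero_replaced": comp.attrs.get("n_zero_replaced", 0),
    }

    # --- fits
    ladder = ols_ladder(person)
    ladder.to_csv(out / "ols_ladder.csv", index=False, float_format="%.6g")
    _interaction_model(person).to_csv(out / "age_sex_interaction.csv",
                                      index=False, float_format="%.6g")

    dens = person.copy()
    dens["sex"] = (dens["sex"] == "female").astype(float)
    dfit = stat_models.fit_ols(dens["density_per_mm2"],
                               dens[["age_at_death", "sex"]])
    pd.DataFrame({"term": dfit.params.index,
                  "estimate": dfit.params.to_numpy(),
                  "se": dfit.bse.to_numpy(),
                  "p": dfit.pvalues.to_numpy()}).to_csv(
        out / "density_model.csv", index=False, float_format="%.6g")

    rho, p_rho = stat_models.spearman(person["age_at_death"],
                                      person["mean_fibre_diameter_um"])

    smooth = stat_models.fit_spline_mixed(
        sub["myelin_thickness_um"], sub["axon_diameter_um"],
        groups=sub["participant_id"])
    grid = np.linspace(0.5, 10.0, 96)
    (out / "spline_fit.json").write_text(json.dumps({
        "lambda": smooth.lam, "edf": smooth.edf, "tau2": smooth.tau2,
        "sigma2": smooth.sigma2, "var_explained": smooth.var_explained,
        "n": smooth.n,
        "grid_axon_um": grid.tolist(),
        "fitted_myelin_um": smooth.curve(grid).tolist(),
        "derivative": smooth.derivative(grid).tolist(),
    }, indent=2))

    y, X, Z, grp = stat_models.alr_model_frame(comp, participants,
                                               age_center=cohort_cfg.age_mean)
    alr_fit = stat_models.fit_hetero_mixed(y, X, Z, grp, seed=cohort_cfg.seed)
    _hetero_table(alr_fit).to_csv(out / "alr_model.csv", index=False,
                                  float_format="%.6g")
    disp = stat_models.dispersion_age_test(
        y, X, grp,
        {"base": Z,
         "age": Z.assign(age=X["age"]),
         "age_x_cat": Z.assign(age=X["age"],
                               **{f"age:cat{k}": X[f"age:cat{k}"]
                                  for k in range(3, 7)})},
        seed=cohort_cfg.seed)
    disp.to_csv(out / "dispersion_test.csv", index=False, float_format="%.6g")

    yg, Xg, Zg, grpg = stat_models.gratio_model_frame(
        sub, participants, age_center=cohort_cfg.age_mean)
    g_fit = stat_models.fit_hetero_mixed(yg, Xg, Zg, grpg, seed=cohort_cfg.seed)
    _hetero_table(g_fit).to_csv(out / "gratio_model.csv", index=False,
                                float_format="%.6g")

    manifest["stages"]["analyze"] = {
        "spearman_age_fibre": {"rho": rho, "p": p_rho},
        "age_slope_fibre_um_per_yr": float(
            ladder.query("outcome == 'mean_fibre_diameter_um' and model == 'ref'")
            ["estimate"].iloc[0]),
        "density_age_slope": float(dfit.params["age_at_death"]),
        "spline_edf": smooth.edf,
        "alr_loglik": alr_fit.loglik,
        "gratio_loglik": g_fit.loglik,
    }

    # --- sensitivity
    if run_config.sensitivity:
        sens = sensitivity_suite(kept, participants, DEFAULT_RULES)
        sens.to_csv(out / "sensitivity.csv", index=False, float_format="%.6g")
        manifest["stages"]["sensitivity"] = {
            "rules": [r.name for r in DEFAULT_RULES]}

    if run_config.make_figures:
        _figures(kept, person, out)

    manifest["counts_conserved"] = (
        manifest["stages"]["measure"]["n_segmented"]
        == manifest["stages"]["measure"]["n_valid"]
        + manifest["stages"]["measure"]["n_excluded"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def sensitivity_suite(fibres: pd.DataFrame, participants: pd.DataFrame,
                      rules: list[SensitivityRule] = DEFAULT_RULES) -> pd.DataFrame:
    """Age-association coefficients under each exclusion rule.

    For the baseline and each rule: person averages are rebuilt, the
    sex-adjusted OLS age slope refit for each morphometric, and the
    compositional model's age x large-bin interactions refit.
    Participants losing all fibres under a rule are dropped with a warning.
    """
    rows = []
    variants = [("baseline", np.ones(len(fibres), dtype=bool))]
    variants += [(r.name, np.asarray(r.keep(fibres), dtype=bool)) for r in rules]
    for name, mask in variants:
        kept = fibres.loc[mask]
        person = aggregation.person_averages(kept, participants)
        base = person.copy()
        base["sex"] = (base["sex"] == "female").astype(float)
        for outcome in _PERSON_METRICS:
            fit = stat_models.fit_ols(
                base[outcome], base[["age_at_death", "sex"]])
            rows.append({"rule": name, "model": "ols", "outcome": outcome,
                         "term": "age_at_death",
                         "estimate": fit.params["age_at_death"],
                         "se": fit.bse["age_at_death"],
                         "p": fit.pvalues["age_at_death"],
                         "n_fibres": int(len(kept)),
                         "n_person": int(len(person))})
        comp = aggregation.bin_composition(kept)
        y, X, Z, grp = stat_models.alr_model_frame(comp, participants)
        fit = stat_models.fit_hetero_mixed(y, X, Z, grp, seed=0)
        for term in ("age:cat5", "age:cat6"):
            rows.append({"rule": name, "model": "alr", "outcome": "log_ratio",
                         "term": term, "estimate": fit.beta[term],
                         "se": fit.se_beta[term], "p": fit.p_beta[term],
                         "n_fibres": int(len(kept)),
                         "n_person": int(fit.n_groups)})
    return pd.DataFrame(rows)
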