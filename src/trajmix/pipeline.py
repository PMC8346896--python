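"""End-to-end analysis pipeline and its serializable configuration.

``run_pipeline`` ties the stages together: restrict ages → select the
number of groups by BIC → classification adequacy → (with covariates)
membership odds ratios and profile probabilities → within-group rate
tables → counterfactual cohort decomposition.  Outputs are a versioned
results JSON plus CSV tables and dense trajectory-curve points; a fixed
(config, seed) reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import TrajectorySpec
from .decomposition import decompose, rate_table
from .membership import membership_effects, profile_probabilities
from .panel import CovariateTable, Panel, read_covariates, read_panel
from .selection import adequacy, select_model

__all__ = ["RunConfig", "run_pipeline", "load_report", "RESULTS_SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; YAML round-trippable."""

    panel_path: str = "panel.csv"
    covariates_path: str | None = None
    output_dir: str = "trajmix_output"
    min_age: int = 10
    max_age: int = 33
    analysis_window: tuple = (17, 24)
    j_min: int = 1
    j_max: int = 4
    degree: int = 3
    n_starts: int = 5
    seed: int = 0
    bic_convention: str = "persons"       # or "person-periods"
    at_means: bool = False
    drop_drug_only: bool = False
    dense_windows: bool = False
    younger_cohorts: tuple = ("0",)
    older_cohorts: tuple = ("9", "12", "15")
    profiles: tuple = ()                  # sequence of covariate-override dicts

    def validate(self) -> None:
        if self.j_min > self.j_max or self.j_min < 1:
            raise ValueError(f"invalid group grid: j_min={self.j_min}, j_max={self.j_max}")
        if self.min_age > self.max_age:
            raise ValueError("min_age exceeds max_age")
        lo, hi = self.analysis_window
        if lo > hi:
            raise ValueError("inverted analysis window")
        if self.bic_convention not in ("persons", "person-periods"):
            raise ValueError(f"unknown bic_convention {self.bic_convention!r}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        d["younger_cohorts"] = list(self.younger_cohorts)
        d["older_cohorts"] = list(self.older_cohorts)
        d["profiles"] = [dict(p) for p in self.profiles]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("analysis_window", "younger_cohorts", "older_cohorts", "profiles"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _drop_drug_only(panel: Panel) -> Panel:
    """Remove arrests carrying only drug charges (sensitivity filter)."""
    if not panel.has_charges:
        raise ValueError("panel has no charge-category columns")
    df = panel.data.copy()
    # every arrest carries >= 1 category, so an arrest with no
    # violence/property/other charge is drug-only; treating the non-drug
    # categories as non-overlapping bounds their arrest count from above,
    # which makes the removal conservative
    non_drug = np.minimum(df[["n_violence", "n_property", "n_other"]].sum(axis=1),
                          df["count"])
    drug_only = np.maximum(df["count"] - non_drug, 0)
    drug_only = np.minimum(drug_only, df["n_drugs"])
    df["count"] = df["count"] - drug_only
    df["n_drugs"] = df["n_drugs"] - drug_only
    for col in ("n_violence", "n_property", "n_other"):
        df[col] = np.minimum(df[col], df["count"])
    return Panel(df, windows=panel.windows.reset_index(), validate=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig, panel: Panel | None = None,
                 covariates: CovariateTable | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    ``panel``/``covariates`` may be passed in memory; otherwise they are
    read from the configured paths.  On any stage failure the partial
    outputs written so far are removed and the stage name is reported.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"

    def emit_csv(frame: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        frame.to_csv(path, float_format="%.10g", **kw)
        written.append(path)

    try:
        if panel is None:
            panel = read_panel(config.panel_path, dense_windows=config.dense_windows)
        if covariates is None and config.covariates_path:
            covariates = read_covariates(config.covariates_path)
        t0 = time.perf_counter()

        stage = "restrict_ages"
        panel = panel.restrict_ages(config.min_age, config.max_age)
        if config.drop_drug_only:
            panel = _drop_drug_only(panel)
        logger.info("stage=%s persons=%d", stage, panel.n_persons)

        stage = "select_model"
        grid = select_model(
            panel, covariates=covariates,
            J_range=range(config.j_min, config.j_max + 1),
            bases=(TrajectorySpec(degree=config.degree),),
            seed=config.seed, n_starts=config.n_starts,
            bic_convention=config.bic_convention,
            compute_se=covariates is not None,
        )
        best = grid.chosen.result
        logger.info("stage=%s chosen_J=%d loglik=%.3f", stage, grid.chosen.J, best.loglik)
        emit_csv(grid.table(), "selection_grid.csv", index=False)

        stage = "adequacy"
        adq = adequacy(best)
        emit_csv(adq.table, "adequacy.csv")

        # paths are environment, not analysis parameters: leave them out of
        # the report so identical analyses give identical bytes
        config_echo = {k: v for k, v in dataclasses.asdict(config).items()
                       if k not in ("panel_path", "covariates_path", "output_dir")}
        results: dict = {
            "schema_version": RESULTS_SCHEMA_VERSION,
            "config": json.loads(json.dumps(config_echo, default=_json_default)),
            "selection": {"chosen_J": grid.chosen.J,
                          "bic_convention": grid.bic_convention},
            "fit": best.to_dict(),
            "adequacy": {str(g): row for g, row
                         in adq.table.to_dict(orient="index").items()},
        }

        if covariates is not None and best.mixture.covariate_names:
            stage = "membership_effects"
            eff = membership_effects(best)
            emit_csv(eff.table, "membership_effects.csv")
            results["membership_effects"] = {
                f"group{g}:{t}": row for (g, t), row in
                eff.table.round(10).to_dict(orient="index").items()
            }
            if config.profiles:
                stage = "profile_probabilities"
                prof = profile_probabilities(best, list(config.profiles),
                                             at_means=config.at_means)
                emit_csv(prof.probs, "profile_probabilities.csv", index=False)
                results["profile_probabilities"] = [
                    {"profile": dict(p), "probs": list(map(float, row))}
                    for p, row in zip(prof.profiles, prof.probs.to_numpy())
                ]

        stage = "rate_table"
        merged = panel.map_cohorts(
            {**{c: "younger" for c in config.younger_cohorts},
             **{c: "older" for c in config.older_cohorts}})
        table = rate_table(merged, best.assignments, config.analysis_window,
                           by_offense=merged.has_charges)
        emit_csv(table.table, "rate_table.csv")
        results["rate_table"] = {
            f"group{g}:{c}": row for (g, c), row in
            table.table.round(10).to_dict(orient="index").items()
        }

        stage = "decompose"
        hard = best.assignments
        coh = merged.cohorts
        J = best.n_groups
        shares, rates = {}, {}
        for cls in ("younger", "older"):
            members = coh.index[coh == cls]
            g = hard.reindex(members)
            shares[cls] = np.array([(g == j).mean() for j in range(J)])
            tot = merged.person_totals(window=config.analysis_window).reindex(members)
            rates[cls] = np.array([
                tot[g == j].mean() if (g == j).any() else 0.0 for j in range(J)])
        dec = decompose(shares["younger"], rates["younger"],
                        shares["older"], rates["older"])
        results["decomposition"] = dec.to_dict()
        results["decomposition"]["shares_younger"] = shares["younger"].tolist()
        results["decomposition"]["shares_older"] = shares["older"].tolist()
        results["decomposition"]["rates_younger"] = rates["younger"].tolist()
        results["decomposition"]["rates_older"] = rates["older"].tolist()

        stage = "curves"
        emit_csv(best.rate_curve(), "trajectory_curves.csv")

        stage = "write_report"
        report = out / "results.json"
        report.write_text(json.dumps(results, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")
        written.append(report)
        logger.info("pipeline complete in %.1fs: %s", time.perf_counter() - t0, report)
        return results
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def load_report(path) -> dict:
    """Load a results JSON, failing loudly on a schema-version mismatch."""
    report = json.loads(Path(path).read_text())
    version = report.get("schema_version")
    if version != RESULTS_SCHEMA_VERSION:
        raise ValueError(
            f"results schema version {version!r} not supported "
            f"(expected {RESULTS_SCHEMA_VERSION})")
    return report
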