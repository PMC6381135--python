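"""End-to-end orchestration: simulate or ingest, score, exclude, summarize,
select a model family, run the regressions, infer strategies, and write every
table plus a reproducibility manifest.

All stages are individually importable; this module only wires them together
behind a :class:`RunConfig` (loadable from YAML) and takes care of file I/O,
stage logging and the run manifest.  Round-level data are 1-based in round
index; all CSVs are UTF-8 with header rows; missing values in analysis
columns are fatal (complete-case analysis throughout).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .automata import build_strategy_set
from .cohort import CohortSpec, generate_cohort
from .errors import ConfigurationError, InputError
from .inference import (
    bootstrap_se,
    fit_cohort,
    render_strategy_table,
    sfem_population,
    trait_strategy_correlations,
)
from .metrics import (
    CORRELATION_VARIABLES,
    correlation_matrix,
    render_correlation_table,
    summarize_participants,
)
from .models import (
    FULL_TERMS,
    TRAIT_TERMS,
    CVResult,
    ModelSpec,
    cv_select,
    fit_model,
    interaction_regressions,
    render_coefficient_table,
)
from .traits import IRS_CUTOFF

log = logging.getLogger("ipdcohort")

ROUND_COLUMNS = (
    "participant_id",
    "round",
    "condition",
    "game_version",
    "participant_action",
    "computer_action",
)
PARTICIPANT_COLUMNS = (
    "participant_id",
    "gender",
    "maximise",
    "fearless_dominance",
    "self_centred_impulsivity",
    "coldheartedness",
    "narcissism",
    "irs10",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    out_dir: str = "ipdcohort_out"
    seed: int = 0
    # synthetic-cohort route (used when rounds_csv is None)
    synthetic: dict = field(default_factory=dict)
    # ingestion route
    rounds_csv: str | None = None
    participants_csv: str | None = None
    column_map: dict = field(default_factory=dict)
    # analysis settings
    strategy_preset: str | list = "table6"
    dv_normalization: str = "total"
    irs_cutoff: int = IRS_CUTOFF
    cv_k: int = 5
    cv_repeats: int = 10
    bootstrap_B: int = 1000
    estimator: str = "posterior_mean"
    run_sfem: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_input(
    rounds_df: pd.DataFrame,
    participants_df: pd.DataFrame | None = None,
    rounds_total: int = 30,
) -> dict:
    """Schema and consistency checks; fatal errors vs non-fatal warnings.

    Fatal: missing columns, invalid action symbols, invalid gender codes.
    Warnings: participants with incomplete round counts, unbalanced condition
    cells.
    """
    fatal: list[str] = []
    warnings: list[str] = []
    missing = [c for c in ROUND_COLUMNS if c not in rounds_df.columns]
    if missing:
        fatal.append(f"round table missing columns {missing}")
    else:
        for col in ("participant_action", "computer_action"):
            bad = set(rounds_df[col].unique()) - {"C", "D"}
            if bad:
                fatal.append(f"invalid action symbols {sorted(map(str, bad))} in {col}")
        bad_cond = set(rounds_df["condition"].unique()) - {1, 2, 3, 4}
        if bad_cond:
            fatal.append(f"invalid condition ids {sorted(bad_cond)}")
        counts = rounds_df.groupby("participant_id")["round"].count()
        short = counts[counts != rounds_total]
        for pid, c in short.items():
            warnings.append(f"participant {pid} has {c} rounds (expected {rounds_total})")
        cells = rounds_df.drop_duplicates("participant_id").groupby(
            ["condition", "game_version"]
        ).size()
        if len(cells) and cells.max() - cells.min() > 1:
            warnings.append(
                f"condition x game-version cells unbalanced (sizes {cells.min()}..{cells.max()})"
            )
    if participants_df is not None:
        pmissing = [c for c in PARTICIPANT_COLUMNS if c not in participants_df.columns]
        if pmissing:
            fatal.append(f"participant table missing columns {pmissing}")
        elif not set(participants_df["gender"].unique()) <= {1, 2}:
            bad = sorted(set(participants_df["gender"].unique()) - {1, 2})
            fatal.append(f"invalid gender codes {bad} (codes are 1=female, 2=male)")
    report = {"fatal": fatal, "warnings": warnings, "ok": not fatal}
    if fatal:
        raise InputError("input validation failed: " + "; ".join(fatal))
    return report


def _load_csv(path: str, column_map: dict) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"input file not found: {p}")
    df = pd.read_csv(p)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle; returns the results.

    Stages: simulate/ingest -> validate -> exclude -> metrics -> CV model
    selection -> trait & full regressions -> interaction regressions ->
    strategy inference (per-subject, bootstrap, trait correlations, optional
    population cross-check) -> manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    warnings: list[str] = []

    # -- stage: data ------------------------------------------------------
    if config.rounds_csv is None:
        spec = CohortSpec(rng_seed=config.seed, **config.synthetic)
        _, participants_df, rounds_df, cohort_manifest = generate_cohort(spec)
        log.info("simulated cohort: %d participants", len(participants_df))
    else:
        rounds_df = _load_csv(config.rounds_csv, config.column_map)
        if config.participants_csv is None:
            raise ConfigurationError("participants_csv is required when ingesting data")
        participants_df = _load_csv(config.participants_csv, config.column_map)
        cohort_manifest = {"source": config.rounds_csv}
        if "positive_feedback" not in participants_df.columns:
            from .models import factorial_encoding

            enc = participants_df["condition"].map(lambda c: factorial_encoding(int(c)))
            participants_df["positive_feedback"] = [e[0] for e in enc]
            participants_df["negative_feedback"] = [e[1] for e in enc]
        if "sum_psychopathic_traits" not in participants_df.columns:
            participants_df["sum_psychopathic_traits"] = (
                participants_df["fearless_dominance"]
                + participants_df["self_centred_impulsivity"]
                + participants_df["coldheartedness"]
            )
    report = validate_input(rounds_df, participants_df)
    warnings.extend(report["warnings"])
    stage_counts["participants_in"] = len(participants_df)
    stage_counts["rounds_in"] = len(rounds_df)

    # -- stage: exclusion -------------------------------------------------
    retained_mask = participants_df["irs10"] < config.irs_cutoff
    excluded = int((~retained_mask).sum())
    participants_df = participants_df[retained_mask].reset_index(drop=True)
    rounds_df = rounds_df[rounds_df["participant_id"].isin(participants_df["participant_id"])]
    stage_counts["excluded_irs"] = excluded
    stage_counts["participants_retained"] = len(participants_df)
    log.info("IRS-10 exclusion (cutoff %d): %d removed, %d retained",
             config.irs_cutoff, excluded, len(participants_df))
    participants_df.to_csv(out / "participants.csv", index=False)
    rounds_df.to_csv(out / "rounds.csv", index=False)

    # -- stage: metrics ---------------------------------------------------
    summaries = summarize_participants(rounds_df, participants_df, config.dv_normalization)
    summaries["rounds_for_dv"] = summaries["rounds"]
    summaries.to_csv(out / "participant_summaries.csv", index=False)
    corr_vars = [v for v in CORRELATION_VARIABLES if v in summaries.columns]
    r, p, stars = correlation_matrix(summaries, corr_vars)
    r.to_csv(out / "correlations.csv")
    (out / "correlations.txt").write_text(render_correlation_table(r, stars) + "\n")

    # -- stage: model selection ------------------------------------------
    cv_results: dict[str, CVResult] = {}
    regression_fits = {}
    for dv in ("cooperation", "cac_proportion"):
        specs = [
            ModelSpec("gaussian_identity", dv, FULL_TERMS),
            ModelSpec("binomial_logit", dv, FULL_TERMS),
            ModelSpec("beta_binomial", dv, FULL_TERMS),
        ]
        cv = cv_select(specs, summaries, k=config.cv_k, repeats=config.cv_repeats,
                       seed=config.seed)
        cv_results[dv] = cv
        log.info("CV selected %s for %s (MSE %s)", cv.chosen_family, dv, cv.mean_error)
        regression_fits[f"{dv} (traits only)"] = fit_model(
            ModelSpec(cv.chosen_family, dv, TRAIT_TERMS), summaries
        )
        regression_fits[f"{dv} (full)"] = fit_model(cv.chosen_spec, summaries)
    (out / "cv_selection.json").write_text(
        json.dumps(
            {
                dv: {
                    "chosen_family": cv.chosen_family,
                    "mean_error": cv.mean_error,
                    "k": cv.k,
                    "repeats": cv.repeats,
                    "seed": cv.seed,
                }
                for dv, cv in cv_results.items()
            },
            indent=2,
        )
    )
    coef_rows = []
    for label, fit in regression_fits.items():
        for term in fit.params.index:
            coef_rows.append(
                {
                    "model": label,
                    "family": fit.family,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "p": fit.pvalues[term],
                }
            )
    pd.DataFrame(coef_rows).to_csv(out / "regression_coefficients.csv", index=False)
    (out / "regression_table.txt").write_text(render_coefficient_table(regression_fits) + "\n")

    interactions = interaction_regressions(summaries)
    interactions.to_csv(out / "interaction_regressions.csv", index=False)

    # -- stage: strategy inference ---------------------------------------
    strategies = build_strategy_set(config.strategy_preset)
    fits = fit_cohort(rounds_df, strategies)
    n_degenerate = sum(f.degenerate for f in fits)
    if n_degenerate:
        warnings.append(f"{n_degenerate} subject fits degenerate (uniform weights)")
    fit_rows = []
    for f in fits:
        for s, w in zip(f.strategy_names, f.weights):
            fit_rows.append(
                {
                    "participant_id": f.participant_id,
                    "strategy": s,
                    "weight": w,
                    "gamma_hat": f.gamma_hat,
                    "loglik": f.loglik,
                    "best_strategy": f.best_strategy,
                }
            )
    pd.DataFrame(fit_rows).to_csv(out / "subject_fits.csv", index=False)

    est = bootstrap_se(fits, B=config.bootstrap_B, seed=config.seed,
                       estimator=config.estimator)
    corr = trait_strategy_correlations(fits, participants_df, estimator=config.estimator)
    corr.to_csv(out / "trait_strategy_correlations.csv", index=False)
    (out / "strategy_estimates.json").write_text(json.dumps(est.as_dict(), indent=2))
    (out / "strategy_table.txt").write_text(render_strategy_table(est, corr) + "\n")

    results = {
        "cv": cv_results,
        "regressions": regression_fits,
        "interactions": interactions,
        "correlations": (r, p, stars),
        "strategy_estimate": est,
        "trait_strategy_correlations": corr,
        "summaries": summaries,
        "fits": fits,
    }
    if config.run_sfem:
        pop = sfem_population(fits, seed=config.seed)
        results["sfem"] = pop
        (out / "sfem_population.json").write_text(
            json.dumps(
                {
                    "phi": dict(zip(pop.strategy_names, map(float, pop.phi))),
                    "gamma": pop.gamma,
                    "loglik": pop.loglik,
                    "converged": pop.converged,
                },
                indent=2,
            )
        )

    # -- manifest ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "cohort": cohort_manifest,
        "stage_counts": stage_counts,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
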