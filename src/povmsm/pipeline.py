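"""End-to-end orchestration: simulate -> derive -> impute -> weight ->
estimate (+ transitions, strata, FE comparison), with run manifests.

Every stochastic stage is seeded deterministically from the global seed by
stable hashing of the stage name, so adding a stage never perturbs earlier
stages' draws, and the same config yields byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .derive import build_analysis_table, derive_poverty, write_table
from .effects import (
    BootstrapConfig,
    EffectEstimate,
    OutcomeModelSpec,
    _pipeline_closure,
    bootstrap_estimate,
    crude_estimate,
    estimate_stratified,
    estimate_transitions,
)
from .errors import InvalidConfigError, SchemaError
from .felogit import fit_conditional_logit
from .impute import ImputationSpec, exclude_high_missingness, mice_impute, pool_rubin
from .simulate import SimulationConfig, generate_panel, impose_missingness, scenario
from .weights import (
    ExposureModelSpec,
    balance_table,
    compute_stabilized_weights,
    love_plot,
)

ALL_STAGES = ("simulate", "derive", "impute", "weight", "estimate",
              "transitions", "strata", "fe-compare")


@dataclass
class RunConfig:
    scenario: str = "default"
    n_individuals: int = 5000
    n_waves: int = 6
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "derive", "weight", "estimate")
    data_path: str | None = None         # read a panel CSV instead of simulating
    output_dir: str = "results"
    simulation_overrides: dict = field(default_factory=dict)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    exposure_model: ExposureModelSpec = field(default_factory=ExposureModelSpec)
    outcome_model: OutcomeModelSpec = field(default_factory=OutcomeModelSpec)
    bootstrap: BootstrapConfig | None = None
    stratifiers: tuple[str, ...] = ("gender", "education", "age-group")
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.bootstrap is not None:
            d["bootstrap"] = dataclasses.asdict(self.bootstrap)
        d["imputation"] = dataclasses.asdict(self.imputation)
        d["exposure_model"] = dataclasses.asdict(self.exposure_model)
        d["outcome_model"] = dataclasses.asdict(self.outcome_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("bootstrap"):
            d["bootstrap"] = BootstrapConfig(**d["bootstrap"])
        if "imputation" in d:
            imp = dict(d["imputation"])
            for k in ("analysis_variables", "log_transform", "interactions"):
                if k in imp and imp[k] is not None:
                    imp[k] = tuple(tuple(x) if isinstance(x, list) else x
                                   for x in imp[k])
            d["imputation"] = ImputationSpec(**imp)
        if "exposure_model" in d:
            em = dict(d["exposure_model"])
            for k in ("denominator", "numerator"):
                if k in em:
                    em[k] = tuple(em[k])
            if em.get("truncation"):
                em["truncation"] = tuple(em["truncation"])
            d["exposure_model"] = ExposureModelSpec(**em)
        if "outcome_model" in d:
            om = dict(d["outcome_model"])
            if "covariates" in om:
                om["covariates"] = tuple(om["covariates"])
            d["outcome_model"] = OutcomeModelSpec(**om)
        for k in ("stages", "stratifiers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name mixed with the
    global seed (stable across runs and process restarts)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    balance: pd.DataFrame | None
    manifest: dict
    warnings: list[str]
    output_dir: Path


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the configured stages and persist the results bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "povmsm": __version__,
        },
    }

    # --- simulate ---------------------------------------------------------
    if config.data_path is not None:
        panel = pd.read_csv(config.data_path)
    else:
        sim_cfg = scenario(
            config.scenario, config.n_individuals,
            seed=stage_seed(config.seed, "simulate"),
            n_waves=config.n_waves, **config.simulation_overrides,
        )
        panel = generate_panel(sim_cfg)
        if sim_cfg.missingness.rate > 0:
            panel, _ = impose_missingness(panel, sim_cfg)
        if "simulate" in config.stages:
            write_table(panel, out / "panel.csv", out / "codebook.txt")
    if set(config.stages) == {"simulate"}:
        _write_manifest(manifest, out)
        return ResultsBundle(pd.DataFrame(), None, manifest, warnings_log, out)

    # --- impute or complete-case -----------------------------------------
    if "impute" in config.stages and panel.isna().any().any():
        panel, excl = exclude_high_missingness(panel, config.imputation)
        spec = dataclasses.replace(
            config.imputation, seed=stage_seed(config.seed, "impute")
        )
        stack = mice_impute(panel, spec)
        panels = stack.datasets
        stack.trace.to_csv(out / "mi_trace.csv", index=False)
        excl.to_csv(out / "mi_exclusions.csv", index=False)
        manifest["imputation"] = {"m": stack.m, "n_excluded": len(excl)}
    else:
        cc = panel.dropna() if panel.isna().any().any() else panel
        if len(cc) < len(panel):
            warnings_log.append(
                f"complete-case analysis: dropped {len(panel) - len(cc)} rows"
            )
        panels = [cc]

    # --- derive / weight / estimate per dataset ---------------------------
    per_dataset_rows: list[list[dict]] = []
    balance = None
    for i, pnl in enumerate(panels):
        at = build_analysis_table(derive_poverty(pnl))
        if "derive" in config.stages and i == 0:
            write_table(at, out / "analysis_table.csv", out / "codebook.txt")
        rows = []
        if {"weight", "estimate", "transitions", "strata"} & set(config.stages):
            ws = compute_stabilized_weights(at, config.exposure_model)
            if i == 0:
                balance = balance_table(at, ws)
                balance.to_csv(out / "balance.csv", index=False)
                love_plot(balance, out / "love_plot.png")
                with open(out / "weight_summary.json", "w") as fh:
                    json.dump(ws.summary, fh, indent=2)
                if not 0.9 <= ws.summary["mean"] <= 1.1:
                    warnings_log.append(
                        f"mean stabilized weight {ws.summary['mean']:.3f}"
                    )
        boot = config.bootstrap
        if boot is not None:
            boot = dataclasses.replace(
                boot, seed=stage_seed(config.seed, f"bootstrap{i}")
            )
        if "estimate" in config.stages:
            closure = _pipeline_closure(
                config.exposure_model, config.outcome_model, "binary", "overall"
            )
            est = closure(at) if boot is None else bootstrap_estimate(
                at, closure, boot
            )
            est.metadata["crude_rd"] = crude_estimate(at)
            rows.append(est.to_row())
        if "transitions" in config.stages:
            for estimand in ("into", "outof"):
                est = estimate_transitions(
                    at, estimand, config.exposure_model, config.outcome_model,
                    boot,
                )
                rows.append(est.to_row())
        if "strata" in config.stages:
            estimands = ["binary"]
            if "transitions" in config.stages:
                estimands += ["into", "outof"]
            for strat in config.stratifiers:
                for estimand in estimands:
                    for est in estimate_stratified(
                        at, strat, estimand, config.exposure_model,
                        config.outcome_model, boot,
                    ):
                        rows.append(est.to_row())
        if "fe-compare" in config.stages:
            covs = [c for c in config.outcome_model.covariates
                    if c not in ("gender", "ethnicity", "education")]
            for label, fe_covs in (
                ("fe_conditional_adjusted", covs),
                ("fe_conditional_unadjusted", ["wave"]),
            ):
                fe = fit_conditional_logit(
                    at, fe_covs, report_probability_contrast=True,
                )
                rows.append(
                    {
                        "estimand": label, "stratum": "overall",
                        "rd": fe.prob_contrast_at_zero_fe, "or": fe.or_exposure,
                        "prev_unexposed": np.nan, "prev_total": np.nan,
                        "paf": np.nan,
                        "n_individuals": fe.n_informative,
                        "n_observations": len(at),
                        "or_se": float(np.exp(fe.params["poverty"])
                                       * fe.bse()["poverty"])
                        if "poverty" in fe.names else np.nan,
                    }
                )
        per_dataset_rows.append(rows)

    # --- pool across imputed datasets -------------------------------------
    if len(per_dataset_rows) == 1:
        results = pd.DataFrame(per_dataset_rows[0])
    else:
        results = _pool_results(per_dataset_rows)
    results.to_csv(out / "results.csv", index=False)
    _write_manifest(manifest, out)
    return ResultsBundle(results, balance, manifest, warnings_log, out)


def _pool_results(per_dataset_rows: list[list[dict]]) -> pd.DataFrame:
    """Rubin-pool the per-imputed-dataset result rows (matched by position)."""
    n_rows = len(per_dataset_rows[0])
    pooled = []
    for r in range(n_rows):
        rows = [d[r] for d in per_dataset_rows]
        base = dict(rows[0])
        for key in ("rd", "or", "prev_unexposed", "paf"):
            ests = [row[key] for row in rows]
            ses = [row.get(f"{key}_se", np.nan) for row in rows]
            if any(np.isnan(ses)):
                base[key] = float(np.mean(ests))
                continue
            pr = pool_rubin(ests, [s**2 for s in ses])
            base[key] = pr.point
            base[f"{key}_se"] = pr.se
            base[f"{key}_ci_lo"], base[f"{key}_ci_hi"] = pr.ci
        pooled.append(base)
    return pd.DataFrame(pooled)


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def report(bundle: ResultsBundle) -> str:
    """Human-readable summary of a results bundle."""
    res = bundle.results
    required = {"estimand", "stratum", "rd"}
    if len(res) and not required <= set(res.columns):
        raise SchemaError(f"results table lacks {sorted(required - set(res.columns))}")
    lines = ["Causal effect estimates of poverty on common mental disorder",
             "=" * 62]
    if len(res):
        for _, row in res.iterrows():
            ci = ""
            if not pd.isna(row.get("rd_ci_lo", np.nan)):
                ci = f" (95% CI {row['rd_ci_lo']:.2f}, {row['rd_ci_hi']:.2f})"
            lines.append(
                f"{row['estimand']:<12} {row['stratum']:<22} "
                f"RD {row['rd']:6.2f}pp{ci}  OR {row.get('or', np.nan):5.2f}  "
                f"PAF {row.get('paf', np.nan):6.2f}%"
            )
    if bundle.balance is not None:
        worst = bundle.balance["smd_weighted"].abs().max()
        lines.append("")
        lines.append(f"Balance: max weighted |SMD| = {worst:.3f} "
                     f"({'good' if worst < 0.1 else 'CHECK'})")
    if bundle.warnings:
        lines.append("")
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in bundle.warnings)
    return "\n".join(lines)
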