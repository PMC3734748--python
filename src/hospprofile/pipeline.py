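"""End-to-end orchestration: generate -> adjust -> fit -> profile -> agree.

A run is fully determined by its :class:`RunConfig` (all seeds are
explicit), and every stage writes its artifact under the output
directory before the next stage starts, so a failed run leaves partial
outputs behind.  The manifest records the config hash, seeds and stage
statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from hospprofile import agreement as agr
from hospprofile import bayes, casemix, cohort, profiling

log = logging.getLogger("hospprofile")

METHODS = ("fixed_ramr", "fixed_rank", "hierarchical_ramr", "hierarchical_rank")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    cohort: cohort.CohortConfig | str = field(default_factory=cohort.CohortConfig)
    exclusions: casemix.ExclusionRules = field(default_factory=casemix.ExclusionRules)
    fixed_model: bayes.ModelSpec = field(default_factory=lambda: bayes.ModelSpec(kind="fixed"))
    hierarchical_model: bayes.ModelSpec = field(
        default_factory=lambda: bayes.ModelSpec(kind="hierarchical")
    )
    mcmc: bayes.McmcConfig = field(default_factory=bayes.McmcConfig)
    profiling: profiling.ProfilingConfig = field(default_factory=profiling.ProfilingConfig)
    mu30_override: float | None = None  # None: compute from the analysed cohort
    output_dir: str = "hospprofile_run"
    write_draws: bool = True


@dataclass
class RunResult:
    config: RunConfig
    cohort: pd.DataFrame
    truth: cohort.TrueParameters | None
    filtered: pd.DataFrame
    exclusion_report: casemix.ExclusionReport
    risk_model: casemix.RiskModel
    summaries: pd.DataFrame
    mu30: float
    draws: dict[str, bayes.PosteriorDraws]
    convergence: dict[str, bayes.ConvergenceReport]
    profiles: dict[str, pd.DataFrame]
    labels: dict[str, list[str]]
    agreement: dict[tuple[str, str], tuple[agr.CrossTab, agr.AgreementResult]]
    manifest: dict[str, Any]


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a declarative YAML file; missing sections
    fall back to the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    if "cohort" in raw:
        c = raw["cohort"]
        kwargs["cohort"] = c if isinstance(c, str) else cohort.CohortConfig(**c)
    for key, cls in (
        ("exclusions", casemix.ExclusionRules),
        ("fixed_model", bayes.ModelSpec),
        ("hierarchical_model", bayes.ModelSpec),
        ("mcmc", bayes.McmcConfig),
        ("profiling", profiling.ProfilingConfig),
    ):
        if key in raw:
            section = dict(raw[key])
            for name, value in section.items():
                if isinstance(value, list):
                    section[name] = tuple(value)
            kwargs[key] = cls(**section)
    for key in ("mu30_override", "output_dir", "write_draws"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as err:  # noqa: BLE001 - abort with stage name
                raise StageError(name, err) from err

        return wrapped

    return deco


def cohort_mu30(filtered: pd.DataFrame) -> float:
    """Overall 30-day mortality of the analysed complete cases, percent."""
    cc = filtered[filtered["died_30d"].notna()]
    return 100.0 * float(cc["died_30d"].astype(int).mean())


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config_hash(config),
        "config": _to_plain(config),
        "stages": {},
        "outputs": {},
    }

    # --- generate / load -------------------------------------------------
    @_stage("generate")
    def _generate():
        if isinstance(config.cohort, str):
            frame = cohort.read_cohort(config.cohort)
            return frame, None, None
        frame, truth = cohort.generate_cohort(config.cohort)
        return frame, truth, config.cohort.seed

    frame, truth, seed = _generate()
    cohort_path = out / "cohort.csv"
    cohort.write_cohort(frame, truth, cohort_path, seed=seed)
    manifest["outputs"]["cohort"] = cohort_path.name
    manifest["stages"]["generate"] = {"patients": len(frame), "seed": seed}
    log.info("generate: %d patients, %d hospitals", len(frame), frame["hospital_id"].nunique())

    # --- adjust -----------------------------------------------------------
    @_stage("adjust")
    def _adjust():
        filtered, report = casemix.apply_exclusions(frame, config.exclusions)
        edges = casemix.derive_bands(filtered)
        model = casemix.fit_risk_model(filtered, edges)
        summaries = casemix.expected_deaths(filtered, model)
        return filtered, report, model, summaries

    filtered, report, risk_model, summaries = _adjust()
    summaries_path = out / "hospital_summaries.csv"
    summaries.to_csv(summaries_path, index=False)
    (out / "exclusions.log").write_text("\n".join(report.lines()) + "\n")
    manifest["outputs"]["summaries"] = summaries_path.name
    manifest["stages"]["adjust"] = {
        "patients_in": report.patients_in,
        "patients_out": report.patients_out,
        "hospitals_retained": report.hospitals_out,
        "c_statistic": risk_model.c_statistic,
    }
    for line in report.lines():
        log.info(line)

    mu30 = config.mu30_override if config.mu30_override is not None else cohort_mu30(filtered)
    prof_config = replace(config.profiling, mu30=mu30)
    manifest["stages"]["adjust"]["mu30"] = mu30

    # --- fit --------------------------------------------------------------
    @_stage("fit")
    def _fit():
        draws = {
            "fixed": bayes.fit_fixed_model(summaries, config.fixed_model, config.mcmc),
            "hierarchical": bayes.fit_hierarchical_model(
                summaries, config.hierarchical_model, config.mcmc
            ),
        }
        conv = {k: bayes.gelman_rubin(d) for k, d in draws.items()}
        return draws, conv

    draws, convergence = _fit()
    conv_lines = []
    for kind, rep in convergence.items():
        conv_lines += [f"[{kind}] {line}" for line in rep.lines()]
    (out / "convergence.txt").write_text("\n".join(conv_lines) + "\n")
    if config.write_draws:
        for kind, d in draws.items():
            p = out / f"draws_{kind}.csv"
            d.write(p)
            manifest["outputs"][f"draws_{kind}"] = p.name
    manifest["stages"]["fit"] = {
        "retained_per_chain": config.mcmc.n_retained,
        "combined_draws": config.mcmc.n_retained * config.mcmc.n_chains,
        "seed": config.mcmc.seed,
        "max_r_hat": {k: rep.max_r_hat() for k, rep in convergence.items()},
    }
    log.info("fit: %d combined draws per model", config.mcmc.n_retained * config.mcmc.n_chains)

    # --- profile ----------------------------------------------------------
    @_stage("profile")
    def _profile():
        profiles = {
            kind: profiling.build_profiles(summaries, d, prof_config)
            for kind, d in draws.items()
        }
        return profiles

    profiles = _profile()
    for kind, prof in profiles.items():
        p = out / f"profiles_{kind}.csv"
        prof.to_csv(p, index=False)
        manifest["outputs"][f"profiles_{kind}"] = p.name
    scatter = pd.DataFrame(
        {
            "hospital_id": profiles["fixed"]["hospital_id"],
            "ramr_median_fixed": profiles["fixed"]["ramr_median"],
            "ramr_median_hierarchical": profiles["hierarchical"]["ramr_median"],
            "rank_median_fixed": profiles["fixed"]["rank_median"],
            "rank_median_hierarchical": profiles["hierarchical"]["rank_median"],
        }
    )
    scatter.to_csv(out / "model_comparison_scatter.csv", index=False)
    manifest["outputs"]["scatter"] = "model_comparison_scatter.csv"

    labels = {
        "fixed_ramr": profiles["fixed"]["ramr_label"].tolist(),
        "fixed_rank": profiles["fixed"]["rank_label"].tolist(),
        "hierarchical_ramr": profiles["hierarchical"]["ramr_label"].tolist(),
        "hierarchical_rank": profiles["hierarchical"]["rank_label"].tolist(),
    }
    manifest["stages"]["profile"] = {
        m: {lab: labs.count(lab) for lab in profiling.LABELS} for m, labs in labels.items()
    }

    # --- agree ------------------------------------------------------------
    @_stage("agree")
    def _agree():
        return agr.pairwise_comparisons(labels)

    comparisons = _agree()
    rows, blocks = [], []
    for (a, b), (tab, res) in comparisons.items():
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "observed_agreement": res.observed_agreement,
                "weighted_agreement": res.weighted_agreement,
                "expected_weighted_agreement": res.expected_weighted_agreement,
                "kappa": res.kappa,
                "qualitative": res.qualitative,
            }
        )
        blocks.append(agr.format_pair_report((a, b), tab, res))
    pd.DataFrame(rows).to_csv(out / "agreement.csv", index=False)
    (out / "agreement.txt").write_text("\n\n".join(blocks) + "\n")
    manifest["outputs"]["agreement"] = "agreement.csv"
    manifest["stages"]["agree"] = {f"{a}|{b}": r["kappa"] for (a, b), r in zip(comparisons, rows)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunResult(
        config=config,
        cohort=frame,
        truth=truth,
        filtered=filtered,
        exclusion_report=report,
        risk_model=risk_model,
        summaries=summaries,
        mu30=mu30,
        draws=draws,
        convergence=convergence,
        profiles=profiles,
        labels=labels,
        agreement=comparisons,
        manifest=manifest,
    )


_SENSITIVITY_KEYS = ("delta", "hyper_precision_prior")


def sensitivity_rerun(
    result: RunResult, overrides: dict[str, Any], output_dir: str | Path | None = None
) -> pd.DataFrame:
    """Re-profile a completed run under altered choices and tabulate
    label changes per hospital.

    Supported overrides: ``delta`` (reclassification threshold) and
    ``hyper_precision_prior`` (refits the hierarchical model).
    """
    unknown = set(overrides) - set(_SENSITIVITY_KEYS)
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")

    config = result.config
    prof_config = replace(config.profiling, mu30=result.mu30)
    if "delta" in overrides:
        prof_config = replace(prof_config, delta=float(overrides["delta"]))

    draws = dict(result.draws)
    if "hyper_precision_prior" in overrides:
        new_spec = replace(
            config.hierarchical_model,
            hyper_precision_prior=overrides["hyper_precision_prior"],
        )
        draws["hierarchical"] = bayes.fit_hierarchical_model(
            result.summaries, new_spec, config.mcmc
        )

    profiles = {
        kind: profiling.build_profiles(result.summaries, d, prof_config)
        for kind, d in draws.items()
    }
    new_labels = {
        "fixed_ramr": profiles["fixed"]["ramr_label"].tolist(),
        "fixed_rank": profiles["fixed"]["rank_label"].tolist(),
        "hierarchical_ramr": profiles["hierarchical"]["ramr_label"].tolist(),
        "hierarchical_rank": profiles["hierarchical"]["rank_label"].tolist(),
    }

    records = []
    hospital_ids = profiles["fixed"]["hospital_id"].tolist()
    for method in METHODS:
        before, after = result.labels[method], new_labels[method]
        for hid, b, a in zip(hospital_ids, before, after):
            records.append(
                {
                    "hospital_id": hid,
                    "method": method,
                    "label_before": b,
                    "label_after": a,
                    "changed": b != a,
                }
            )
    comparison = pd.DataFrame(records)
    if output_dir is not None:
        p = Path(output_dir)
        p.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(p / "sensitivity_label_changes.csv", index=False)
    return comparison
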