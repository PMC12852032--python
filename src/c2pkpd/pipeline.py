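"""End-to-end orchestration: configuration, seeds, manifests, replications.

All randomness flows from one root seed: each pipeline stage derives a
named child seed from (root seed, stage name), so stages are individually
reproducible.  Every artifact directory receives a manifest recording the
configuration hash and the per-stage seeds; re-running from the same
manifest reproduces all CSV/JSON outputs byte-identically.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .nca import ConcProfile, nca_iv_bolus
from .outcomes import fit_day3, fit_longitudinal, wald_contrast
from .population import (
    EventDataset,
    PopulationModel,
    SAEMOptions,
    saem_fit,
    visual_predictive_check,
)
from .regimen import evaluate_regimen, suppression_duration, total_c2_fold_change
from .synthetic import (
    OutcomeArm,
    OutcomeStudyDesign,
    PKStudyDesign,
    default_generator_config,
    generate_pkpd_study,
    generate_transplant_outcomes,
)
from .tmdd import Regimen, TMDDParams, expand_regimen, simulate_individual

__all__ = [
    "RunManifest",
    "ConfigError",
    "load_config",
    "build_model",
    "build_pk_design",
    "build_outcome_design",
    "parse_doses",
    "child_seed",
    "run_pkpd_replication",
    "run_transplant_replication",
]


class ConfigError(ValueError):
    pass


def child_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    ss = np.random.SeedSequence([int(root), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _default_config() -> dict:
    model, pk_design, outcome_design = default_generator_config()
    return {
        "model": {
            "params": dataclasses.asdict(model.theta),
            "omega": dict(model.omega),
            "sigma_prop": dict(model.sigma_prop),
            "lloq": dict(model.lloq),
        },
        "pk_design": {
            "dose_groups": list(pk_design.dose_groups),
            "n_per_group": pk_design.n_per_group,
            "sample_times": list(pk_design.sample_times),
            "baseline_times": list(pk_design.baseline_times),
            "observables": list(pk_design.observables),
            "lloq": dict(pk_design.lloq),
        },
        "outcome_design": {
            "days": list(outcome_design.days),
            "n_treated": list(outcome_design.n_treated),
            "n_control": list(outcome_design.n_control),
            "arms": {
                name: dataclasses.asdict(arm)
                for name, arm in outcome_design.arms.items()
            },
        },
        "saem": {"K1": 300, "K2": 200, "n_mcmc": 3, "chains": 1, "rtol": 1e-8},
        "vpc": {"n_sim": 100},
        "regimen": {"doses": "0:50,3:25", "n": 1000, "horizon": 14.0, "threshold": 5.0},
        "replicate": {"n_replicates": 1, "single_doses": [2, 5, 10, 25, 50]},
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the frozen defaults."""
    cfg = _default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_model(cfg: dict) -> PopulationModel:
    m = cfg["model"]
    return PopulationModel(
        theta=TMDDParams(**m["params"]),
        omega={k: float(v) for k, v in m["omega"].items()},
        sigma_prop={k: float(v) for k, v in m["sigma_prop"].items()},
        estimate_flags=dict(m.get("estimate_flags", {})),
        lloq={k: float(v) for k, v in m["lloq"].items()},
    )


def build_pk_design(cfg: dict) -> PKStudyDesign:
    d = cfg["pk_design"]
    return PKStudyDesign(
        dose_groups=tuple(float(x) for x in d["dose_groups"]),
        n_per_group=int(d["n_per_group"]),
        sample_times=tuple(float(x) for x in d["sample_times"]),
        baseline_times=tuple(float(x) for x in d["baseline_times"]),
        observables=tuple(d["observables"]),
        lloq={k: float(v) for k, v in d["lloq"].items()},
    )


def build_outcome_design(cfg: dict) -> OutcomeStudyDesign:
    d = cfg["outcome_design"]
    arms = {
        name: OutcomeArm(
            control_geomean=tuple(float(x) for x in a["control_geomean"]),
            treated_multiplier=tuple(float(x) for x in a["treated_multiplier"]),
            log_sd_control=float(a["log_sd_control"]),
            log_sd_treated=float(a["log_sd_treated"]),
            rho=float(a["rho"]),
            structure=a["structure"],
        )
        for name, a in d["arms"].items()
    }
    return OutcomeStudyDesign(
        days=tuple(float(x) for x in d["days"]),
        n_treated=tuple(int(x) for x in d["n_treated"]),
        n_control=tuple(int(x) for x in d["n_control"]),
        arms=arms,
    )


def parse_doses(spec: str) -> Regimen:
    """Parse ``"0:50,3:25"`` (day:mg/kg pairs) into a regimen."""
    events = []
    if spec.strip():
        for part in spec.split(","):
            try:
                t, a = part.split(":")
                events.append((float(t), float(a)))
            except ValueError as exc:
                raise ConfigError(f"bad dose spec {part!r}; expected day:amount") from exc
    return expand_regimen(events)


@dataclass
class RunManifest:
    """Reproducibility record written next to every artifact set."""

    config_hash: str
    root_seed: int
    stage_seeds: dict
    version: str = field(default_factory=lambda: __version__)
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def nca_linear_check(model: PopulationModel, design: PKStudyDesign) -> dict:
    """NCA on noise-free, binding-free typical profiles at each dose.

    With kon = 0 the antibody sub-model is linear, so AUC∞ = dose/CL and
    the log(AUC)–log(dose) slope measures dose-proportionality of the
    NCA pipeline itself.
    """
    params = model.theta.with_updates(kon=0.0)
    times = np.asarray(design.sample_times, dtype=float)
    results = {}
    for dose in design.dose_groups:
        if dose <= 0:
            continue
        prof = simulate_individual(
            params, expand_regimen([(0.0, dose)], duration=params.Tinf), times
        )
        res = nca_iv_bolus(ConcProfile(times=times, concs=prof.mab_total, dose=dose))
        results[dose] = res
    doses = sorted(results)
    if len(doses) >= 2:
        x = np.log([d for d in doses])
        y = np.log([results[d].auc_inf for d in doses])
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float("nan")
    half_life = results[doses[-1]].t_half if doses else float("nan")
    return {
        "half_life_days": float(half_life),
        "dose_prop_slope": slope,
        "per_dose": {
            f"{d:g}": dataclasses.asdict(results[d]) for d in doses
        },
    }


def nca_observed(dataset: EventDataset, design: PKStudyDesign) -> pd.DataFrame:
    """Per-animal NCA of the observed antibody concentrations."""
    rows = []
    for id_ in dataset.ids():
        di = dataset.individual(id_)
        doses = di[(di["evid"] == 1) & (di["amt"] > 0)]
        if doses.empty:
            continue
        dose = float(doses["amt"].iloc[0])
        obs = di[(di["evid"] == 0) & (di["observable"] == "mab_total") & (di["time"] >= 0)]
        obs = obs.sort_values("time")
        if len(obs) < 3:
            continue
        prof = ConcProfile(
            times=obs["time"].to_numpy(float),
            concs=obs["dv"].to_numpy(float),
            dose=dose,
            blq=obs["blq"].to_numpy(float) > 0,
        )
        try:
            res = nca_iv_bolus(prof)
        except Exception:
            continue
        row = {"id": id_, "dose": dose}
        row.update(dataclasses.asdict(res))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pkpd_replication(
    config: dict, seed: int, out_dir=None, *, dry_run: bool = False
) -> dict:
    """Turnkey PK/PD replication: generate → NCA → SAEM → VPC → regimens.

    Returns the report dict; when ``out_dir`` is given, writes dataset,
    truth, NCA table, VPC bands, report and manifest there.
    """
    model = build_model(config)
    design = build_pk_design(config)
    stages = ["generate", "fit", "vpc", "regimen"]
    seeds = {s: child_seed(seed, s) for s in stages}
    manifest = RunManifest(config_hash=config_hash(config), root_seed=seed, stage_seeds=seeds)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    if dry_run:
        if out is not None:
            manifest.write(out / "manifest.json")
        return {"dry_run": True, "stage_seeds": seeds}

    dataset, truth = generate_pkpd_study(model, design, seeds["generate"], return_truth=True)
    linear = nca_linear_check(model, design)
    nca_table = nca_observed(dataset, design)

    saem_cfg = config["saem"]
    options = SAEMOptions(
        K1=int(saem_cfg["K1"]),
        K2=int(saem_cfg["K2"]),
        n_mcmc=int(saem_cfg.get("n_mcmc", 3)),
        chains=int(saem_cfg.get("chains", 1)),
        seed=seeds["fit"],
        rtol=float(saem_cfg.get("rtol", 1e-8)),
    )
    estimate = saem_fit(dataset, model, options)
    fitted = estimate.to_model()

    vpc = visual_predictive_check(
        fitted, design, int(config["vpc"]["n_sim"]), seeds["vpc"], observed=dataset
    )

    reg_cfg = config["regimen"]
    horizon = float(reg_cfg["horizon"])
    threshold = float(reg_cfg.get("threshold", 5.0))
    schedule = parse_doses(reg_cfg["doses"])
    summary = evaluate_regimen(
        fitted, schedule, int(reg_cfg["n"]), horizon, seeds["regimen"], threshold=threshold
    )
    single = {}
    grid = np.linspace(0.0, 21.0, 421)
    for dose in config["replicate"].get("single_doses", []):
        prof = simulate_individual(
            fitted.theta, expand_regimen([(0.0, float(dose))]), grid
        )
        single[f"{dose:g}"] = {
            "suppression_days": suppression_duration(prof, threshold),
            "total_c2_fold": total_c2_fold_change(prof),
        }

    report = {
        "half_life_days": linear["half_life_days"],
        "dose_prop_slope": linear["dose_prop_slope"],
        "theta_hat": dataclasses.asdict(estimate.theta_hat),
        "omega_hat": estimate.omega_hat,
        "sigma_hat": estimate.sigma_hat,
        "schedule": reg_cfg["doses"],
        "schedule_median_suppression_days": summary.median_duration,
        "schedule_p5_suppression_days": summary.p5_duration,
        "single_dose_typical": single,
        "n_animals": len(dataset.ids()),
        "stage_seeds": seeds,
    }
    if out is not None:
        dataset.to_csv(out / "dataset.csv")
        truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
        nca_table.to_csv(out / "nca.csv", index=False, float_format="%.10g")
        vpc.bands.to_csv(out / "vpc.csv", index=False, float_format="%.10g")
        summary.quantile_bands.to_csv(out / "regimen_bands.csv", index=False, float_format="%.10g")
        _write_json(report, out / "report.json")
        manifest.outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest.write(out / "manifest.json")
    return report


def run_transplant_replication(
    config: dict, seed: int, out_dir=None, *, dry_run: bool = False
) -> dict:
    """Turnkey outcome replication: generate → day-3 fits → longitudinal fits.

    With ``replicate.n_replicates`` > 1 the per-effect estimates are
    averaged over independently generated datasets (Monte-Carlo mode).
    """
    design = build_outcome_design(config)
    n_rep = int(config["replicate"]["n_replicates"])
    seeds = {"outcomes": child_seed(seed, "outcomes")}
    manifest = RunManifest(config_hash=config_hash(config), root_seed=seed, stage_seeds=seeds)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    if dry_run:
        if out is not None:
            manifest.write(out / "manifest.json")
        return {"dry_run": True, "stage_seeds": seeds}

    structures = {"creatinine": "CSH", "bun": "ARH1", "ngal": "ARH1"}
    ss = np.random.SeedSequence(seeds["outcomes"])
    rep_seeds = ss.spawn(n_rep)
    acc: dict[str, list] = {}
    last_table = None
    for r in range(n_rep):
        table = generate_transplant_outcomes(design, rep_seeds[r])
        last_table = table
        for name in design.arms:
            day3 = fit_day3(table, name)
            fit = fit_longitudinal(table, name, structures.get(name, "CSH"))
            across = wald_contrast(fit, "across-days")
            acc.setdefault(name, []).append(
                {
                    "day3_pct": day3.pct_reduction,
                    "day3_ci": [day3.ci_low, day3.ci_high],
                    "day3_p": day3.p_value,
                    "across_pct": across.pct_reduction,
                    "across_ci": [across.ci_low, across.ci_high],
                    "across_p": across.p_value,
                    "structure": fit.structure,
                    "reml_loglik": fit.reml_loglik,
                }
            )
    effects = {}
    for name, rows in acc.items():
        effects[name] = {
            "day3_pct_mean": float(np.mean([r["day3_pct"] for r in rows])),
            "across_pct_mean": float(np.mean([r["across_pct"] for r in rows])),
            "n_replicates": n_rep,
            "last_replicate": rows[-1],
        }
    report = {"effects": effects, "stage_seeds": seeds, "n_replicates": n_rep}
    if out is not None:
        assert last_table is not None
        last_table.to_csv(out / "outcomes.csv")
        _write_json(report, out / "report.json")
        manifest.outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest.write(out / "manifest.json")
    return report
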