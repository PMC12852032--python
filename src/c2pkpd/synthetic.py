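"""Synthetic study generators.

Two designs are emulated, with frozen defaults:

* a single-ascending-dose PK/PD study — doses 2, 5, 10, 25 and 50 mg/kg
  IV, three rats per group, samples at 5 min, 6 h, 24 h, 48 h and days 3,
  5, 7, 14 and 21 post-dose plus two pre-dose baselines (−7 and −1 days),
  antibody and free-C2 observables, free-C2 LLOQ 0.9375 µg/mL (5% of the
  18.75 µg/mL baseline);
* a kidney-transplant outcome study — creatinine, BUN and NGAL measured
  at days 3, 5, 7 and 14 with group sizes shrinking from 18 to 7
  (treated) and 9 to 6 (control), log-normal outcomes with within-animal
  CS or AR(1) correlation and deterministic attrition reproducing the
  per-day group sizes.

Generators are pure functions of (config, seed).  Censoring never touches
the companion truth records: observed tables and truth are emitted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import OutcomeTable
from .population import OBSERVABLES, EventDataset, PopulationModel
from .tmdd import DEFAULT_PARAMS, Regimen, DoseEvent, nm_to_ugml, simulate_individual

__all__ = [
    "PKStudyDesign",
    "OutcomeArm",
    "OutcomeStudyDesign",
    "DesignError",
    "generate_pkpd_study",
    "generate_transplant_outcomes",
    "default_generator_config",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class PKStudyDesign:
    """Single-ascending-dose PK/PD study design."""

    dose_groups: tuple[float, ...] = (2.0, 5.0, 10.0, 25.0, 50.0)
    n_per_group: int = 3
    sample_times: tuple[float, ...] = (5 / 1440, 0.25, 1.0, 2.0, 3.0, 5.0, 7.0, 14.0, 21.0)
    baseline_times: tuple[float, ...] = (-7.0, -1.0)
    observables: tuple[str, ...] = ("mab_total", "c2_free")
    lloq: dict = field(default_factory=lambda: {"mab_total": 0.1, "c2_free": 0.9375})

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise DesignError("n_per_group must be >= 1")
        if any(d < 0 for d in self.dose_groups):
            raise DesignError("doses must be >= 0")
        if list(self.sample_times) != sorted(self.sample_times) or min(self.sample_times) < 0:
            raise DesignError("sample_times must be sorted and non-negative")
        if any(t >= 0 for t in self.baseline_times):
            raise DesignError("baseline_times must be pre-dose (negative)")
        unknown = set(self.observables) - set(OBSERVABLES)
        if unknown:
            raise DesignError(f"unknown observables {sorted(unknown)}")


@dataclass(frozen=True)
class OutcomeArm:
    """Per-outcome generating distribution of the transplant study."""

    control_geomean: tuple[float, ...]
    treated_multiplier: tuple[float, ...]
    log_sd_control: float
    log_sd_treated: float
    rho: float
    structure: str  # "CS" | "AR1"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.control_geomean):
            raise DesignError("geometric means must be > 0")
        if any(v <= 0 for v in self.treated_multiplier):
            raise DesignError("multipliers must be > 0")
        if not (-1.0 < self.rho < 1.0):
            raise DesignError("correlation must be in (-1, 1)")
        if self.structure not in ("CS", "AR1"):
            raise DesignError("structure must be 'CS' or 'AR1'")


@dataclass(frozen=True)
class OutcomeStudyDesign:
    """Transplant-outcome study design: sizes, days and per-outcome arms."""

    days: tuple[float, ...] = (3.0, 5.0, 7.0, 14.0)
    n_treated: tuple[int, ...] = (18, 11, 9, 7)
    n_control: tuple[int, ...] = (9, 8, 7, 6)
    arms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ns in (self.n_treated, self.n_control):
            if len(ns) != len(self.days):
                raise DesignError("group sizes must match the number of days")
            if list(ns) != sorted(ns, reverse=True):
                raise DesignError("group sizes must be non-increasing over days")
        for name, arm in self.arms.items():
            if len(arm.control_geomean) != len(self.days):
                raise DesignError(f"{name}: geometric means must match the days")
            if len(arm.treated_multiplier) != len(self.days):
                raise DesignError(f"{name}: multipliers must match the days")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_pkpd_study(
    model: PopulationModel,
    design: PKStudyDesign,
    seed,
    *,
    return_truth: bool = False,
):
    """Generate one synthetic single-ascending-dose study.

    Per animal: draw eta from the model's IIV, simulate, apply
    proportional residual noise, then left-censor at each observable's
    LLOQ (BLQ rows keep ``dv`` at the LLOQ with the flag set; the truth
    record keeps the uncensored value).  Pre-dose free-C2 baselines get
    independent proportional noise around the individual's steady state.
    """
    rng = _rng(seed)
    rows = []
    truth_rows = []
    post = np.asarray(design.sample_times, dtype=float)
    n_animals = len(design.dose_groups) * design.n_per_group
    etas = model.draw_etas(rng, n_animals)
    a = 0
    for gi, dose in enumerate(design.dose_groups):
        for k in range(design.n_per_group):
            id_ = f"g{gi + 1}-d{dose:g}-{k + 1}"
            eta = etas[a]
            a += 1
            params_i = model.individual_params(eta)
            regimen = Regimen(
                events=(DoseEvent(time=0.0, amount=dose, duration=params_i.Tinf),)
            )
            prof = simulate_individual(params_i, regimen, post, rtol=1e-9, atol=1e-12, keep_dense=False)
            curves = {
                "mab_total": prof.mab_total,
                "c2_free": prof.c2_free,
                "c2_total": prof.c2_total,
            }
            r0_ugml = float(nm_to_ugml(params_i.r0, params_i.mw_target))
            rows.append(
                dict(id=id_, time=0.0, evid=1, amt=dose, dv=np.nan, mdv=1, blq=0,
                     observable=".", lloq=np.nan)
            )
            # pre-dose free-C2 baselines
            if "c2_free" in design.observables:
                for t in design.baseline_times:
                    sd = model.sigma_prop["c2_free"]
                    val = r0_ugml * (1.0 + sd * rng.standard_normal())
                    val = max(val, 1e-9)
                    lloq = design.lloq.get("c2_free", 0.0)
                    is_blq = int(val < lloq)
                    rows.append(
                        dict(id=id_, time=float(t), evid=0, amt=0.0,
                             dv=lloq if is_blq else val, mdv=0, blq=is_blq,
                             observable="c2_free", lloq=lloq)
                    )
                    truth_rows.append(
                        dict(id=id_, time=float(t), observable="c2_free",
                             pred=r0_ugml, dv_uncensored=val)
                    )
            for obs_name in design.observables:
                sd = model.sigma_prop[obs_name]
                lloq = design.lloq.get(obs_name, 0.0)
                f = curves[obs_name]
                noisy = f * (1.0 + sd * rng.standard_normal(f.size))
                noisy = np.maximum(noisy, 1e-9)
                for t, ft, val in zip(post, f, noisy):
                    is_blq = int(val < lloq)
                    rows.append(
                        dict(id=id_, time=float(t), evid=0, amt=0.0,
                             dv=lloq if is_blq else float(val), mdv=0, blq=is_blq,
                             observable=obs_name, lloq=lloq)
                    )
                    truth_rows.append(
                        dict(id=id_, time=float(t), observable=obs_name,
                             pred=float(ft), dv_uncensored=float(val))
                    )
            truth_rows.append(
                dict(id=id_, time=np.nan, observable="eta",
                     pred=np.nan, dv_uncensored=np.nan, **{f"eta_{k}": v for k, v in eta.items()})
            )
    ds = EventDataset(pd.DataFrame(rows))
    if return_truth:
        return ds, pd.DataFrame(truth_rows)
    return ds


def _corr(structure: str, rho: float, d: int) -> np.ndarray:
    if structure == "CS":
        C = np.full((d, d), rho)
        np.fill_diagonal(C, 1.0)
        return C
    lag = np.abs(np.arange(d)[:, None] - np.arange(d)[None, :])
    return rho**lag


def _attrition_last_day(index: int, sizes: tuple[int, ...]) -> int:
    """Index of the last observed day for the ``index``-th animal (0-based)."""
    last = -1
    for j, n in enumerate(sizes):
        if index < n:
            last = j
    return last


def generate_transplant_outcomes(
    design: OutcomeStudyDesign,
    seed,
    *,
    outcomes: list[str] | None = None,
    return_truth: bool = False,
):
    """Generate one synthetic transplant-outcome table.

    Each animal's log-outcome vector over all study days is multivariate
    normal with the arm's per-day means, a single per-group SD and the
    arm's CS or AR(1) correlation; values are exponentiated and follow-up
    is truncated deterministically to reproduce the printed per-day group
    sizes.  The truth table keeps every animal's full (untruncated)
    trajectory.
    """
    rng = _rng(seed)
    names = outcomes if outcomes is not None else list(design.arms)
    d = len(design.days)
    rows = []
    truth_rows = []
    for name in names:
        arm: OutcomeArm = design.arms[name]
        C = _corr(arm.structure, arm.rho, d)
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"{name}: infeasible correlation matrix") from exc
        log_control = np.log(np.asarray(arm.control_geomean, dtype=float))
        log_treated = log_control + np.log(np.asarray(arm.treated_multiplier, dtype=float))
        for group, n0, sizes, mean, sd in (
            ("treated", design.n_treated[0], design.n_treated, log_treated, arm.log_sd_treated),
            ("control", design.n_control[0], design.n_control, log_control, arm.log_sd_control),
        ):
            for i in range(n0):
                animal = f"{group[0]}{i + 1:02d}"
                z = chol @ rng.standard_normal(d)
                logs = mean + sd * z
                vals = np.exp(logs)
                last = _attrition_last_day(i, sizes)
                for j, day in enumerate(design.days):
                    truth_rows.append(
                        dict(animal=animal, group=group, day=day, outcome=name,
                             value=float(vals[j]), observed=j <= last)
                    )
                    if j <= last:
                        rows.append(
                            dict(animal=animal, group=group, day=day,
                                 outcome=name, value=float(vals[j]))
                        )
    table = OutcomeTable(pd.DataFrame(rows))
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


def default_generator_config() -> tuple[PopulationModel, PKStudyDesign, OutcomeStudyDesign]:
    """The frozen default study conditions.

    PK/PD: the default TMDD parameters with log-normal IIV of variance
    0.05 on CL, Vc and kin, proportional residual SDs of 0.10 (antibody)
    and 0.15 (free C2), free-C2 LLOQ 0.9375 µg/mL.  Outcomes: per-day
    control geometric means and treated/control ratios chosen so the
    day-3 and across-day treatment effects equal the study's headline
    percent reductions (creatinine 40% and 49%, BUN 33% and 49%); the
    absolute levels are plausible placeholders for a severe
    ischemia-reperfusion course, only ratios and SDs are calibrated.
    """
    model = PopulationModel(
        theta=DEFAULT_PARAMS,
        omega={"CL": 0.05, "Vc": 0.05, "kin": 0.05},
        sigma_prop={"mab_total": 0.10, "c2_free": 0.15},
        lloq={"mab_total": 0.1, "c2_free": 0.9375},
    )
    pk_design = PKStudyDesign(lloq=dict(model.lloq))
    outcome_design = OutcomeStudyDesign(
        arms={
            "creatinine": OutcomeArm(
                control_geomean=(4.0, 2.0, 1.2, 0.8),
                treated_multiplier=(0.60, 0.45, 0.50, 0.50),
                log_sd_control=0.50,
                log_sd_treated=0.38,
                rho=0.4,
                structure="CS",
            ),
            "bun": OutcomeArm(
                control_geomean=(120.0, 70.0, 45.0, 30.0),
                treated_multiplier=(0.67, 0.466, 0.466, 0.466),
                log_sd_control=0.35,
                log_sd_treated=0.28,
                rho=0.5,
                structure="AR1",
            ),
            "ngal": OutcomeArm(
                control_geomean=(8.0, 5.0, 3.0, 2.0),
                treated_multiplier=(0.6, 0.6, 0.6, 0.6),
                log_sd_control=0.40,
                log_sd_treated=0.40,
                rho=0.5,
                structure="AR1",
            ),
        }
    )
    return model, pk_design, outcome_design
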