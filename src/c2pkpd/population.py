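"""Nonlinear mixed-effects estimation of the TMDD model.

Inter-individual variability is log-normal on the structural parameters
(diagonal omega), residual error is proportional per observable, and
observations below the assay's lower limit of quantification enter the
likelihood as left-censored terms (the M3 method): a quantified
observation contributes a normal density around the model prediction,
a BLQ observation contributes log Φ((LLOQ − f)/s).

Estimation uses stochastic-approximation EM (SAEM): the E-step runs a few
component-wise random-walk Metropolis transitions per individual on the
random effects, with proposal scales adapted toward a 30–45% acceptance
rate; the M-step performs stochastic-approximation updates of the
sufficient statistics, giving closed-form updates of the typical values
(means of the individual log-parameters), omega (second moments) and the
proportional error SDs (mean squared weighted residuals of quantified
observations).  Runs are deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .tmdd import (
    DoseEvent,
    IntegrationError,
    Regimen,
    TMDDParams,
    nm_to_ugml,
    simulate_individual,
)

__all__ = [
    "OBSERVABLES",
    "STRUCTURAL_PARAMS",
    "EventDataset",
    "PopulationModel",
    "PopulationEstimate",
    "SAEMOptions",
    "EBEResult",
    "VPCResult",
    "DatasetError",
    "EstimationError",
    "individual_loglik_m3",
    "saem_fit",
    "empirical_bayes",
    "visual_predictive_check",
]

OBSERVABLES = ("mab_total", "c2_free", "c2_total")
#: structural parameters that may carry IIV / be estimated
STRUCTURAL_PARAMS = ("CL", "Vc", "Q", "Vp", "kin", "kout", "kon", "koff", "kint")

CSV_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "MDV", "BLQ", "OBS", "LLOQ"]
_INTERNAL = ["id", "time", "evid", "amt", "dv", "mdv", "blq", "observable", "lloq"]


class DatasetError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass
class EventDataset:
    """Dose/observation event records in the standard pharmacometric layout.

    Internal columns: id, time (day), evid (1 dose / 0 observation), amt
    (mg/kg), dv (µg/mL), mdv, blq, observable, lloq.  Observation times may
    be negative (pre-dose baselines); dose times must be non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _INTERNAL if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        doses = df[df["evid"] == 1]
        obs = df[df["evid"] == 0]
        if (doses["time"] < 0).any():
            raise DatasetError("dose times must be >= 0")
        if (doses["amt"] < 0).any():
            raise DatasetError("dose amounts must be >= 0")
        bad = ~obs["observable"].isin(OBSERVABLES)
        if bad.any():
            raise DatasetError(
                f"unknown observables: {sorted(obs.loc[bad, 'observable'].unique())}"
            )
        if ((obs["blq"] == 1) & (obs["mdv"] != 0)).any():
            raise DatasetError("BLQ observations must have mdv=0")

    @classmethod
    def from_csv(cls, path) -> "EventDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing CSV columns: {missing}")
        df = df[CSV_COLUMNS].rename(columns=dict(zip(CSV_COLUMNS, _INTERNAL)))
        return cls(df)

    def to_csv(self, path) -> None:
        out = self.df[_INTERNAL].rename(columns=dict(zip(_INTERNAL, CSV_COLUMNS)))
        out.to_csv(path, index=False, float_format="%.10g")

    def ids(self) -> list:
        return list(pd.unique(self.df["id"]))

    def individual(self, id_) -> pd.DataFrame:
        return self.df[self.df["id"] == id_]

    def n_obs(self) -> int:
        return int((self.df["evid"] == 0).sum())


@dataclass
class PopulationModel:
    """Typical values, IIV variances, residual error and LLOQs.

    ``omega`` maps structural parameter names to log-scale variances;
    ``sigma_prop`` maps observables to proportional residual SDs;
    ``estimate_flags`` marks which structural parameters the fit updates.
    """

    theta: TMDDParams
    omega: dict[str, float]
    sigma_prop: dict[str, float]
    estimate_flags: dict[str, bool] = field(default_factory=dict)
    lloq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.omega.items():
            if k not in STRUCTURAL_PARAMS:
                raise DatasetError(f"unknown omega entry {k!r}")
            if v < 0:
                raise DatasetError("omega variances must be >= 0")
        for k, v in self.sigma_prop.items():
            if k not in OBSERVABLES:
                raise DatasetError(f"unknown observable {k!r} in sigma_prop")
            if v < 0:
                raise DatasetError("sigma_prop must be >= 0 (0 only for noise-free generation)")
        if not self.estimate_flags:
            # IIV on all structural parameters by default, but the binding
            # constants are fixed: a censored free-C2 design cannot identify them
            self.estimate_flags = {
                p: p not in ("kon", "koff") for p in STRUCTURAL_PARAMS
            }
        if not any(self.estimate_flags.values()):
            raise DatasetError("at least one parameter must be estimated")

    def estimated_random(self) -> list[str]:
        """Parameters that are estimated and carry IIV."""
        return [
            p
            for p in STRUCTURAL_PARAMS
            if self.estimate_flags.get(p, False) and self.omega.get(p, 0.0) > 0
        ]

    def individual_params(self, eta: dict[str, float]) -> TMDDParams:
        updates = {
            k: getattr(self.theta, k) * math.exp(v) for k, v in eta.items() if v != 0.0
        }
        return replace(self.theta, **updates) if updates else self.theta

    def draw_etas(self, rng: np.random.Generator, n: int) -> list[dict[str, float]]:
        names = [p for p in STRUCTURAL_PARAMS if self.omega.get(p, 0.0) > 0]
        sds = np.array([math.sqrt(self.omega[p]) for p in names])
        draws = rng.standard_normal((n, len(names))) * sds
        return [dict(zip(names, row)) for row in draws]


@dataclass
class SAEMOptions:
    """Iteration budgets and MCMC settings for :func:`saem_fit`."""

    K1: int = 300
    K2: int = 200
    n_mcmc: int = 3
    chains: int = 1
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10


@dataclass
class PopulationEstimate:
    """SAEM output: estimates, objective trajectory and diagnostics."""

    theta_hat: TMDDParams
    omega_hat: dict[str, float]
    sigma_hat: dict[str, float]
    trajectory: pd.DataFrame
    diagnostics: dict
    seed: int
    init: PopulationModel

    def to_model(self) -> PopulationModel:
        return PopulationModel(
            theta=self.theta_hat,
            omega=dict(self.omega_hat),
            sigma_prop=dict(self.sigma_hat),
            estimate_flags=dict(self.init.estimate_flags),
            lloq=dict(self.init.lloq),
        )


class _IndividualWork:
    """Cached per-individual design: regimen, observation rows, predictor."""

    def __init__(self, model: PopulationModel, data_i: pd.DataFrame, rtol: float, atol: float):
        doses = data_i[data_i["evid"] == 1].sort_values("time")
        events = tuple(
            DoseEvent(time=float(r.time), amount=float(r.amt), duration=model.theta.Tinf)
            for r in doses.itertuples()
            if r.amt > 0
        )
        self.regimen = Regimen(events=events)
        obs = data_i[data_i["evid"] == 0]
        self.obs_times = obs["time"].to_numpy(float)
        self.observable = obs["observable"].to_numpy(object)
        self.dv = obs["dv"].to_numpy(float)
        self.blq = obs["blq"].to_numpy(float) > 0
        self.lloq_row = obs["lloq"].to_numpy(float)
        self.rtol, self.atol = rtol, atol
        pos = self.obs_times >= 0
        self.pos_mask = pos
        self.sim_times = np.unique(self.obs_times[pos]) if pos.any() else None
        self.n_obs = len(self.dv)

    def predict(self, params: TMDDParams) -> np.ndarray:
        """Model prediction (µg/mL) for every observation row."""
        f = np.empty(self.n_obs)
        # pre-dose rows sit at the steady state
        r0_ugml = float(nm_to_ugml(params.r0, params.mw_target))
        baseline = {"mab_total": 0.0, "c2_free": r0_ugml, "c2_total": r0_ugml}
        if self.sim_times is not None:
            prof = simulate_individual(
                params,
                self.regimen,
                self.sim_times,
                rtol=self.rtol,
                atol=self.atol,
                keep_dense=False,
            )
            curves = {
                "mab_total": prof.mab_total,
                "c2_free": prof.c2_free,
                "c2_total": prof.c2_total,
            }
            idx = np.searchsorted(self.sim_times, self.obs_times)
        for i in range(self.n_obs):
            if self.obs_times[i] < 0:
                f[i] = baseline[self.observable[i]]
            else:
                f[i] = curves[self.observable[i]][idx[i]]
        return f

    def loglik(self, f: np.ndarray, sigma: dict[str, float], lloq: dict[str, float]) -> float:
        total = 0.0
        for obs_name in np.unique(self.observable):
            m = self.observable == obs_name
            s_prop = sigma[obs_name]
            lq = lloq.get(obs_name, self.lloq_row[m][0] if np.isfinite(self.lloq_row[m][0]) else 0.0)
            floor = s_prop * lq / 2.0 if lq > 0 else 1e-10
            fm = f[m]
            s = np.maximum(s_prop * fm, floor)
            s = np.maximum(s, 1e-12)
            bl = self.blq[m]
            if (~bl).any():
                total += float(np.sum(norm.logpdf(self.dv[m][~bl], fm[~bl], s[~bl])))
            if bl.any():
                lq_rows = self.lloq_row[m][bl]
                total += float(np.sum(norm.logcdf((lq_rows - fm[bl]) / s[bl])))
        return total


def _split_works(
    model: PopulationModel, dataset: EventDataset, rtol: float, atol: float
) -> list[_IndividualWork]:
    works = []
    for id_ in dataset.ids():
        data_i = dataset.individual(id_)
        if (data_i["evid"] == 0).any():
            works.append(_IndividualWork(model, data_i, rtol, atol))
    return works


def individual_loglik_m3(
    model: PopulationModel, eta: dict[str, float], data_i: pd.DataFrame
) -> float:
    """M3 log-likelihood of one individual's records at random effects ``eta``.

    Quantified rows contribute normal densities with SD max(σ·f, floor);
    BLQ rows contribute the left-censoring probability log Φ((LLOQ−f)/s).
    With no censored rows this is the plain Gaussian log-likelihood.
    """
    work = _IndividualWork(model, data_i, rtol=1e-9, atol=1e-12)
    params = model.individual_params(eta)
    f = work.predict(params)
    return work.loglik(f, model.sigma_prop, model.lloq)


def _direct_fit(
    dataset: EventDataset, init: PopulationModel, options: SAEMOptions
) -> PopulationEstimate:
    """Pooled fit with eta = 0 when no estimated parameter carries IIV."""
    works = _split_works(init, dataset, options.rtol, options.atol)
    names = [p for p in STRUCTURAL_PARAMS if init.estimate_flags.get(p, False)]
    x0 = np.log([getattr(init.theta, p) for p in names])

    def objective(x: np.ndarray) -> float:
        updates = {p: math.exp(v) for p, v in zip(names, x)}
        try:
            params = replace(init.theta, **updates)
        except ValueError:
            return 1e12
        total = 0.0
        for w in works:
            try:
                total += w.loglik(w.predict(params), init.sigma_prop, init.lloq)
            except IntegrationError:
                return 1e12
        return -total

    res = minimize(objective, x0, method="Nelder-Mead", options={"maxfev": 4000, "xatol": 1e-8, "fatol": 1e-10})
    theta_hat = replace(init.theta, **{p: math.exp(v) for p, v in zip(names, res.x)})
    traj = pd.DataFrame([{p: math.exp(v) for p, v in zip(names, res.x)}])
    return PopulationEstimate(
        theta_hat=theta_hat,
        omega_hat=dict(init.omega),
        sigma_hat=dict(init.sigma_prop),
        trajectory=traj,
        diagnostics={"method": "direct", "success": bool(res.success), "neg_loglik": float(res.fun)},
        seed=options.seed,
        init=init,
    )


def saem_fit(
    dataset: EventDataset, init: PopulationModel, options: SAEMOptions
) -> PopulationEstimate:
    """SAEM estimation of typical values, omega and residual error.

    Step sizes are 1 during the first ``K1`` (burn-in) iterations and
    1/(k−K1) afterwards.  If no estimated parameter carries IIV the fit
    degenerates to a pooled maximum-likelihood optimisation.
    """
    if any(v <= 0 for v in init.sigma_prop.values()):
        raise EstimationError("estimation requires strictly positive sigma_prop")
    est = [p for p in init.estimated_random() if init.estimate_flags.get(p, False)]
    if not est:
        return _direct_fit(dataset, init, options)
    works = _split_works(init, dataset, options.rtol, options.atol)
    if len(works) < 2:
        if init.omega and max(init.omega.values()) > 0 and len(works) < 2:
            warnings.warn("fewer than 2 individuals with observations; IIV weakly identified")
    if not works:
        raise EstimationError("no individuals with observations")

    rng = np.random.default_rng(options.seed)
    n_est = len(est)
    n_ind = len(works)
    n_chain = max(1, options.chains)

    mu = np.log([getattr(init.theta, p) for p in est])
    om = np.array([init.omega[p] for p in est], dtype=float)
    sigma = dict(init.sigma_prop)
    obs_names = sorted({o for w in works for o in np.unique(w.observable)})
    quantified_counts = {
        o: sum(int(((w.observable == o) & ~w.blq).sum()) for w in works) for o in obs_names
    }
    for o in obs_names:
        if quantified_counts[o] == 0:
            warnings.warn(f"all {o} observations are BLQ; sigma held at its initial value")

    # the MCMC runs on phi = log individual parameters, prior N(mu, omega);
    # phi stays valid across M-step updates of mu, so cached predictions
    # never go stale
    phis = np.tile(mu, (n_chain, n_ind, 1))
    f_cache: list[list[np.ndarray]] = [[None] * n_ind for _ in range(n_chain)]  # type: ignore[list-item]
    ll_cache = np.full((n_chain, n_ind), -np.inf)

    def params_at(phi_vec: np.ndarray) -> TMDDParams:
        return replace(init.theta, **{p: math.exp(v) for p, v in zip(est, phi_vec)})

    for c in range(n_chain):
        for i, w in enumerate(works):
            f = w.predict(params_at(phis[c, i]))
            f_cache[c][i] = f
            ll_cache[c, i] = w.loglik(f, sigma, init.lloq)

    scales = np.clip(np.sqrt(om), 0.1, None)
    K = options.K1 + options.K2
    s1 = np.zeros(n_est)
    s2 = np.zeros(n_est)
    s_err = {o: 0.0 for o in obs_names}
    init_stats = False
    traj_rows = []
    acc_hist = np.zeros(n_est)
    prop_hist = np.zeros(n_est)

    for k in range(K):
        gamma = 1.0 if k < options.K1 else 1.0 / (k - options.K1 + 1)
        acc = np.zeros(n_est)
        prop = np.zeros(n_est)
        for c in range(n_chain):
            for i, w in enumerate(works):
                phi_i = phis[c, i]
                # refresh against current sigma (predictions are cached)
                ll_cache[c, i] = w.loglik(f_cache[c][i], sigma, init.lloq)
                prior_i = -0.5 * float(np.sum((phi_i - mu) ** 2 / om))
                for _ in range(options.n_mcmc):
                    for j in range(n_est):
                        phi_prop = phi_i.copy()
                        phi_prop[j] += scales[j] * rng.standard_normal()
                        try:
                            f_p = w.predict(params_at(phi_prop))
                            ll_p = w.loglik(f_p, sigma, init.lloq)
                        except (IntegrationError, ValueError):
                            ll_p = -np.inf
                        prior_p = -0.5 * float(np.sum((phi_prop - mu) ** 2 / om))
                        prop[j] += 1
                        if math.log(rng.uniform()) < (ll_p + prior_p) - (
                            ll_cache[c, i] + prior_i
                        ):
                            phi_i = phi_prop
                            ll_cache[c, i] = ll_p
                            f_cache[c][i] = f_p
                            prior_i = prior_p
                            acc[j] += 1
                phis[c, i] = phi_i
        # adapt proposal scales toward 30-45% acceptance
        with np.errstate(invalid="ignore"):
            rate = np.where(prop > 0, acc / np.maximum(prop, 1), 0.375)
        scales = np.where(rate > 0.45, scales * 1.1, np.where(rate < 0.30, scales * 0.9, scales))
        acc_hist += acc
        prop_hist += prop

        # M-step: stochastic approximation of sufficient statistics
        flat_phi = phis.reshape(-1, n_est)
        t1 = flat_phi.sum(axis=0) / n_chain
        t2 = (flat_phi**2).sum(axis=0) / n_chain
        t_err = {}
        for o in obs_names:
            if quantified_counts[o] == 0:
                continue
            ssq = 0.0
            for c in range(n_chain):
                for i, w in enumerate(works):
                    m = (w.observable == o) & ~w.blq
                    if not m.any():
                        continue
                    f = np.maximum(f_cache[c][i][m], 1e-12)
                    ssq += float(np.sum(((w.dv[m] - f) / f) ** 2))
            t_err[o] = ssq / n_chain
        if not init_stats:
            s1, s2 = t1.copy(), t2.copy()
            s_err = dict(t_err)
            init_stats = True
        else:
            s1 += gamma * (t1 - s1)
            s2 += gamma * (t2 - s2)
            for o in t_err:
                s_err[o] += gamma * (t_err[o] - s_err[o])
        mu = s1 / n_ind
        om = np.maximum(s2 / n_ind - mu**2, 1e-6)
        for o in obs_names:
            if quantified_counts[o] > 0:
                sigma[o] = math.sqrt(max(s_err[o] / quantified_counts[o], 1e-12))
        row = {p: math.exp(m) for p, m in zip(est, mu)}
        row.update({f"omega_{p}": v for p, v in zip(est, om)})
        row.update({f"sigma_{o}": sigma[o] for o in obs_names})
        row["mean_loglik"] = float(np.mean(ll_cache))
        traj_rows.append(row)

    theta_hat = replace(init.theta, **{p: math.exp(m) for p, m in zip(est, mu)})
    if not np.isfinite(ll_cache).all():
        bad = int(np.argwhere(~np.isfinite(ll_cache))[0][1])
        raise EstimationError(f"non-finite objective for individual index {bad}")
    omega_hat = dict(init.omega)
    omega_hat.update({p: float(v) for p, v in zip(est, om)})
    traj = pd.DataFrame(traj_rows)
    return PopulationEstimate(
        theta_hat=theta_hat,
        omega_hat=omega_hat,
        sigma_hat={o: float(sigma[o]) for o in sigma},
        trajectory=traj,
        diagnostics={
            "acceptance_rate": {
                p: float(a / max(q, 1)) for p, a, q in zip(est, acc_hist, prop_hist)
            },
            "proposal_scales": {p: float(s) for p, s in zip(est, scales)},
            "estimated": est,
        },
        seed=options.seed,
        init=init,
    )


@dataclass
class EBEResult:
    eta: dict[str, float]
    converged: bool
    log_posterior: float


def empirical_bayes(
    model: PopulationModel, data_i: pd.DataFrame, seed: int = 0
) -> EBEResult:
    """Empirical-Bayes (MAP) random effects for one individual.

    Maximises the M3 likelihood plus the N(0, omega) log-prior, from the
    prior mode and one random start.
    """
    est = model.estimated_random()
    work = _IndividualWork(model, data_i, rtol=1e-8, atol=1e-10)
    if work.n_obs == 0 or not est:
        return EBEResult(eta={p: 0.0 for p in est}, converged=True, log_posterior=0.0)
    om = np.array([model.omega[p] for p in est])

    def objective(x: np.ndarray) -> float:
        try:
            f = work.predict(model.individual_params(dict(zip(est, x))))
        except (IntegrationError, ValueError):
            return 1e12
        ll = work.loglik(f, model.sigma_prop, model.lloq)
        return -(ll - 0.5 * float(np.sum(x**2 / om)))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(len(est)), rng.standard_normal(len(est)) * np.sqrt(om)]
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead", options={"maxfev": 2000, "xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    return EBEResult(
        eta=dict(zip(est, [float(v) for v in best.x])),
        converged=bool(best.success),
        log_posterior=-float(best.fun),
    )


@dataclass
class VPCResult:
    """Per-time simulated quantile bands and observed medians."""

    bands: pd.DataFrame  # observable, time, lo, med, hi, observed_median
    n_sim: int


def visual_predictive_check(
    model: PopulationModel | PopulationEstimate,
    design,
    n_sim: int,
    seed: int,
    observed: EventDataset | None = None,
) -> VPCResult:
    """Simulate ``n_sim`` replicate studies and compare observed medians.

    BLQ-censoring is applied to each replicate exactly as to the observed
    data; censored values are imputed at LLOQ/2 for the medians on both
    sides of the comparison.  Bands are the 5/50/95 percentiles across
    replicates of each per-time median.
    """
    from .synthetic import generate_pkpd_study  # local import to avoid a cycle

    if n_sim < 1:
        raise DatasetError("n_sim must be >= 1")
    if isinstance(model, PopulationEstimate):
        model = model.to_model()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_sim + 1)
    if observed is None:
        observed = generate_pkpd_study(model, design, seed=child[-1])

    def medians(ds: EventDataset) -> pd.Series:
        obs = ds.df[ds.df["evid"] == 0].copy()
        imputed = np.where(obs["blq"] > 0, obs["lloq"] / 2.0, obs["dv"])
        obs["val"] = imputed
        return obs.groupby(["observable", "time"])["val"].median()

    sims = []
    for r in range(n_sim):
        ds = generate_pkpd_study(model, design, seed=child[r])
        sims.append(medians(ds))
    sim_mat = pd.concat(sims, axis=1)
    lo = sim_mat.quantile(0.05, axis=1)
    med = sim_mat.quantile(0.50, axis=1)
    hi = sim_mat.quantile(0.95, axis=1)
    obs_med = medians(observed)
    bands = pd.DataFrame(
        {"lo": lo, "med": med, "hi": hi, "observed_median": obs_med}
    ).reset_index()
    return VPCResult(bands=bands, n_sim=n_sim)
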