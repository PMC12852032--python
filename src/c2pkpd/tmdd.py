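"""Mechanistic PK/PD core: two-compartment antibody disposition with
target-mediated binding to complement C2.

The model tracks four states per rat, in molar units normalised to body
weight:

* ``Ac`` — antibody binding sites in the central compartment, nmol/kg
* ``Ap`` — antibody binding sites in the peripheral compartment, nmol/kg
* ``R``  — free target (C2), nM
* ``RC`` — antibody–target complex, nM

Antibody is eliminated linearly from the central compartment (clearance
``CL``), distributes to a peripheral compartment (``Q``, ``Vp``) and is
delivered as a zero-order input of duration ``Tinf`` per dose (an IV bolus
is a very short infusion).  The target turns over with zero-order synthesis
``kin`` and first-order degradation ``kout``; it binds antibody sites with
second-order rate ``kon`` and dissociates with ``koff``; the complex is
eliminated with first-order rate ``kint``.  A bivalent IgG is treated as
two independent binding sites, so doses in mg/kg convert to nmol/kg of
sites via the per-site molar mass ``mw_site``.

All user-facing concentrations are µg/mL, doses mg/kg and times days; the
conversion is conc(µg/mL) = conc(nM) · MW(g/mol) · 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TMDDParams",
    "DoseEvent",
    "Regimen",
    "SimulatedProfile",
    "TMDDError",
    "IntegrationError",
    "DEFAULT_PARAMS",
    "baseline_free_target",
    "expand_regimen",
    "pct_of_baseline",
    "simulate_individual",
    "mg_per_kg_to_nmol_sites",
    "nm_to_ugml",
]

NM_TO_UGML = 1e-6  # conc(µg/mL) = conc(nM) * MW(g/mol) * 1e-6


class TMDDError(ValueError):
    """Invalid model parameters or inputs."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce an acceptable solution."""


@dataclass(frozen=True)
class TMDDParams:
    """Structural PK/PD parameters.

    Units: clearances L/day/kg, volumes L/kg, times days, first-order rates
    1/day, ``kin`` nM/day, ``kon`` 1/(nM·day), molar masses g/mol.
    """

    CL: float
    Vc: float
    Q: float
    Vp: float
    Tinf: float
    kin: float
    kout: float
    kon: float
    koff: float
    kint: float
    mw_site: float = 75_000.0
    mw_target: float = 102_000.0

    def __post_init__(self) -> None:
        for name in ("Vc", "Vp", "Tinf", "mw_site", "mw_target"):
            if not (getattr(self, name) > 0) or not math.isfinite(getattr(self, name)):
                raise TMDDError(f"{name} must be strictly positive and finite")
        for name in ("CL", "Q", "kin", "kon", "koff", "kint", "kout"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise TMDDError(f"{name} must be non-negative and finite")
        # kout = 0 is admitted only for a switched-off target (kin = 0),
        # where the baseline is taken as zero unless overridden
        if self.kout == 0 and self.kin > 0:
            raise TMDDError("kout must be > 0 when kin > 0 (baseline kin/kout)")
        if self.kout > 0 and not math.isfinite(self.kin / self.kout):
            raise TMDDError("baseline free target kin/kout must be finite")

    @property
    def r0(self) -> float:
        """Baseline free-target concentration kin/kout, nM."""
        return self.kin / self.kout if self.kout > 0 else 0.0

    def with_updates(self, **kwargs: float) -> "TMDDParams":
        return replace(self, **kwargs)


#: Default parameter set, calibrated jointly to the observed kinetics:
#: CL/Vc/Q/Vp give the linear antibody sub-model a 12.5-day terminal
#: half-life; kin/kout pins the free-C2 baseline at 18.75 µg/mL (183.8 nM of
#: a 102 kDa target — the concentration at which a 0.9375 µg/mL assay LLOQ
#: sits exactly at 5% of baseline); kout/kint = 10 sets the ~10-fold
#: accumulation plateau of total C2 under saturating antibody, and the
#: absolute turnover scale (kout = 1.3/day) is the balance point at which a
#: 50 mg/kg dose keeps free C2 below 5% of baseline for the full 21-day
#: study despite target-mediated antibody consumption (cumulative use
#: kin·Vc ≈ 9.6 nmol sites/kg/day at saturation) while kint·21 is still
#: large enough to approach the accumulation plateau within the study
#: window.  KD = koff/kon = 1 nM with a slow off-rate.
DEFAULT_PARAMS = TMDDParams(
    CL=0.004712,
    Vc=0.040,
    Q=0.020,
    Vp=0.040,
    Tinf=0.001,
    kin=238.97,
    kout=1.3,
    kon=0.0864,
    koff=0.0864,
    kint=0.13,
)


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous dose delivered as a zero-order input.

    ``time`` and ``duration`` in days, ``amount`` in mg/kg.
    """

    time: float
    amount: float
    duration: float = DEFAULT_PARAMS.Tinf
    route: str = "iv"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise TMDDError("dose time must be >= 0")
        if self.amount < 0:
            raise TMDDError("dose amount must be >= 0")
        if not self.duration > 0:
            raise TMDDError("infusion duration must be > 0")
        if self.route != "iv":
            raise TMDDError(f"unsupported route {self.route!r}: only 'iv'")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events; empty means placebo."""

    events: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise TMDDError("regimen events must be sorted by time")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def first_dose_time(self) -> float | None:
        for e in self.events:
            if e.amount > 0:
                return e.time
        return None


def expand_regimen(
    events: Iterable[tuple[float, float]], duration: float = DEFAULT_PARAMS.Tinf
) -> Regimen:
    """Build a validated :class:`Regimen` from ``(time, amount)`` pairs.

    Events are sorted by time and each gets the default zero-order input
    duration unless the pair carries a third element.
    """
    built = []
    for ev in events:
        if len(ev) == 3:
            t, a, d = ev  # type: ignore[misc]
        else:
            t, a = ev
            d = duration
        built.append(DoseEvent(time=float(t), amount=float(a), duration=float(d)))
    built.sort(key=lambda e: e.time)
    return Regimen(events=tuple(built))


def baseline_free_target(params: TMDDParams) -> float:
    """Pre-dose steady-state free target R0 = kin/kout, in nM."""
    if not params.kout > 0:
        raise TMDDError("kout must be > 0")
    return params.kin / params.kout


def pct_of_baseline(values: np.ndarray | float, baseline_mean: float) -> np.ndarray | float:
    """Express concentrations as a percentage of a (group) baseline mean."""
    if not baseline_mean > 0:
        raise TMDDError("baseline_mean must be > 0")
    return 100.0 * np.asarray(values, dtype=float) / baseline_mean


def mg_per_kg_to_nmol_sites(amount_mg_per_kg: float, mw_site: float) -> float:
    """Convert an antibody dose in mg/kg to nmol/kg of binding sites."""
    return amount_mg_per_kg * 1e6 / mw_site


def nm_to_ugml(conc_nm: np.ndarray | float, mw: float) -> np.ndarray | float:
    """Convert a molar concentration (nM) to µg/mL for species of mass ``mw``."""
    return np.asarray(conc_nm, dtype=float) * mw * NM_TO_UGML


@dataclass
class SimulatedProfile:
    """Observable time courses from one simulated individual.

    Concentrations are µg/mL; ``c2_free_pct_baseline`` is free C2 as a
    percentage of the model's own pre-dose baseline.  ``states`` holds the
    raw trajectories (rows: Ac nmol/kg, Ap nmol/kg, R nM, RC nM).
    """

    times: np.ndarray
    mab_total: np.ndarray
    c2_free: np.ndarray
    c2_total: np.ndarray
    c2_free_pct_baseline: np.ndarray
    states: np.ndarray
    params: TMDDParams
    regimen: Regimen
    r0_nm: float = 0.0
    _segments: list[tuple[float, float, Callable]] = field(default_factory=list, repr=False)

    def c2_free_pct_at(self, t: float) -> float:
        """Evaluate free C2 (% of baseline) from the continuous solution."""
        r0 = self.r0_nm
        if r0 <= 0:
            raise TMDDError("baseline free target is zero")
        for t0, t1, sol in self._segments:
            if t0 <= t <= t1:
                return 100.0 * float(sol(t)[2]) / r0
        # outside the integrated span: fall back to grid interpolation
        return float(np.interp(t, self.times, self.c2_free_pct_baseline))


def _infusion_schedule(regimen: Regimen, mw_site: float, t_end: float):
    """Piecewise-constant input rate (nmol/kg/day of sites) up to t_end."""
    starts, rates = [], []
    for e in regimen.events:
        if e.amount <= 0 or e.time > t_end:
            continue
        starts.append((e.time, e.time + e.duration, mg_per_kg_to_nmol_sites(e.amount, mw_site) / e.duration))
    cuts = {0.0, t_end}
    for a, b, _ in starts:
        cuts.add(a)
        if b < t_end:
            cuts.add(b)
    cutpoints = sorted(c for c in cuts if 0.0 <= c <= t_end)
    segments = []
    for i in range(len(cutpoints) - 1):
        a, b = cutpoints[i], cutpoints[i + 1]
        mid = 0.5 * (a + b)
        rate = sum(r for s, e, r in starts if s <= mid < e)
        segments.append((a, b, rate))
    return segments


def simulate_individual(
    params: TMDDParams,
    regimen: Regimen,
    times: Sequence[float] | np.ndarray,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    keep_dense: bool = True,
    r0_override: float | None = None,
) -> SimulatedProfile:
    """Integrate the TMDD system for one individual and return observables.

    ``times`` is a sorted, non-negative day grid; integration always starts
    at day 0 from the pre-dose steady state (0, 0, R0, 0).  Doses are
    zero-order inputs over each event's duration.  A stiff-capable solver
    (LSODA) is used; states are clipped at zero only for reporting.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise TMDDError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) < 0):
        raise TMDDError("times must be sorted ascending")
    if times[0] < 0:
        raise TMDDError("times must be non-negative")

    r0 = params.r0 if r0_override is None else float(r0_override)
    t_end = float(times[-1])
    y0 = np.array([0.0, 0.0, r0, 0.0])

    CL, Vc, Q, Vp = params.CL, params.Vc, params.Q, params.Vp
    kin, kout, kon, koff, kint = params.kin, params.kout, params.kon, params.koff, params.kint

    def make_rhs(rate: float):
        def rhs(t, y):
            Ac, Ap, R, RC = y
            C = Ac / Vc
            bind = kon * C * R - koff * RC
            dAc = rate - (CL / Vc) * Ac - (Q / Vc) * Ac + (Q / Vp) * Ap - Vc * bind
            dAp = (Q / Vc) * Ac - (Q / Vp) * Ap
            dR = kin - kout * R - bind
            dRC = bind - kint * RC
            return (dAc, dAp, dR, dRC)

        return rhs

    if t_end == 0.0:
        states = np.tile(y0[:, None], (1, times.size))
        segments_out: list[tuple[float, float, Callable]] = []
    else:
        seg_defs = _infusion_schedule(regimen, params.mw_site, t_end)
        out = np.empty((4, times.size))
        segments_out = []
        y = y0
        for a, b, rate in seg_defs:
            mask = (times >= a) & (times <= b if b == t_end else times < b)
            t_eval = times[mask]
            sol = solve_ivp(
                make_rhs(rate),
                (a, b),
                y,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                t_eval=t_eval if t_eval.size else None,
                dense_output=True,
            )
            if not sol.success:
                raise IntegrationError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
            if t_eval.size:
                out[:, mask] = sol.y
            if keep_dense:
                segments_out.append((a, b, sol.sol))
            y = sol.sol(b)
        # grid points exactly at 0 (before the first segment's interior)
        states = out
        if times[0] == 0.0:
            states[:, times == 0.0] = y0[:, None]

    scale = max(r0, 1.0)
    if states.min() < -1e-6 * scale:
        raise IntegrationError(
            f"negative state beyond tolerance: min={states.min():.3e}"
        )
    states = np.clip(states, 0.0, None)

    Ac, _Ap, R, RC = states
    c_sites = Ac / params.Vc  # nM of binding sites
    mab_total = nm_to_ugml(c_sites + RC, params.mw_site)
    c2_free = nm_to_ugml(R, params.mw_target)
    c2_total = nm_to_ugml(R + RC, params.mw_target)
    if r0 > 0:
        pct = 100.0 * R / r0
    else:
        pct = np.zeros_like(R)
    return SimulatedProfile(
        times=times,
        mab_total=np.asarray(mab_total),
        c2_free=np.asarray(c2_free),
        c2_total=np.asarray(c2_total),
        c2_free_pct_baseline=pct,
        states=states,
        params=params,
        regimen=regimen,
        r0_nm=r0,
        _segments=segments_out,
    )
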