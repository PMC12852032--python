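"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the linear
two-compartment solution is built from the matrix exponential of the rate
matrix, and the terminal rate constant from its eigenvalues.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def rate_matrix(CL: float, Vc: float, Q: float, Vp: float) -> np.ndarray:
    """Rate matrix for central/peripheral antibody amounts."""
    return np.array(
        [
            [-(CL + Q) / Vc, Q / Vp],
            [Q / Vc, -Q / Vp],
        ]
    )


def terminal_rate(CL: float, Vc: float, Q: float, Vp: float) -> float:
    """Smallest-magnitude eigenvalue (terminal slope) of the linear system."""
    eig = np.linalg.eigvals(rate_matrix(CL, Vc, Q, Vp))
    return float(-np.max(eig.real))


def two_cpt_zero_order_amounts(
    CL: float,
    Vc: float,
    Q: float,
    Vp: float,
    dose_amt: float,
    tinf: float,
    times: np.ndarray,
) -> np.ndarray:
    """Central/peripheral amounts for a single zero-order input at t=0.

    Exact piecewise solution: during the infusion y(t) = A⁻¹(e^{At}−I)·b
    with b = (rate, 0); afterwards the homogeneous propagator applies.
    Returns an array (2, len(times)).
    """
    A = rate_matrix(CL, Vc, Q, Vp)
    Ainv = np.linalg.inv(A)
    b = np.array([dose_amt / tinf, 0.0])
    y_end = Ainv @ (expm(A * tinf) - np.eye(2)) @ b
    out = np.empty((2, len(times)))
    for i, t in enumerate(np.asarray(times, dtype=float)):
        if t <= 0:
            out[:, i] = 0.0
        elif t < tinf:
            out[:, i] = Ainv @ (expm(A * t) - np.eye(2)) @ b
        else:
            out[:, i] = expm(A * (t - tinf)) @ y_end
    return out


def two_cpt_mab_total_ugml(params, dose_mg_per_kg: float, times: np.ndarray) -> np.ndarray:
    """Total-antibody concentration (µg/mL) of the binding-free sub-model."""
    dose_amt = dose_mg_per_kg * 1e6 / params.mw_site  # nmol sites / kg
    amounts = two_cpt_zero_order_amounts(
        params.CL, params.Vc, params.Q, params.Vp, dose_amt, params.Tinf, times
    )
    conc_nm = amounts[0] / params.Vc
    return conc_nm * params.mw_site * 1e-6
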