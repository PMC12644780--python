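"""Regularized inversion of impedance spectra into relaxation-time distributions.

The continuous model

    Z(omega) = R_inf + R_p * integral g(tau)/(1 + j*omega*tau) dtau

is discretized on a uniform natural-log-tau grid: the distribution becomes M
step functions, bin j carrying the resistance mass w_j = R_p * G(x_j) * dx
evaluated at the bin's log-midpoint tau_j.  Stacking real and imaginary parts
of the N measured impedances gives a 2N x (M+1) linear system (the last column
is the R_inf regressor).  With M comparable to or larger than N the problem is
ill-posed, so the weights are found by nonnegative ridge regression,

    min_{w >= 0} ||Z_meas - Z_model||^2 + lambda * ||D1 w||^2,

where D1 takes first differences of the bin weights along the log-tau axis
(the discrete form of a ||g'||^2 smoothness penalty) and does not touch the
R_inf column.  The problem is convex and solved deterministically with
scipy's NNLS on the augmented system [[A], [sqrt(lambda) D1]].

Both impedance parts are fitted jointly: the real part is what identifies
R_inf, and the highest measured frequency is generally not asymptotic for the
fastest tissue dispersions, so pinning R_inf to |Z| at the top frequency
would bias the short-time end of the distribution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .core import DRTResult, ImpedanceSpectrum, RelaxationGrid

__all__ = [
    "InversionSettings",
    "build_kernel",
    "solve_drt",
    "reconstruct_impedance",
    "tune_lambda",
    "LambdaSelection",
]

log = logging.getLogger(__name__)


@dataclass
class InversionSettings:
    """Settings for :func:`solve_drt`.

    ``lambda_reg`` trades data fidelity against smoothness of the recovered
    distribution; 0.1 is a good default for spectra with sub-percent noise.
    ``part_weighting`` multiplies the imaginary-part residuals relative to the
    real-part residuals (1.0 = joint fit with equal weight).
    """

    lambda_reg: float = 0.1
    grid: RelaxationGrid = field(default_factory=RelaxationGrid.default)
    fit_R_inf: bool = True
    part_weighting: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.part_weighting <= 0:
            raise ValueError("part_weighting must be positive")


def build_kernel(grid: RelaxationGrid, frequencies: np.ndarray) -> np.ndarray:
    """Design matrix of the discretized problem, shape (2N, M+1).

    Rows 0..N-1 hold Re[1/(1 + j*omega_i*tau_j)], rows N..2N-1 hold the
    imaginary parts; the final column is the R_inf regressor (1 on real rows,
    0 on imaginary rows).  Each bin is represented by midpoint evaluation at
    its log-center tau_j (the bin width is absorbed into the weight).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    omega_tau = 2.0 * np.pi * frequencies[:, None] * grid.centers[None, :]
    denom = 1.0 + omega_tau**2
    n = frequencies.size
    A = np.zeros((2 * n, grid.M + 1))
    A[:n, :-1] = 1.0 / denom
    A[n:, :-1] = -omega_tau / denom
    A[:n, -1] = 1.0
    return A


def _difference_operator(m: int) -> np.ndarray:
    """First differences of the m bin weights; the R_inf column is untouched.

    Boundary bins enter only their one interior difference (one-sided)."""
    D = np.zeros((m - 1, m + 1))
    idx = np.arange(m - 1)
    D[idx, idx] = -1.0
    D[idx, idx + 1] = 1.0
    return D


def _coverage_warning(spectrum: ImpedanceSpectrum, grid: RelaxationGrid) -> None:
    # Frequencies should fall within the grid's reciprocal range expanded by
    # two decades each side, else parts of the spectrum are unexplainable.
    f_lo = 1.0 / (2.0 * np.pi * grid.tau_sup) / 100.0
    f_hi = 1.0 / (2.0 * np.pi * grid.tau_inf) * 100.0
    if spectrum.frequencies[0] < f_lo or spectrum.frequencies[-1] > f_hi:
        warnings.warn(
            "spectrum frequencies extend beyond the relaxation grid's "
            "reciprocal range (+/- 2 decades); consider widening the grid",
            stacklevel=3,
        )


def solve_drt(spectrum: ImpedanceSpectrum, settings: InversionSettings | None = None) -> DRTResult:
    """Invert a spectrum into a nonnegative, smoothed DRT.

    Minimizes ``||Z - Z_model||^2 + lambda ||D1 w||^2`` subject to ``w >= 0``
    over the bin weights and R_inf.  The problem is convex; the solution is
    deterministic and invariant to the ordering of the input points.
    """
    if settings is None:
        settings = InversionSettings()
    if spectrum.n < 3:
        raise ValueError("need at least 3 frequency points to invert")
    grid = settings.grid
    _coverage_warning(spectrum, grid)

    A = build_kernel(grid, spectrum.frequencies)
    b = np.concatenate([spectrum.impedance.real, spectrum.impedance.imag])
    n = spectrum.n
    if settings.part_weighting != 1.0:
        A = A.copy()
        A[n:] *= settings.part_weighting
        b = b.copy()
        b[n:] *= settings.part_weighting
    if not settings.fit_R_inf:
        # Pin R_inf to the real part at the highest measured frequency.
        r_inf_fixed = float(spectrum.impedance.real[-1])
        b = b - A[:, -1] * r_inf_fixed
        A = A[:, :-1]

    D = _difference_operator(grid.M)
    if not settings.fit_R_inf:
        D = D[:, :-1]
    if settings.lambda_reg > 0:
        A_aug = np.vstack([A, math.sqrt(settings.lambda_reg) * D])
        b_aug = np.concatenate([b, np.zeros(D.shape[0])])
    else:
        A_aug, b_aug = A, b
        if grid.M > 2 * n:
            warnings.warn("lambda = 0 with M > 2N: exact-fit problem is underdetermined",
                          stacklevel=2)

    try:
        coef, _ = scipy.optimize.nnls(A_aug, b_aug)
    except RuntimeError as exc:
        raise RuntimeError(
            f"NNLS failed to converge (N={n}, M={grid.M}, "
            f"lambda={settings.lambda_reg}): {exc}"
        ) from exc

    if settings.fit_R_inf:
        weights, r_inf = coef[:-1], float(coef[-1])
    else:
        weights, r_inf = coef, r_inf_fixed
    residual = float(np.linalg.norm(A[:, : grid.M] @ weights
                                    + (A[:, -1] * r_inf if settings.fit_R_inf else 0.0)
                                    - b))
    drt = DRTResult(grid, weights, r_inf, settings.lambda_reg, residual)
    log.info(
        "DRT inversion: N=%d M=%d lambda=%g residual=%.4g ohm R_inf=%.4g ohm R_p=%.4g ohm",
        n, grid.M, settings.lambda_reg, residual, r_inf, drt.R_p,
    )
    return drt


def reconstruct_impedance(drt: DRTResult, frequencies: np.ndarray) -> ImpedanceSpectrum:
    """Forward-evaluate a DRT: Z(omega) = R_inf + sum_j w_j/(1 + j*omega*tau_j).

    At omega -> 0 this tends to R_inf + R_p; at omega -> inf, to R_inf.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    omega_tau = 2.0 * np.pi * frequencies[:, None] * drt.grid.centers[None, :]
    z = drt.R_inf + (drt.weights[None, :] / (1.0 + 1j * omega_tau)).sum(axis=1)
    with warnings.catch_warnings():
        # model evaluations on sparse grids are fine; suppress the N-point nag
        warnings.simplefilter("ignore", UserWarning)
        return ImpedanceSpectrum(frequencies, z, {"reconstructed": True})


@dataclass
class LambdaSelection:
    """Outcome of :func:`tune_lambda`: the chosen penalty and a diagnostics
    table with one row per candidate (lambda, residual, roughness, gcv)."""

    lambda_reg: float
    table: pd.DataFrame


def _effective_dof(A: np.ndarray, D: np.ndarray, lam: float, active: np.ndarray) -> float:
    """Trace of the hat matrix of the penalized LS problem restricted to the
    active (nonzero) coordinates of the NNLS solution."""
    Aa = A[:, active]
    Da = D[:, active]
    M = Aa.T @ Aa + lam * (Da.T @ Da)
    # tiny jitter guards rank deficiency of degenerate active sets
    M += 1e-12 * np.trace(M) / max(M.shape[0], 1) * np.eye(M.shape[0])
    try:
        H = scipy.linalg.solve(M, Aa.T @ Aa, assume_a="pos")
    except scipy.linalg.LinAlgError:
        return float(active.sum())
    return float(np.trace(H))


def tune_lambda(
    spectrum: ImpedanceSpectrum,
    settings: InversionSettings | None = None,
    candidate_lambdas: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0),
) -> LambdaSelection:
    """Pick the penalty weight by generalized cross-validation (GCV).

    For each candidate the spectrum is inverted and scored with
    ``GCV = 2N * RSS / (2N - df)^2`` where ``df`` is the effective number of
    parameters (trace of the active-set hat matrix).  Returns the candidate
    with the smallest score plus a diagnostics table; with a single candidate
    it is returned unconditionally.
    """
    if settings is None:
        settings = InversionSettings()
    candidates = list(candidate_lambdas)
    if not candidates:
        raise ValueError("need at least one candidate lambda")

    A = build_kernel(settings.grid, spectrum.frequencies)
    D = _difference_operator(settings.grid.M)
    rows = []
    for lam in candidates:
        s = InversionSettings(lam, settings.grid, settings.fit_R_inf, settings.part_weighting)
        drt = solve_drt(spectrum, s)
        w_full = np.concatenate([drt.weights, [drt.R_inf]])
        active = w_full > 0
        active[-1] = True  # R_inf always in the model
        df = _effective_dof(A, D, lam, active)
        n2 = 2 * spectrum.n
        rss = drt.residual_norm**2
        gcv = n2 * rss / max(n2 - df, 1.0) ** 2
        rows.append(
            {
                "lambda": lam,
                "residual_norm": drt.residual_norm,
                "roughness": float(np.linalg.norm(D @ w_full)),
                "effective_dof": df,
                "gcv": gcv,
            }
        )
    table = pd.DataFrame(rows)
    chosen = float(table.loc[table["gcv"].idxmin(), "lambda"])
    log.info("lambda selection by GCV: chose %g among %s", chosen, candidates)
    return LambdaSelection(chosen, table)
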