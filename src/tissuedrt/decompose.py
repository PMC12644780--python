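"""Gaussian decomposition of a DRT and F-test model selection.

A complex tissue distribution ``R_p * G(x)`` (x = natural-log tau) is fitted
with a sum of K Gaussians; each component corresponds to a log-normal family
of relaxation processes in one tissue compartment and contributes
``R_pk = a_k sigma_k sqrt(2 pi)`` ohms to the DC resistance,
``R_0 = R_inf + sum_k R_pk``.

K is chosen by nested F-tests: adding a component costs three parameters
(amplitude, location, spread), so the improvement of the K-component model
over the (K-1)-component model is scored with

    F = (RSS_{K-1} - RSS_K) / RSS_K * (n - 3K - 1) / 3

against an F(3, n - 3K - 1) reference, where n is the number of time bins in
the fit.  Because a new component often refines only a narrow region of the
distribution, the same statistic can be recomputed on a short-time tail
window (residuals restricted to tau < tail_cutoff, n replaced by the tail
bin count), which is much more sensitive to structure there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .core import DecompositionModel, DRTResult, GaussianComponent, ValidationError

__all__ = [
    "FTestReport",
    "SelectionResult",
    "fit_gaussians",
    "component_resistances",
    "f_test",
    "select_K",
]

log = logging.getLogger(__name__)

SIGMA_MIN = 0.05  # natural-log units; below this a component degenerates to a spike
SIGMA_MAX = 3.0   # above this it degenerates to a plateau
GRID_SIGMA_FACTOR = 1.5  # a component must span ~1.5 bins to be identifiable


def _sigma_floor(bin_width_logtau: float) -> float:
    """Lower bound on component spread: the larger of the absolute floor and
    ~1.5 grid bins (narrower components cannot be distinguished from the
    discretization and act as single-bin noise absorbers)."""
    return max(SIGMA_MIN, GRID_SIGMA_FACTOR * bin_width_logtau)


@dataclass(frozen=True)
class FTestReport:
    """Nested F-test for going from k-1 to k Gaussian components."""

    k: int
    F: float
    df1: int
    df2: int
    p_value: float
    rss_km1: float
    rss_k: float


@dataclass
class SelectionResult:
    chosen_K: int
    reports: list[FTestReport]
    tail_reports: list[FTestReport]
    models: dict[int, DecompositionModel]


def _window_mask(drt: DRTResult, tau_window: tuple[float, float] | None) -> np.ndarray:
    tau = drt.grid.centers
    if tau_window is None:
        return np.ones(tau.size, dtype=bool)
    lo, hi = tau_window
    if not (0 < lo < hi):
        raise ValidationError("tau_window must satisfy 0 < lo < hi")
    return (tau >= lo) & (tau < hi)


def _model_curve(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a = params[0::3][:, None]
    m = params[1::3][:, None]
    s = params[2::3][:, None]
    return (a * np.exp(-((x[None, :] - m) ** 2) / (2.0 * s**2))).sum(axis=0)


def _initial_guesses(x: np.ndarray, y: np.ndarray, K: int,
                     rng: np.random.Generator, n_starts: int,
                     sigma_lo: float) -> list[np.ndarray]:
    """Multi-start initializations: local maxima of the smoothed curve, mass
    quantiles, and seeded jitters of both."""
    span = x[-1] - x[0]
    kernel = np.ones(5) / 5.0
    ys = np.convolve(y, kernel, mode="same")

    # (i) the K most prominent local maxima, padded with mass quantiles
    interior = np.arange(1, x.size - 1)
    is_max = (ys[interior] >= ys[interior - 1]) & (ys[interior] >= ys[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[np.argsort(ys[peaks])[::-1]]

    # (ii) quantiles of the cumulative mass
    cdf = np.cumsum(y)
    cdf = cdf / cdf[-1]
    q_locs = np.interp((np.arange(K) + 0.5) / K, cdf, x)

    amp0 = max(y.max(), 1e-12)
    sig0 = max(min(span / (2.0 * K), 1.0), 2 * sigma_lo)

    def pack(locs: np.ndarray) -> np.ndarray:
        p = np.empty(3 * K)
        amps = np.interp(locs, x, ys)
        p[0::3] = np.clip(amps, 0.05 * amp0, None)
        p[1::3] = locs
        p[2::3] = sig0
        return p

    starts = []
    peak_locs = list(x[peaks[:K]])
    while len(peak_locs) < K:
        peak_locs.append(float(q_locs[len(peak_locs) % K]))
    starts.append(pack(np.sort(np.asarray(peak_locs))))
    starts.append(pack(np.sort(q_locs)))
    while len(starts) < n_starts:
        base = starts[len(starts) % 2].copy()
        base[1::3] = np.clip(base[1::3] + rng.normal(0, 0.15 * sig0 + 0.1, K), x[0], x[-1])
        base[0::3] = base[0::3] * np.exp(rng.normal(0, 0.3, K))
        base[2::3] = np.clip(base[2::3] * np.exp(rng.normal(0, 0.3, K)),
                             sigma_lo, SIGMA_MAX)
        starts.append(base)
    return starts


def _refine(x: np.ndarray, y: np.ndarray, p0: np.ndarray,
            bounds: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, float]:
    p0 = np.clip(p0, bounds[0], bounds[1])
    res = scipy.optimize.least_squares(
        lambda p: _model_curve(p, x) - y,
        p0,
        bounds=bounds,
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=400 * p0.size,
    )
    return res.x, float(res.cost * 2.0)  # least_squares cost = rss/2


def fit_gaussians(
    drt: DRTResult,
    K: int,
    tau_window: tuple[float, float] | None = None,
    seed: int = 0,
    n_starts: int = 6,
    warm_start: DecompositionModel | None = None,
) -> DecompositionModel:
    """Least-squares fit of K Gaussians to the DRT curve ``R_p * G(x)``.

    Deterministic for a given seed: a fixed roster of initializations (curve
    maxima, mass quantiles, seeded jitters, plus an optional warm start) is
    refined with bounded trust-region least squares and the lowest-RSS fit
    wins.  Component locations are constrained to the fitted window and
    spreads to [max(0.05, 1.5 bins), 3] natural-log units.
    """
    if K < 1:
        raise ValidationError("K must be at least 1")
    mask = _window_mask(drt, tau_window)
    x = drt.grid.log_centers[mask]
    y = drt.curve[mask]
    n = int(mask.sum())
    if n < 3 * K + 1:
        raise ValidationError(
            f"K={K} needs at least {3 * K + 1} bins in the fit window, got {n}"
        )
    if not np.any(y > 0):
        raise ValidationError("DRT has no mass in the fit window")

    sigma_lo = _sigma_floor(drt.grid.bin_width_logtau)
    lb = np.tile([0.0, x[0], sigma_lo], K)
    ub = np.tile([10.0 * y.max(), x[-1], SIGMA_MAX], K)
    rng = np.random.default_rng(seed)
    starts = _initial_guesses(x, y, K, rng, n_starts, sigma_lo)
    if warm_start is not None:
        p = []
        for c in warm_start.components[:K]:
            p.extend([c.a, np.log(c.mu), c.sigma])
        k_have = len(p) // 3
        if k_have < K:
            resid = y - warm_start.evaluate(x)
            for _ in range(K - k_have):
                j = int(np.argmax(resid))
                p.extend([max(resid[j], 0.05 * y.max()), x[j],
                          max(2 * sigma_lo, 0.2)])
                resid = resid - _model_curve(np.asarray(p[-3:]), x)
        starts.insert(0, np.asarray(p))

    best_p, best_rss = None, np.inf
    for p0 in starts:
        try:
            p, rss = _refine(x, y, p0, (lb, ub))
        except Exception as exc:  # pragma: no cover - solver pathologies
            log.debug("gaussian fit start failed: %s", exc)
            continue
        if rss < best_rss:
            best_p, best_rss = p, rss
    if best_p is None:
        raise RuntimeError(
            f"gaussian fit did not converge for K={K} after {len(starts)} starts"
        )

    # tie-break exactly coincident locations (degenerate stacked components)
    # so the decreasing-mu ordering is strict
    locs = best_p[1::3]
    order = np.argsort(-locs)
    for i, j in zip(order, order[1:]):
        if locs[j] >= locs[i] - 1e-9:
            locs[j] = locs[i] - 1e-9
    best_p[1::3] = locs

    components = []
    for k in range(K):
        a, m, s = best_p[3 * k], best_p[3 * k + 1], best_p[3 * k + 2]
        if a <= 0:
            # a component pinned to zero amplitude carries no information
            warnings.warn(
                f"component {k} collapsed to zero amplitude in K={K} fit",
                stacklevel=2,
            )
            a = 1e-12 * max(y.max(), 1.0)
        components.append(GaussianComponent(a, float(np.exp(m)), s))
    model = DecompositionModel(components, drt.R_inf, best_rss, n)
    log.info("fit_gaussians: K=%d n=%d rss=%.4g R_0=%.4g", K, n, best_rss, model.R_0)
    return model


def component_resistances(model: DecompositionModel) -> tuple[np.ndarray, float]:
    """Per-component DC contributions R_pk = a_k sigma_k sqrt(2 pi) and the
    total DC resistance R_0 = R_inf + sum_k R_pk."""
    return model.R_pks, model.R_0


def f_test(rss_km1: float, rss_k: float, n: int, k: int) -> FTestReport:
    """Nested F-test: does the k-th Gaussian significantly reduce the RSS?

    F = (RSS_{k-1} - RSS_k)/RSS_k * (n - 3k - 1)/3 with an F(3, n - 3k - 1)
    reference distribution (three parameters per component).
    """
    if rss_k <= 0:
        raise ValidationError("rss_k must be positive (perfect fits leave F undefined)")
    if rss_km1 < rss_k:
        raise ValidationError("rss must be non-increasing in k (rss_km1 >= rss_k)")
    df2 = n - 3 * k - 1
    if df2 < 1:
        raise ValidationError(f"n={n} leaves no residual degrees of freedom at k={k}")
    F = (rss_km1 - rss_k) / rss_k * df2 / 3.0
    p = float(scipy.stats.f.sf(F, 3, df2))
    return FTestReport(k, float(F), 3, df2, p, rss_km1, rss_k)


def _tail_rss(model: DecompositionModel, drt: DRTResult, mask: np.ndarray) -> float:
    x = drt.grid.log_centers[mask]
    return float(np.sum((model.evaluate(x) - drt.curve[mask]) ** 2))


def select_K(
    drt: DRTResult,
    K_range: tuple[int, int] | range = (1, 8),
    p_threshold: float = 0.05,
    tail_cutoff: float | None = None,
    tau_window: tuple[float, float] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Choose the number of Gaussian components by sequential F-tests.

    Fits each K in ``K_range`` (warm-started from the previous fit so RSS is
    non-increasing by construction) and computes the F sequence for each
    increment.  When ``tail_cutoff`` is given, a second F sequence restricted
    to bins with tau < tail_cutoff is computed and drives the choice
    (sensitive to short-time structure that full-range tests wash out);
    otherwise the full-range sequence drives it.  The chosen K is the
    smallest whose increment to K+1 is insignificant (p > p_threshold).
    """
    if isinstance(K_range, range):
        ks = list(K_range)
    else:
        ks = list(range(K_range[0], K_range[1] + 1))
    if not ks or ks != list(range(ks[0], ks[-1] + 1)) or ks[0] < 1:
        raise ValidationError("K_range must be a contiguous ascending range of K >= 1")

    mask = _window_mask(drt, tau_window)
    if tail_cutoff is not None:
        tail_mask = mask & (drt.grid.centers < tail_cutoff)
        if not np.any(tail_mask):
            raise ValidationError(
                f"tail_cutoff={tail_cutoff} leaves no bins in the fit window"
            )

    models: dict[int, DecompositionModel] = {}
    warm = None
    for k in ks:
        model = fit_gaussians(drt, k, tau_window, seed=seed, warm_start=warm)
        if warm is not None and model.rss > models[k - 1].rss:
            # warm start guarantees the initial point matches rss_{k-1};
            # a worse converged rss means a failed refinement - retry harder
            model2 = fit_gaussians(drt, k, tau_window, seed=seed + 1,
                                   n_starts=10, warm_start=warm)
            if model2.rss < model.rss:
                model = model2
        models[k] = model
        warm = model

    reports, tail_reports = [], []
    for k in ks[1:]:
        reports.append(f_test(models[k - 1].rss, models[k].rss, models[k].n, k))
        if tail_cutoff is not None:
            r0 = _tail_rss(models[k - 1], drt, tail_mask)
            r1 = _tail_rss(models[k], drt, tail_mask)
            n_tail = int(tail_mask.sum())
            if r1 <= 0 or r0 < r1:
                tail_reports.append(
                    FTestReport(k, 0.0, 3, max(n_tail - 3 * k - 1, 1), 1.0, r0, r1)
                )
            else:
                tail_reports.append(f_test(r0, r1, n_tail, k))

    deciding = tail_reports if tail_cutoff is not None else reports
    chosen = ks[-1]
    for rep in deciding:
        if rep.p_value > p_threshold:
            chosen = rep.k - 1
            break
    else:
        warnings.warn(
            f"every increment up to K={ks[-1]} is significant; "
            "consider extending K_range",
            stacklevel=2,
        )
    if chosen < ks[0]:
        chosen = ks[0]
    log.info("select_K: chose K=%d (threshold p>%g, %s range)",
             chosen, p_threshold, "tail" if tail_cutoff is not None else "full")
    return SelectionResult(chosen, reports, tail_reports, models)
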