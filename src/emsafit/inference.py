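"""Estimation of (Kd, C, f) from titration band fractions.

The objective is unweighted least squares on normalized band fractions: one
residual per lane and band, observed fraction minus the mixture-occupancy
prediction at that lane's statistical weight ``alpha = conc / Kd``.  The
optimizer works in ``x = (log10 Kd, log10 C, f)`` — logarithms condition the
wide dynamic range of the ladder and enforce positivity through finite box
bounds — using trust-region-reflective least squares from a fixed,
deterministic multistart grid; the best sum of squares wins, with ties broken
toward C closest to 1 (the conservative, no-cooperativity reading).

Confidence intervals are percentile bootstrap: synthetic datasets are drawn
per (concentration, band) from a Gaussian with the replicate mean and SD of
the observed normalized fractions, truncated at zero and renormalized per
lane, and each is refit; the interval is the empirical quantile band of the
resample estimates.  The default resample count is 5,000 and the default
level 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares

from .binding_model import ModelParams
from .gel_io import (
    ReplicateSummary,
    TitrationSeries,
    normalized_fractions,
    summarize_replicates,
)

__all__ = [
    "DEFAULT_N_BOOT",
    "DEFAULT_CI_LEVEL",
    "FitOptions",
    "GridSpec",
    "FitResult",
    "BootstrapResult",
    "UnidentifiableSeriesError",
    "BootstrapFailureError",
    "residual_vector",
    "fit_model",
    "grid_oracle",
    "resample_series",
    "bootstrap_cis",
]

DEFAULT_N_BOOT = 5_000
DEFAULT_CI_LEVEL = 0.95

# Box bounds in fit coordinates (log10 Kd in nM, log10 C, f).
_LO = np.array([-3.0, -3.0, 0.0])
_HI = np.array([6.0, 3.0, 1.0])
_BOUND_TOL = 1e-6
_PARAM_NAMES = ("kd", "C", "f")


class UnidentifiableSeriesError(ValueError):
    """The series cannot constrain the three model parameters."""


class BootstrapFailureError(RuntimeError):
    """Too many bootstrap refits failed; carries the failure census."""

    def __init__(self, n_failed: int, n_boot: int):
        self.n_failed = n_failed
        self.n_boot = n_boot
        super().__init__(
            f"{n_failed}/{n_boot} bootstrap refits failed (> 50%); "
            "the series is likely unidentifiable under resampling noise"
        )


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the least-squares fit.

    ``weighted`` scales each residual by the inverse replicate SD of its
    (concentration, band) cell, floored at ``sd_floor`` to keep exactly
    reproducible cells from dominating.  ``replicate_means`` fits the
    per-concentration mean fractions instead of every lane.  ``starts``
    overrides the default multistart grid with explicit (kd, C, f) triples
    (used by the bootstrap to warm-start refits from the point estimate).
    """

    weighted: bool = False
    sd_floor: float = 1e-3
    replicate_means: bool = False
    starts: tuple[tuple[float, float, float], ...] | None = None


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive-search grid over (log10 Kd, log10 C, f) for verification."""

    n_kd: int = 40
    n_C: int = 40
    n_f: int = 20
    log10_kd_range: tuple[float, float] = (0.0, 4.0)
    log10_C_range: tuple[float, float] = (-2.0, 2.0)
    f_range: tuple[float, float] = (0.0, 1.0)

    def axes(self) -> tuple[NDArray, NDArray, NDArray]:
        if min(self.n_kd, self.n_C, self.n_f) < 1:
            raise ValueError("grid axes must have at least 1 point")
        return (
            np.linspace(*self.log10_kd_range, self.n_kd),
            np.linspace(*self.log10_C_range, self.n_C),
            np.linspace(*self.f_range, self.n_f),
        )


@dataclass(frozen=True)
class FitResult:
    """Point estimate of (Kd, C, f) for one titration series."""

    params: ModelParams
    ssr: float
    n_points: int
    converged: bool
    n_starts: int
    at_bound: tuple[str, ...] = ()
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.params.kd,
            "C": self.params.C,
            "f": self.params.f,
            "ssr": self.ssr,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "at_bound": list(self.at_bound),
        }


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap of the fit parameters.

    ``estimates`` has one row per successful resample refit, columns
    (kd, C, f); ``ci`` maps parameter name to (lower, upper) at ``level``.
    """

    n_boot: int
    seed: int
    level: float
    estimates: NDArray[np.float64] = field(repr=False)
    ci: dict[str, tuple[float, float]]
    n_failed: int

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "ci_level": self.level,
            "n_failed": self.n_failed,
            "ci": {
                "kd_nM": list(self.ci["kd"]),
                "C": list(self.ci["C"]),
                "f": list(self.ci["f"]),
            },
        }


def _design_matrices(
    series: TitrationSeries, options: FitOptions
) -> tuple[NDArray, NDArray, NDArray]:
    """Concentrations, observed fractions and residual weights for the fit."""
    if options.replicate_means:
        summary = summarize_replicates(series)
        conc = summary.mean.index.to_numpy(dtype=float)
        obs = summary.mean.to_numpy(dtype=float)
        sd = summary.sd.to_numpy(dtype=float)
    else:
        conc = series.lanes["conc_nM"].to_numpy(dtype=float)
        obs = normalized_fractions(series)
        if options.weighted:
            summary = summarize_replicates(series)
            sd = summary.sd.loc[conc].to_numpy(dtype=float)
        else:
            sd = None
    if options.weighted:
        weights = 1.0 / np.maximum(sd, options.sd_floor)
    else:
        weights = np.ones_like(obs)
    return conc, obs, weights


def _predict_fractions(conc: NDArray, kd: float, C: float, f: float) -> NDArray:
    """Mixture-occupancy fractions for each concentration, shape (n, 3)."""
    alpha = conc / kd
    z2 = 1.0 + 2.0 * alpha + C * alpha * alpha
    z1 = 1.0 + 2.0 * alpha
    p0 = f / z2 + (1.0 - f) / z1
    p1 = f * 2.0 * alpha / z2 + (1.0 - f) * 2.0 * alpha / z1
    p2 = f * C * alpha * alpha / z2
    return np.stack([p0, p1, p2], axis=-1)


_LN10 = np.log(10.0)


def _predict_jacobian(
    conc: NDArray, kd: float, C: float, f: float
) -> NDArray:
    """Analytic d(pred)/d(log10 kd, log10 C, f), shape (n, 3, 3).

    Middle axis is the band, last axis the fit coordinate.  Uses
    d(alpha)/d(log10 kd) = -alpha ln10 and dC/d(log10 C) = C ln10.
    """
    a = conc / kd
    z2 = 1.0 + 2.0 * a + C * a * a
    z1 = 1.0 + 2.0 * a
    inv_z2sq = 1.0 / (z2 * z2)
    inv_z1sq = 1.0 / (z1 * z1)
    p0 = f / z2 + (1.0 - f) / z1

    dz2_da = 2.0 + 2.0 * C * a
    dp0_da = -f * dz2_da * inv_z2sq - 2.0 * (1.0 - f) * inv_z1sq
    dp1_da = 2.0 * p0 + 2.0 * a * dp0_da
    dp2_da = f * C * a * (2.0 * z2 - a * dz2_da) * inv_z2sq

    dp0_dC = -f * a * a * inv_z2sq
    dp1_dC = 2.0 * a * dp0_dC
    dp2_dC = f * a * a * z1 * inv_z2sq

    dp0_df = 1.0 / z2 - 1.0 / z1
    dp1_df = 2.0 * a * dp0_df
    dp2_df = C * a * a / z2

    da_du = -a * _LN10  # u = log10 kd
    dC_dv = C * _LN10   # v = log10 C
    jac = np.empty((conc.size, 3, 3))
    jac[:, 0, 0] = dp0_da * da_du
    jac[:, 1, 0] = dp1_da * da_du
    jac[:, 2, 0] = dp2_da * da_du
    jac[:, 0, 1] = dp0_dC * dC_dv
    jac[:, 1, 1] = dp1_dC * dC_dv
    jac[:, 2, 1] = dp2_dC * dC_dv
    jac[:, 0, 2] = dp0_df
    jac[:, 1, 2] = dp1_df
    jac[:, 2, 2] = dp2_df
    return jac


def residual_vector(
    params: ModelParams,
    series: TitrationSeries,
    options: FitOptions = FitOptions(),
) -> NDArray[np.float64]:
    """Observed minus predicted fractions, flattened lane-major, band-minor.

    Length is ``3 * n_lanes`` (or ``3 * n_concentrations`` when fitting
    replicate means).
    """
    conc, obs, weights = _design_matrices(series, options)
    pred = _predict_fractions(conc, params.kd, params.C, params.f)
    return ((obs - pred) * weights).ravel()


def _default_starts(series: TitrationSeries) -> list[tuple[float, float, float]]:
    """Fixed multistart grid: Kd decades spanning the ladder x C x f."""
    conc = series.concentrations
    conc = conc[conc > 0]
    lo = int(np.floor(np.log10(conc.min())))
    hi = int(np.ceil(np.log10(conc.max())))
    kd_starts = [10.0**k for k in range(lo, hi + 1)]
    return [
        (kd, C, f)
        for kd in kd_starts
        for C in (0.1, 1.0, 10.0)
        for f in (0.5, 0.9)
    ]


def _clip_x(kd: float, C: float, f: float) -> NDArray:
    x = np.array([np.log10(kd), np.log10(C), f])
    return np.clip(x, _LO + 1e-9, _HI - 1e-9)


def fit_model(
    series: TitrationSeries, options: FitOptions = FitOptions()
) -> FitResult:
    """Fit (Kd, C, f) to one series by bounded multistart least squares.

    Deterministic given the series and options.  Parameters whose estimate
    lies on a box bound are listed in ``at_bound``; a false ``converged``
    still carries the best candidate found.
    """
    if series.n_distinct_concentrations() < 3:
        raise UnidentifiableSeriesError(
            f"series {series.condition!r} has "
            f"{series.n_distinct_concentrations()} distinct concentrations; "
            "at least 3 are required to constrain (Kd, C, f)"
        )
    conc, obs, weights = _design_matrices(series, options)

    def residuals(x: NDArray) -> NDArray:
        pred = _predict_fractions(conc, 10.0 ** x[0], 10.0 ** x[1], x[2])
        return ((obs - pred) * weights).ravel()

    def jac(x: NDArray) -> NDArray:
        j = _predict_jacobian(conc, 10.0 ** x[0], 10.0 ** x[1], x[2])
        return (-j * weights[:, :, None]).reshape(-1, 3)

    starts = (
        list(options.starts) if options.starts is not None
        else _default_starts(series)
    )
    candidates = []
    for kd0, C0, f0 in starts:
        try:
            sol = least_squares(
                residuals, _clip_x(kd0, C0, f0), jac=jac, bounds=(_LO, _HI),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        candidates.append((float(2.0 * sol.cost), sol.x, bool(sol.success)))
    if not candidates:
        raise UnidentifiableSeriesError(
            f"all {len(starts)} starts failed for series {series.condition!r}"
        )
    best_ssr = min(c[0] for c in candidates)
    # ties toward C closest to 1 (|log10 C| smallest)
    near = [c for c in candidates if c[0] <= best_ssr + 1e-12]
    ssr, x, success = min(near, key=lambda c: abs(c[1][1]))
    at_bound = tuple(
        name
        for name, xi, lo, hi in zip(_PARAM_NAMES, x, _LO, _HI)
        if xi - lo <= _BOUND_TOL or hi - xi <= _BOUND_TOL
    )
    return FitResult(
        params=ModelParams(kd=10.0 ** x[0], C=10.0 ** x[1], f=float(x[2])),
        ssr=ssr,
        n_points=obs.size,
        converged=success,
        n_starts=len(starts),
        at_bound=at_bound,
    )


def grid_oracle(
    series: TitrationSeries,
    grid: GridSpec = GridSpec(),
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Brute-force SSR minimisation over an exhaustive parameter grid.

    Verification tool: evaluates the sum of squared residuals at every grid
    point and returns the argmin.  Used in tests to bound the SSR reached by
    :func:`fit_model`; never the production estimator.
    """
    conc, obs, weights = _design_matrices(series, options)
    lkd, lC, fax = grid.axes()
    kd = 10.0 ** lkd
    C = 10.0 ** lC
    # broadcast to (n_kd, n_C, n_f, n_lanes, 3)
    alpha = conc[None, :] / kd[:, None]  # (n_kd, L)
    a = alpha[:, None, None, :]
    Cb = C[None, :, None, None]
    fb = fax[None, None, :, None]
    z2 = 1.0 + 2.0 * a + Cb * a * a
    z1 = 1.0 + 2.0 * a
    p0 = fb / z2 + (1.0 - fb) / z1
    p1 = fb * 2.0 * a / z2 + (1.0 - fb) * 2.0 * a / z1
    p2 = fb * Cb * a * a / z2
    pred = np.stack([p0, p1, p2], axis=-1)
    resid = (obs[None, None, None, :, :] - pred) * weights[None, None, None, :, :]
    ssr = np.einsum("ijklm,ijklm->ijk", resid, resid)
    i, j, k = np.unravel_index(np.argmin(ssr), ssr.shape)
    return FitResult(
        params=ModelParams(kd=float(kd[i]), C=float(C[j]), f=float(fax[k])),
        ssr=float(ssr[i, j, k]),
        n_points=obs.size,
        converged=True,
        n_starts=ssr.size,
        message="grid search",
    )


def resample_series(
    summary: ReplicateSummary,
    design: TitrationSeries,
    seed: int | np.random.SeedSequence,
    sd_override: float | None = None,
) -> TitrationSeries:
    """Draw one synthetic series matching the observed mean/SD structure.

    Each lane of ``design`` is replaced by fractions drawn independently per
    band from a Gaussian centred on its concentration cell's replicate mean,
    truncated at zero and renormalized to sum to 1.  Deterministic per seed.

    The Gaussian scale is calibrated so the resamples actually carry the
    summary's SD: per-lane renormalization shrinks the realized per-band SD
    by about ``sqrt(1 - 2*m + 3*m**2)`` (delta method, ``m`` the band's mean
    fraction), so the draw SD is divided by that factor; and the sample SD of
    ``n`` replicates underestimates the underlying scale by the standard
    normal-theory factor ``c4(n)``, which is divided out as well.  Without
    these corrections resampled datasets are systematically quieter than the
    data they are meant to mimic.

    A summary with single-replicate concentrations carries no measured
    spread; resampling then requires ``sd_override`` (the Gaussian draw SD,
    applied to all cells uncorrected) and refuses otherwise.
    """
    if summary.single_replicate and sd_override is None:
        raise ValueError(
            "summary contains single-replicate concentrations whose SD is "
            "unmeasured; supply sd_override to resample"
        )
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    conc = design.lanes["conc_nM"].to_numpy(dtype=float)
    mean = summary.mean.loc[conc].to_numpy(dtype=float)
    if sd_override is not None:
        sd = np.full_like(mean, float(sd_override))
    else:
        from scipy.special import gammaln

        n = summary.n_reps.loc[conc].to_numpy(dtype=float)
        c4 = np.where(
            n > 1,
            np.exp(
                0.5 * np.log(2.0 / np.maximum(n - 1, 1))
                + gammaln(n / 2.0)
                - gammaln(np.maximum(n - 1, 1) / 2.0)
            ),
            1.0,
        )
        shrink = np.sqrt(1.0 - 2.0 * mean + 3.0 * mean * mean)
        sd = summary.sd.loc[conc].to_numpy(dtype=float) / c4[:, None] / shrink
    frac = rng.normal(mean, sd)
    frac = np.clip(frac, 0.0, None)
    totals = frac.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] <= 0
    if degenerate.any():
        frac[degenerate] = mean[degenerate]
        totals = frac.sum(axis=1, keepdims=True)
    frac = frac / totals
    lanes = design.lanes.copy()
    lanes[["band0", "band1", "band2"]] = frac * 10_000.0
    return TitrationSeries(design.condition, lanes)


def bootstrap_cis(
    series: TitrationSeries,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = DEFAULT_CI_LEVEL,
    options: FitOptions = FitOptions(),
    sd_override: float | None = None,
) -> BootstrapResult:
    """Percentile bootstrap confidence intervals for (Kd, C, f).

    Resamples are drawn via :func:`resample_series` with sub-seeds spawned
    from ``seed`` by a fixed splitting rule, so increasing ``n_boot`` extends
    rather than reshuffles the resample stream.  Each resample is refit
    warm-started from the point estimate (plus a no-cooperativity fallback
    start), keeping refits deterministic and cheap.  Raises
    :class:`BootstrapFailureError` if more than half the refits fail.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = fit_model(series, options)
    summary = summarize_replicates(series)
    p = point.params
    refit_options = replace(
        options, starts=((p.kd, p.C, p.f), (p.kd, 1.0, 0.9))
    )
    children = np.random.SeedSequence(seed).spawn(n_boot)
    estimates = []
    n_failed = 0
    for child in children:
        try:
            resampled = resample_series(summary, series, child, sd_override)
            fit = fit_model(resampled, refit_options)
        except Exception:
            n_failed += 1
            continue
        q = fit.params
        estimates.append((q.kd, q.C, q.f))
    if n_failed > n_boot / 2:
        raise BootstrapFailureError(n_failed, n_boot)
    est = np.asarray(estimates, dtype=float)
    tail = 100.0 * (1.0 - level) / 2.0
    ci = {
        name: (
            float(np.percentile(est[:, i], tail)),
            float(np.percentile(est[:, i], 100.0 - tail)),
        )
        for i, name in enumerate(_PARAM_NAMES)
    }
    return BootstrapResult(
        n_boot=n_boot,
        seed=int(seed),
        level=level,
        estimates=est,
        ci=ci,
        n_failed=n_failed,
    )
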