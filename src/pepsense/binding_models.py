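"""1:1 sense–antisense binding: equilibrium model, K_d fitting, simulation.

The complex A·L of the signal-bearing antisense peptide A (fixed total
concentration) and the titrated epitope L obeys

    Kd = [A][L]/[AL],
    [AL] = ((A_t + L_t + Kd) − sqrt((A_t + L_t + Kd)² − 4·A_t·L_t)) / 2,

evaluated here in the numerically stable form 2·A_t·L_t/(b + sqrt(b² − 4·A_t·L_t)).
Two observation models share this core:

* **fluorescence**: signal = baseline + q_free·[A] + q_complex·[AL] — exactly
  two spectrally active species (the titrant is dark);
* **mst** (thermophoresis dose–response): response = R_unbound +
  (R_bound − R_unbound)·[AL]/A_t.

K_d is fitted by nonlinear least squares in log10 K_d (positivity enforced by
construction), with a multi-start over log-spaced K_d initial values when no
initial guess is supplied.  All concentrations are µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import lmfit
import numpy as np

__all__ = [
    "TitrationSeries",
    "SpectraMatrix",
    "BindingParams",
    "FitResult",
    "complex_concentration",
    "predict_signal",
    "mst_response",
    "fit_fluorescence",
    "fit_mst",
    "simulate_titration",
    "simulate_spectra",
    "estimate_n_species",
    "bootstrap_kd_ci",
]

Mode = Literal["fluorescence", "mst"]


@dataclass(frozen=True)
class TitrationSeries:
    """One dose–response titration record.

    ``fixed_total`` is the total concentration (µM) of the signal-bearing
    component; ``titrant_totals`` the strictly increasing totals (µM) of the
    dark partner; ``signal`` the observed response at each level.
    """

    fixed_total: float
    titrant_totals: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.titrant_totals, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "titrant_totals", t)
        object.__setattr__(self, "signal", s)
        if self.fixed_total <= 0:
            raise ValueError("fixed_total must be positive")
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("signal and titrant_totals must be 1-D and equal length")
        if np.any(t <= 0):
            raise ValueError("titrant totals must be strictly positive")
        if np.any(np.diff(t) <= 0):
            raise ValueError("titrant totals must be strictly increasing")

    def __len__(self) -> int:
        return self.titrant_totals.size


@dataclass(frozen=True)
class SpectraMatrix:
    """Titration spectra: one row per titration point, one column per
    wavelength (nm)."""

    wavelengths: np.ndarray
    spectra: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.spectra, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "spectra", m)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError("spectra must be a matrix with at least 2 rows")
        if m.shape[1] != w.size:
            raise ValueError("one spectra column per wavelength required")
        if not np.all(np.isfinite(m)):
            raise ValueError("spectra matrix contains non-finite values")


@dataclass(frozen=True)
class BindingParams:
    """1:1 model parameters: K_d (µM), per-µM signal coefficients of the free
    antisense peptide and of the complex, and an additive baseline.

    In MST mode ``q_free``/``q_complex`` are the unbound/bound response
    levels themselves (the dose–response is already normalised per molecule).
    """

    kd: float
    q_free: float
    q_complex: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit outcome: point estimate, K_d standard error (delta
    method from the log10 K_d covariance), residuals and convergence flag."""

    params: BindingParams
    kd_se: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    mode: Mode


def complex_concentration(
    a_total: float, l_total: float | np.ndarray, kd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equilibrium ([A]_free, [L]_free, [AL]) of the 1:1 model, µM.

    Vectorised over ``l_total``.  Uses the stable quadratic root
    2AL/(b + sqrt(b² − 4AL)); mass balance holds to machine precision.
    """
    lt = np.asarray(l_total, dtype=float)
    if a_total < 0 or np.any(lt < 0):
        raise ValueError("total concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("Kd must be positive")
    b = a_total + lt + kd
    disc = np.sqrt(np.maximum(b * b - 4.0 * a_total * lt, 0.0))
    al = np.where(b + disc > 0, 2.0 * a_total * lt / (b + disc), 0.0)
    return a_total - al, lt - al, al


def predict_signal(params: BindingParams, series: TitrationSeries) -> np.ndarray:
    """Fluorescence forward model: baseline + q_free·[A] + q_complex·[AL]."""
    a_free, _, al = complex_concentration(
        series.fixed_total, series.titrant_totals, params.kd
    )
    return params.baseline + params.q_free * a_free + params.q_complex * al


def mst_response(params: BindingParams, series: TitrationSeries) -> np.ndarray:
    """Thermophoresis forward model: R_un + (R_b − R_un)·fraction bound."""
    _, _, al = complex_concentration(
        series.fixed_total, series.titrant_totals, params.kd
    )
    frac = al / series.fixed_total
    return params.q_free + (params.q_complex - params.q_free) * frac


_MODELS: dict[Mode, Callable[[BindingParams, TitrationSeries], np.ndarray]] = {
    "fluorescence": predict_signal,
    "mst": mst_response,
}


def _initial_q(series: TitrationSeries, mode: Mode) -> tuple[float, float]:
    """Crude start values for the signal coefficients from the curve ends."""
    lo, hi = float(series.signal[0]), float(series.signal[-1])
    if mode == "fluorescence":
        return lo / series.fixed_total, hi / series.fixed_total
    return lo, hi


def _fit(series: TitrationSeries, mode: Mode, init: BindingParams | None) -> FitResult:
    if len(series) < 4:
        raise ValueError(f"need at least 4 titration points, got {len(series)}")
    if np.ptp(series.signal) == 0:
        raise ValueError("signal is constant; binding parameters are not identifiable")

    model = _MODELS[mode]
    baseline = init.baseline if init is not None else 0.0

    def residual(p: lmfit.Parameters) -> np.ndarray:
        params = BindingParams(
            kd=10.0 ** p["log10_kd"].value,
            q_free=p["q_free"].value,
            q_complex=p["q_complex"].value,
            baseline=p["baseline"].value,
        )
        return model(params, series) - series.signal

    if init is not None:
        kd_starts = [init.kd]
        q0, q1 = init.q_free, init.q_complex
    else:
        t = series.titrant_totals
        kd_starts = list(np.geomspace(0.1 * t.min(), 100.0 * t.max(), 7))
        q0, q1 = _initial_q(series, mode)

    best = None
    for kd0 in kd_starts:
        pars = lmfit.Parameters()
        # bounds keep 10**log10_kd finite and positive during line searches
        pars.add("log10_kd", value=math.log10(kd0), min=-9.0, max=9.0)
        pars.add("q_free", value=q0)
        pars.add("q_complex", value=q1)
        # held fixed: with a fixed fluorophore total the offset is collinear
        # with q_free, so freeing it would make the covariance singular
        pars.add("baseline", value=baseline, vary=False)
        res = lmfit.minimize(
            residual, pars, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=20000
        )
        if best is None or res.chisqr < best.chisqr:
            best = res

    kd = 10.0 ** best.params["log10_kd"].value
    se_log = best.params["log10_kd"].stderr
    kd_se = float(kd * math.log(10.0) * se_log) if se_log is not None else math.nan
    fitted = BindingParams(
        kd=kd,
        q_free=float(best.params["q_free"].value),
        q_complex=float(best.params["q_complex"].value),
        baseline=baseline,
    )
    return FitResult(
        params=fitted,
        kd_se=kd_se,
        residuals=np.asarray(best.residual, dtype=float),
        converged=bool(best.success),
        n_points=len(series),
        mode=mode,
    )


def fit_fluorescence(
    series: TitrationSeries, init: BindingParams | None = None
) -> FitResult:
    """Fit K_d and signal coefficients to a fluorescence titration.

    Without ``init``, a multi-start over 7 log-spaced K_d values spanning
    [0.1·min titrant, 100·max titrant] guards against local minima.
    """
    return _fit(series, "fluorescence", init)


def fit_mst(series: TitrationSeries, init: BindingParams | None = None) -> FitResult:
    """Fit K_d and bound/unbound response levels to an MST dose–response."""
    return _fit(series, "mst", init)


def simulate_titration(
    truth: BindingParams,
    fixed_total: float,
    titrant_totals: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    mode: Mode = "fluorescence",
    relative_noise: bool = False,
    meta: dict | None = None,
) -> TitrationSeries:
    """Forward-simulate a titration, optionally with Gaussian noise.

    ``noise_sd`` is an absolute standard deviation by default; with
    ``relative_noise`` it is a fraction of the clean signal at each point
    (multiplicative noise).  Reproducible: the same seed yields an identical
    series; a seed is required whenever ``noise_sd`` > 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    clean = TitrationSeries(
        fixed_total=fixed_total,
        titrant_totals=np.asarray(titrant_totals, dtype=float),
        signal=np.zeros(len(titrant_totals)),
        meta=meta or {},
    )
    signal = _MODELS[mode](truth, clean)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd * np.abs(signal) if relative_noise else noise_sd
        signal = signal + sd * rng.standard_normal(signal.shape)
    return replace(clean, signal=signal)


def simulate_spectra(
    concentrations: np.ndarray,
    shapes: np.ndarray,
    wavelengths: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SpectraMatrix:
    """Build a titration spectra matrix C·S (+ Gaussian noise) from species
    concentration columns C (points × species) and spectral shapes S
    (species × wavelengths)."""
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    s = np.atleast_2d(np.asarray(shapes, dtype=float))
    m = c @ s
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    return SpectraMatrix(wavelengths=np.asarray(wavelengths, float), spectra=m)


def estimate_n_species(
    m: SpectraMatrix, noise_level: float, margin: float = 1.1
) -> int:
    """Count spectrally active species by singular value thresholding.

    Singular values are compared against the largest value expected from a
    pure-noise matrix of the given per-element noise standard deviation,
    ≈ noise_level·(√rows + √cols) (Marchenko–Pastur edge), inflated by a
    small ``margin`` to absorb edge fluctuations.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    sv = np.linalg.svd(m.spectra, compute_uv=False)
    rows, cols = m.spectra.shape
    threshold = margin * noise_level * (math.sqrt(rows) + math.sqrt(cols))
    return int(np.sum(sv > threshold))


def bootstrap_kd_ci(
    series: TitrationSeries,
    fit: FitResult,
    n_boot: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Residual-resampling bootstrap percentile interval for K_d (µM)."""
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if len(series) < 5:
        raise ValueError("too few titration points for a residual bootstrap")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    fitted = _MODELS[fit.mode](fit.params, series)
    resid = series.signal - fitted
    kds = np.empty(n_boot)
    for b in range(n_boot):
        boot_signal = fitted + rng.choice(resid, size=resid.size, replace=True)
        boot = replace(series, signal=boot_signal)
        kds[b] = _fit(boot, fit.mode, init=fit.params).params.kd
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(kds, [alpha, 1.0 - alpha])
    return float(low), float(high)
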