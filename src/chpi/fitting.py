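"""Recovery of 1:1 binding parameters from titration data.

NMR titrations are fitted globally: one association constant K shared
across all observed signals, plus free/bound limiting shifts per signal,
minimising the summed squared shift residuals.
ITC thermograms are fitted to the 1:1 Wiseman-type isotherm with
parameters (n, K, ΔH), or (K, ΔH) at fixed n = 1.

K is optimised on a log10 scale, which enforces positivity and keeps the
problem well conditioned over the 10⁰–10⁸ M⁻¹ range met in practice.  A
multi-start over a log-spaced K grid guards against local minima; for a
trial K the remaining parameters enter the model linearly and are
profiled out in closed form, so the grid scan is cheap.  Uncertainties
default to asymptotic standard errors from the residual-scaled parameter
covariance; a residual-resampling bootstrap is available as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import (
    ITCExperiment,
    ITCModelParams,
    TitrationSeries,
    predict_itc_heats,
)
from .hbond import ThermoConstants

__all__ = [
    "BindingResult",
    "BootstrapResult",
    "UnidentifiableKError",
    "IsothermConditioningWarning",
    "fit_nmr_titration",
    "fit_itc",
    "bootstrap_uncertainty",
]

LN10 = np.log(10.0)


class UnidentifiableKError(ValueError):
    """Raised when the data carry no information about the binding constant."""


class IsothermConditioningWarning(UserWarning):
    """ITC c-parameter outside the window where K is well determined."""


@dataclass
class BindingResult:
    """A fitted (or tabulated) association constant with its free energy.

    ``dG`` is −RT ln K at ``temperature``; sigmas are one standard error.
    For a non-converged/unidentifiable fit ``converged`` is False, the
    offending condition is named in ``flags`` and K may be NaN.
    """

    K: float
    K_sigma: float
    dG: float
    dG_sigma: float
    method: str
    temperature: float = 298.0
    host_id: str = ""
    guest_id: str = ""
    n: Optional[float] = None
    n_sigma: Optional[float] = None
    dH: Optional[float] = None
    dH_sigma: Optional[float] = None
    residual_rms: float = float("nan")
    converged: bool = True
    flags: Tuple[str, ...] = ()
    shift_params: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_K(
        cls,
        K: float,
        K_sigma: float = 0.0,
        method: str = "tabulated",
        const: ThermoConstants = ThermoConstants(),
        **kwargs,
    ) -> "BindingResult":
        """Build a result from a known K, propagating σ_K to ΔG as RT·σ_K/K."""
        if K <= 0:
            raise ValueError(f"K must be > 0, got {K}")
        return cls(
            K=K,
            K_sigma=K_sigma,
            dG=-const.RT * np.log(K),
            dG_sigma=const.RT * K_sigma / K,
            method=method,
            temperature=const.T,
            **kwargs,
        )


@dataclass
class BootstrapResult:
    """Empirical K uncertainty from residual resampling."""

    K_sigma: float
    ci_low: float
    ci_high: float
    samples: np.ndarray


# ---------------------------------------------------------------------------
# shared speciation kernel (vectorised over titration points)


def _complex_conc(H0: np.ndarray, G0: np.ndarray, K: float) -> np.ndarray:
    b = H0 + G0 + 1.0 / K
    disc = np.maximum(b * b - 4.0 * H0 * G0, 0.0)
    return 2.0 * H0 * G0 / (b + np.sqrt(disc))


# ---------------------------------------------------------------------------
# NMR global fit


def _nmr_masks(series: TitrationSeries) -> Dict[str, np.ndarray]:
    """Finite-observation mask per signal (guest signals drop G0 = 0 points)."""
    G0 = series.G0
    masks = {}
    for sid, obs in series.signals.items():
        mask = np.isfinite(obs)
        if series.owners[sid] == "guest":
            mask &= G0 > 0
        masks[sid] = mask
    return masks


def _bound_fraction(series: TitrationSeries, sid: str, K: float) -> np.ndarray:
    H0, G0 = series.H0, series.G0
    hg = _complex_conc(H0, G0, K)
    if series.owners[sid] == "host":
        return hg / H0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(G0 > 0, hg / np.where(G0 > 0, G0, 1.0), np.nan)


def _profile_shifts(
    series: TitrationSeries, masks: Dict[str, np.ndarray], log10K: float
) -> Tuple[float, Dict[str, Tuple[float, float]]]:
    """For fixed K, solve each signal's (δ_free, δ_bound) linearly; return SSR."""
    K = 10.0**log10K
    ssr = 0.0
    shift_params = {}
    for sid, obs in series.signals.items():
        m = masks[sid]
        f = _bound_fraction(series, sid, K)[m]
        y = obs[m]
        A = np.column_stack([1.0 - f, f])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        r = A @ coef - y
        ssr += float(r @ r)
        shift_params[sid] = (float(coef[0]), float(coef[1]))
    return ssr, shift_params


def _nmr_residuals(
    x: np.ndarray, series: TitrationSeries, masks: Dict[str, np.ndarray]
) -> np.ndarray:
    K = 10.0 ** x[0]
    res = []
    for j, (sid, obs) in enumerate(series.signals.items()):
        m = masks[sid]
        f = _bound_fraction(series, sid, K)[m]
        d_free, d_bound = x[1 + 2 * j], x[2 + 2 * j]
        pred = d_free * (1.0 - f) + d_bound * f
        res.append(pred - obs[m])
    return np.concatenate(res)


def fit_nmr_titration(
    series: TitrationSeries,
    init: Optional[float] = None,
    noise_floor: float = 0.01,
    const: Optional[ThermoConstants] = None,
    host_id: str = "",
    guest_id: str = "",
) -> BindingResult:
    """Global 1:1 fit of an NMR titration: shared K, per-signal shift limits.

    Parameters
    ----------
    series
        Titration points and observed shifts (ppm).
    init
        Optional starting K (M⁻¹); added to the multi-start grid.
    noise_floor
        Minimum total shift excursion (ppm) any signal must show; if every
        signal is flat below this, K is unidentifiable and
        :class:`UnidentifiableKError` is raised.

    Returns the fitted K with asymptotic standard errors and the fitted
    δ_free/δ_bound per signal in ``shift_params``.
    """
    if const is None:
        const = ThermoConstants(T=series.temperature)
    masks = _nmr_masks(series)
    n_obs = sum(int(m.sum()) for m in masks.values())
    n_par = 1 + 2 * len(series.signals)
    if n_obs <= n_par:
        raise ValueError(
            f"{n_obs} observations cannot constrain {n_par} parameters"
        )
    excursions = [
        float(np.ptp(series.signals[sid][m])) for sid, m in masks.items() if m.any()
    ]
    if not excursions or max(excursions) < noise_floor:
        raise UnidentifiableKError(
            "all signals are flat within the noise floor; K is unidentifiable"
        )

    # Multi-start: profile the linear shift parameters on a log-spaced K grid.
    grid = list(np.linspace(-1.0, 8.0, 8))
    if init is not None and init > 0:
        grid.append(float(np.log10(init)))
    scored = sorted((_profile_shifts(series, masks, g)[0], g) for g in grid)
    best = None
    for _, g in scored[:3]:
        _, shifts = _profile_shifts(series, masks, g)
        x0 = np.concatenate([[g], np.ravel([shifts[s] for s in series.signals])])
        sol = least_squares(_nmr_residuals, x0, args=(series, masks), method="lm")
        if best is None or sol.cost < best.cost:
            best = sol

    return _package_nmr(best, series, masks, n_obs, n_par, const, host_id, guest_id)


def _package_nmr(sol, series, masks, n_obs, n_par, const, host_id, guest_id):
    K = 10.0 ** sol.x[0]
    ssr = 2.0 * sol.cost
    dof = n_obs - n_par
    s2 = ssr / dof if dof > 0 else float("nan")
    cov = _covariance(sol.jac, s2)
    sig_log10K = np.sqrt(cov[0, 0]) if cov is not None else float("nan")
    K_sigma = LN10 * K * sig_log10K
    converged = bool(sol.success) and np.isfinite(K_sigma)
    shift_params = {
        sid: (float(sol.x[1 + 2 * j]), float(sol.x[2 + 2 * j]))
        for j, sid in enumerate(series.signals)
    }
    return BindingResult(
        K=K,
        K_sigma=float(K_sigma),
        dG=float(-const.RT * np.log(K)),
        dG_sigma=float(const.RT * K_sigma / K),
        method="NMR",
        temperature=const.T,
        host_id=host_id,
        guest_id=guest_id,
        residual_rms=float(np.sqrt(ssr / n_obs)),
        converged=converged,
        flags=() if converged else ("non_convergence",),
        shift_params=shift_params,
    )


def _covariance(jac: np.ndarray, s2: float) -> Optional[np.ndarray]:
    try:
        jtj = jac.T @ jac
        return s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# ITC fit


def _itc_residuals(
    x: np.ndarray, exp: ITCExperiment, use: np.ndarray, float_n: bool
) -> np.ndarray:
    n = x[2] if float_n else 1.0
    K = 10.0 ** x[0]
    if n <= 0 or not (0.0 < K < np.inf):
        # penalty for excursions outside the physical domain
        return np.full(int(use.sum()), float(np.max(np.abs(exp.heats))) * 1e3)
    params = ITCModelParams(n=n, K=K, dH=x[1])
    return predict_itc_heats(exp, params)[use] - exp.heats[use]


def fit_itc(
    exp: ITCExperiment,
    float_n: bool = False,
    skip_first: bool = True,
    init_K: Optional[float] = None,
    const: Optional[ThermoConstants] = None,
    host_id: str = "",
    guest_id: str = "",
) -> BindingResult:
    """Least-squares fit of an ITC thermogram to the 1:1 isotherm.

    The first injection is excluded by default (syringe-tip diffusion
    artefact in practice).  With ``float_n`` the stoichiometry is a free
    parameter; the default fixes n = 1, the appropriate choice whenever
    the stoichiometry is known independently — in particular for runs
    that stop short of the equivalence point, where (n, K, ΔH) are
    jointly degenerate and floating n leaves K unidentified.  Emits
    :class:`IsothermConditioningWarning` when the Wiseman c-parameter
    n·K·[cell] leaves the [1, 1000] window where the isotherm shape
    determines K, and when n is floated on a titration that never
    reaches one molar equivalent.  An all-zero thermogram yields a
    flagged, non-converged result (ΔH ≈ 0, K unidentifiable) rather
    than an error.
    """
    if exp.heats is None:
        raise ValueError("experiment has no measured heats")
    if const is None:
        const = ThermoConstants(T=exp.temperature)
    use = np.ones(exp.n_injections, dtype=bool)
    if skip_first:
        use[0] = False
    if int(use.sum()) < 5:
        raise ValueError("need at least 5 usable injections")

    heat_scale = float(np.max(np.abs(exp.heats[use])))
    if heat_scale == 0.0:
        return BindingResult(
            K=float("nan"),
            K_sigma=float("inf"),
            dG=float("nan"),
            dG_sigma=float("inf"),
            method="ITC",
            temperature=const.T,
            host_id=host_id,
            guest_id=guest_id,
            n=1.0,
            dH=0.0,
            residual_rms=0.0,
            converged=False,
            flags=("unidentifiable_K", "zero_heats"),
        )

    total_ratio = (
        exp.syringe_conc * float(np.sum(exp.injection_volumes))
        / (exp.cell_conc * exp.cell_volume)
    )
    if float_n and total_ratio < 1.0:
        warnings.warn(
            f"titration reaches only {total_ratio:.2f} molar equivalents; "
            "floating n on a pre-equivalence isotherm leaves K ill-determined "
            "(consider float_n=False)",
            IsothermConditioningWarning,
            stacklevel=2,
        )

    # Grid scan: ΔH enters linearly at fixed (K, n); profile it in closed form.
    grid = list(np.linspace(0.0, 9.0, 8))
    if init_K is not None and init_K > 0:
        grid.append(float(np.log10(init_K)))
    starts = []
    for g in grid:
        unit = predict_itc_heats(exp, ITCModelParams(n=1.0, K=10.0**g, dH=1.0))[use]
        denom = float(unit @ unit)
        if denom == 0.0:
            continue
        dh = float(unit @ exp.heats[use]) / denom
        r = dh * unit - exp.heats[use]
        starts.append((float(r @ r), g, dh))
    starts.sort()

    best = None
    for _, g, dh in starts[:3]:
        x0 = [g, dh, 1.0] if float_n else [g, dh]
        sol = least_squares(
            _itc_residuals, x0, args=(exp, use, float_n), method="lm"
        )
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best

    K = 10.0 ** sol.x[0]
    dH = float(sol.x[1])
    n = float(sol.x[2]) if float_n else 1.0
    n_obs = int(use.sum())
    n_par = 3 if float_n else 2
    dof = n_obs - n_par
    ssr = 2.0 * sol.cost
    s2 = ssr / dof if dof > 0 else float("nan")
    cov = _covariance(sol.jac, s2)
    if cov is not None:
        sig_log10K = float(np.sqrt(cov[0, 0]))
        dH_sigma = float(np.sqrt(cov[1, 1]))
        n_sigma = float(np.sqrt(cov[2, 2])) if float_n else 0.0
    else:
        sig_log10K = dH_sigma = n_sigma = float("nan")
    K_sigma = LN10 * K * sig_log10K

    c = n * K * exp.cell_conc
    if not (1.0 <= c <= 1000.0):
        warnings.warn(
            f"Wiseman c-parameter {c:.3g} outside [1, 1000]; "
            "the isotherm poorly conditions K",
            IsothermConditioningWarning,
            stacklevel=2,
        )

    converged = bool(sol.success) and np.isfinite(K_sigma)
    return BindingResult(
        K=K,
        K_sigma=float(K_sigma),
        dG=float(-const.RT * np.log(K)),
        dG_sigma=float(const.RT * K_sigma / K),
        method="ITC",
        temperature=const.T,
        host_id=host_id,
        guest_id=guest_id,
        n=n,
        n_sigma=n_sigma,
        dH=dH,
        dH_sigma=dH_sigma,
        residual_rms=float(np.sqrt(ssr / n_obs)),
        converged=converged,
        flags=() if converged else ("non_convergence",),
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_uncertainty(
    data: Union[TitrationSeries, ITCExperiment],
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Residual-resampling bootstrap of the fitted K.

    The model is fitted once; pooled residuals are resampled with
    replacement onto the fitted values and the fit repeated ``n_boot``
    times.  Deterministic under a fixed ``seed``.  Requires a converged
    base fit and ``n_boot >= 10``.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    rng = np.random.default_rng(seed)

    if isinstance(data, TitrationSeries):
        base = fit_nmr_titration(data, **fit_kwargs)
        if not base.converged:
            raise ValueError("base fit did not converge; bootstrap unavailable")
        masks = _nmr_masks(data)
        fitted = {}
        residuals = []
        for sid, obs in data.signals.items():
            f = _bound_fraction(data, sid, base.K)
            d_free, d_bound = base.shift_params[sid]
            pred = d_free * (1.0 - f) + d_bound * f
            fitted[sid] = pred
            residuals.append((obs - pred)[masks[sid]])
        pool = np.concatenate(residuals)
        samples = []
        for _ in range(n_boot):
            signals = {}
            for sid, obs in data.signals.items():
                new = np.where(
                    masks[sid], fitted[sid] + rng.choice(pool, size=obs.size), np.nan
                )
                signals[sid] = new
            boot = TitrationSeries(
                points=data.points,
                signals=signals,
                owners=dict(data.owners),
                temperature=data.temperature,
            )
            try:
                samples.append(fit_nmr_titration(boot, init=base.K, **fit_kwargs).K)
            except (UnidentifiableKError, ValueError):
                continue
    elif isinstance(data, ITCExperiment):
        base = fit_itc(data, **fit_kwargs)
        if not base.converged:
            raise ValueError("base fit did not converge; bootstrap unavailable")
        params = ITCModelParams(n=base.n or 1.0, K=base.K, dH=base.dH)
        pred = predict_itc_heats(data, params)
        pool = data.heats - pred
        samples = []
        for _ in range(n_boot):
            boot = ITCExperiment(
                cell_conc=data.cell_conc,
                syringe_conc=data.syringe_conc,
                cell_volume=data.cell_volume,
                injection_volumes=data.injection_volumes,
                heats=pred + rng.choice(pool, size=pool.size),
                temperature=data.temperature,
            )
            try:
                samples.append(fit_itc(boot, init_K=base.K, **fit_kwargs).K)
            except ValueError:
                continue
    else:
        raise TypeError(f"cannot bootstrap a {type(data).__name__}")

    arr = np.asarray(samples)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return BootstrapResult(
        K_sigma=float(np.std(arr, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        samples=arr,
    )
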