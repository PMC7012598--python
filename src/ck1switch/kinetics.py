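"""Quantitative enzymology: efficiencies, half-lives, and the
phosphoswitch regression.

The substrate-selectivity framework compares CK1's catalytic efficiency
(kcat/Km, an apparent second-order rate constant in M⁻¹s⁻¹) on the
stabilizing FASP region of PER2 versus the degrading Degron site, and
relates the FASP/Degron efficiency ratio to the PER2::LUC half-life
measured by luminescence decay after cycloheximide. Under substrate
concentrations far below Km, product formation is pseudo-first-order:

    P(t) = S0 · (1 − exp(−(kcat/Km) · E · t))

so a single endpoint inverts to kcat/Km = −ln(1 − P/S0) / (E·t). PER2
stability is modelled as a one-phase exponential decay
Y(t) = (Y0 − plateau)·exp(−k·(t − t₀)) + plateau with half-life ln2/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lmfit import Model
from scipy import stats

__all__ = [
    "ProgressCurve",
    "EfficiencyEstimate",
    "DecayFit",
    "RegressionFit",
    "SiteRatioSeries",
    "initial_rate",
    "estimate_efficiency",
    "site_ratio",
    "fit_one_phase_decay",
    "efficiency_halflife_regression",
]


class KineticsError(ValueError):
    pass


@dataclass
class ProgressCurve:
    """Timepoints (strictly increasing) and signal for one replicate."""

    timepoints: np.ndarray  # s (enzymology) or hr (decay) — record in `time_unit`
    signal: np.ndarray  # product µM, counts, or peak volume
    time_unit: str = "s"
    signal_unit: str = "uM"
    replicate: int | str | None = None
    substrate: str = "other"  # FASP, Degron, other

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.timepoints.shape != self.signal.shape:
            raise KineticsError("timepoints and signal must have equal length")
        if len(self.timepoints) > 1 and not np.all(np.diff(self.timepoints) > 0):
            raise KineticsError("timepoints must be strictly increasing")


@dataclass
class EfficiencyEstimate:
    """kcat/Km in M⁻¹s⁻¹ with replicate scatter and assay conditions."""

    kcat_over_km: float
    sd: float
    n: int
    conditions: dict


@dataclass
class DecayFit:
    """One-phase decay fit: Y = span·exp(−k·(t−t0)) + plateau."""

    span: float
    plateau: float
    rate: float  # hr⁻¹
    half_life: float  # hr
    t_start: float
    t_end: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.span * np.exp(-self.rate * (np.asarray(t) - self.t_start)) + self.plateau


@dataclass
class RegressionFit:
    """OLS of half-life on efficiency ratio, with a 95% CI band."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r_squared: float
    p_value: float
    band_x: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray


@dataclass
class SiteRatioSeries:
    """Pointwise ratio of two site intensities with propagated noise."""

    timepoints: np.ndarray
    ratio: np.ndarray  # NaN where undefined
    sd: np.ndarray
    defined: np.ndarray  # False where denominator is below the noise floor


def initial_rate(curve: ProgressCurve, window: slice | tuple[float, float] | None = None,
                 s0: float | None = None, max_conversion: float = 0.10):
    """Least-squares initial slope (signal units per time) with its SE.

    ``window`` selects early timepoints by index slice or (t_min, t_max);
    when the substrate concentration ``s0`` is known the window is further
    restricted to below ``max_conversion`` fractional conversion.
    """
    t, y = curve.timepoints, curve.signal
    if isinstance(window, slice):
        t, y = t[window], y[window]
    elif isinstance(window, tuple):
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    if s0 is not None:
        keep = y <= max_conversion * s0
        if keep.sum() >= 3:
            t, y = t[keep], y[keep]
    if len(t) < 3:
        raise KineticsError(f"initial-rate window holds {len(t)} points; need ≥ 3")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def estimate_efficiency(
    product: float | np.ndarray,
    e_total: float,
    s0: float,
    t: float,
    conditions: dict | None = None,
) -> EfficiencyEstimate:
    """kcat/Km from endpoint product under pseudo-first-order depletion.

    ``product``, ``s0`` in the same concentration unit; ``e_total`` in M;
    ``t`` in s. Scalar input gives a single estimate (sd 0); an array is
    treated as replicates, reported as mean ± s.d.

    Raises a saturation error when P ≥ S0 (the log form is undefined) and
    a data error for negative product.
    """
    p = np.atleast_1d(np.asarray(product, dtype=float))
    if np.any(p < 0):
        raise KineticsError("negative product concentration")
    if np.any(p >= s0):
        raise KineticsError(
            "product reached or exceeded S0; endpoint estimate undefined (saturation)"
        )
    if e_total <= 0 or s0 <= 0 or t <= 0:
        raise KineticsError("E_total, S0 and t must be positive")
    k = -np.log(1.0 - p / s0) / (e_total * t)
    return EfficiencyEstimate(
        kcat_over_km=float(np.mean(k)),
        sd=float(np.std(k, ddof=1)) if len(k) > 1 else 0.0,
        n=len(k),
        conditions=dict(conditions or {}, E_total_M=e_total, S0=s0, t_s=t),
    )


def site_ratio(
    numerator: ProgressCurve,
    denominator: ProgressCurve,
    noise_sd: float,
    floor_factor: float = 3.0,
) -> SiteRatioSeries:
    """Pointwise ratio of two site signals with first-order error propagation.

    ``noise_sd`` is the spectral noise s.d. applied to both signals. The
    ratio is flagged undefined wherever the denominator falls below
    ``floor_factor × noise_sd``.
    """
    if len(numerator.timepoints) != len(denominator.timepoints) or not np.allclose(
        numerator.timepoints, denominator.timepoints
    ):
        raise KineticsError("numerator and denominator timepoints do not match")
    num, den = numerator.signal, denominator.signal
    defined = den > floor_factor * noise_sd
    ratio = np.full_like(num, np.nan, dtype=float)
    sd = np.full_like(num, np.nan, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
        # var(r)/r² = var(num)/num² + var(den)/den² to first order
        rel = np.sqrt((noise_sd / num) ** 2 + (noise_sd / den) ** 2)
    ratio[defined] = r[defined]
    sd[defined] = np.abs(r[defined]) * rel[defined]
    return SiteRatioSeries(
        timepoints=numerator.timepoints.copy(), ratio=ratio, sd=sd, defined=defined
    )


def _one_phase(t, span, plateau, rate, t0):
    return span * np.exp(-rate * (t - t0)) + plateau


def fit_one_phase_decay(
    timepoints: np.ndarray,
    signal: np.ndarray,
    t_chx: float = 0.0,
) -> DecayFit:
    """Fit Y(t) = (Y0 − plateau)·exp(−k·(t − t_chx)) + plateau.

    The fit window runs from the treatment time ``t_chx`` to the observed
    minimum of the signal (the plateau of minimum activity). Initial
    values: Y0 = first in-window point, plateau = window minimum, k from a
    log-linear fit of Y − plateau. Nonlinear least squares via lmfit;
    half-life = ln2/k in the input time unit.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(signal, dtype=float)
    t_end = float(t[np.argmin(y)])
    keep = (t >= t_chx) & (t <= t_end)
    t_fit, y_fit = t[keep], y[keep]
    if len(t_fit) < 5:
        raise KineticsError(
            f"only {len(t_fit)} points between CHX addition and the minimum; need ≥ 5"
        )
    if np.ptp(y_fit) == 0:
        raise KineticsError("signal is constant; no decay to fit")

    plateau0 = float(y_fit.min())
    span0 = float(y_fit[0] - plateau0)
    if span0 <= 0:
        raise KineticsError("signal does not decay from the treatment point")
    # log-linear initial rate from the upper part of the decay
    resid = y_fit - plateau0
    pos = resid > 0.05 * span0
    if pos.sum() >= 2:
        k0 = -stats.linregress(t_fit[pos], np.log(resid[pos])).slope
    else:
        k0 = 1.0
    k0 = max(k0, 1e-6)

    model = Model(_one_phase, independent_vars=["t"])
    params = model.make_params(span=span0, plateau=plateau0, rate=k0, t0=t_chx)
    params["t0"].set(vary=False)
    params["rate"].set(min=0)
    params["span"].set(min=0)
    result = model.fit(y_fit, params, t=t_fit)
    if not result.success:
        raise KineticsError(f"one-phase decay fit failed: {result.message}")
    rate = float(result.params["rate"].value)
    if rate <= 0:
        raise KineticsError("fitted rate is non-positive; no decay detected")
    return DecayFit(
        span=float(result.params["span"].value),
        plateau=float(result.params["plateau"].value),
        rate=rate,
        half_life=math.log(2) / rate,
        t_start=t_chx,
        t_end=t_end,
    )


def efficiency_halflife_regression(
    efficiency_ratio: np.ndarray,
    half_life: np.ndarray,
    band_points: int = 100,
) -> RegressionFit:
    """OLS of PER2 half-life (hr) on the FASP/Degron efficiency ratio.

    Returns the slope with its t-distribution 95% CI, R², the slope's
    p-value, and a 95% confidence band for the mean response, evaluated on
    a uniform grid over the observed ratio range (for plotting).
    """
    x = np.asarray(efficiency_ratio, dtype=float)
    y = np.asarray(half_life, dtype=float)
    if len(x) != len(y):
        raise KineticsError("x and y lengths differ")
    if len(x) < 3:
        raise KineticsError(f"regression needs ≥ 3 mutants, got {len(x)}")
    exog = sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    ci = fit.conf_int(alpha=0.05)
    band_x = np.linspace(x.min(), x.max(), band_points)
    pred = fit.get_prediction(sm.add_constant(band_x))
    band = pred.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        band_x=band_x,
        band_lower=band[:, 0],
        band_upper=band[:, 1],
    )


def read_progress_curves(path) -> list[ProgressCurve]:
    """Read progress curves from CSV with columns time, signal, replicate, label."""
    df = pd.read_csv(path)
    required = {"time", "signal"}
    if not required.issubset(df.columns):
        raise KineticsError(f"CSV must have columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    if "label" not in df.columns:
        df["label"] = "other"
    curves = []
    for (rep, label), group in df.groupby(["replicate", "label"], sort=True):
        group = group.sort_values("time")
        curves.append(
            ProgressCurve(
                timepoints=group["time"].to_numpy(),
                signal=group["signal"].to_numpy(),
                replicate=rep,
                substrate=str(label),
            )
        )
    return curves
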