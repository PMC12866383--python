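"""Internal (MIRD-style) organ dosimetry from time-activity samples.

Pipeline: hybrid planar/SPECT rescaling of whole-body planar series ->
kinetic model fit of the organ's fraction of injected activity fia(t) ->
time-integrated activity coefficient (TIAC, hours) -> absorbed-dose
coefficient (Gy/GBq) via a per-organ dose factor -> projected cumulative
absorbed dose (Gy) for a planned cumulative administered activity, and the
activity cap implied by external-beam (EBRT) organ-toxicity thresholds.

Activity fractions are decay-uncorrected: the fitted effective rate
already contains physical decay, so the TIAC integral converges without an
explicit decay term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "LU177_HALF_LIFE_H",
    "DEFAULT_DOSE_FACTORS",
    "DEFAULT_EBRT_THRESHOLDS",
    "TimeActivitySample",
    "KineticFit",
    "OrganDoseResult",
    "EcaResult",
    "DosimetryConfig",
    "rescale_hybrid",
    "fit_kinetics",
    "compute_tiac",
    "absorbed_dose_coefficient",
    "projected_cad",
    "max_allowed_cumulative_activity",
    "summarize_dosimetry",
    "round_sig",
]

#: Physical half-life of Lu-177 in hours (6.647 d).
LU177_HALF_LIFE_H = 159.53

#: Effective self-dose factors, Gy per (GBq x h of time-integrated
#: activity coefficient).  Config-switchable; see docs/methods.md.
DEFAULT_DOSE_FACTORS: dict[str, float] = {
    "kidneys": 0.050,
    "pancreas": 0.100,
    "red_marrow": 0.0016,
    "total_body": 0.0005,
}

#: EBRT organ-toxicity thresholds (Gy) reused as activity caps.
DEFAULT_EBRT_THRESHOLDS: dict[str, float] = {
    "red_marrow": 2.0,
    "kidneys": 23.0,
    "pancreas": 40.0,
}


class UnanchoredSeriesError(ValueError):
    """No planar time point matches the SPECT anchor within the window."""


class DivergentIntegralError(ValueError):
    """Tail rate non-positive: the time-activity integral does not converge."""


@dataclass(frozen=True)
class TimeActivitySample:
    """One organ activity measurement: fraction of injected activity at t.

    ``fia`` is decay-uncorrected (what the camera sees, scaled to the
    injected activity).  ``modality`` distinguishes planar whole-body
    views from quantitative SPECT/CT anchors.
    """

    organ: str
    t: float  # hours post-injection
    fia: float  # fraction of injected activity, dimensionless
    modality: str = "planar"  # planar | spect

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got {self.t}")
        if not (0.0 <= self.fia <= 1.0):
            raise ValueError(f"fia must lie in [0, 1], got {self.fia}")
        if self.modality not in ("planar", "spect"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class KineticFit:
    """Fitted decay model of an organ time-activity curve.

    model 'monoexp': fia(t) = A0 exp(-k t) with amplitudes=[A0], rates=[k].
    model 'biexp':   sum of two such terms (uptake-washout when one
    amplitude is negative is rejected; both amplitudes kept >= 0).
    model 'trapezoid_tail': no parametric form; the observed points are
    kept and integrated numerically with a monoexponential tail at the
    terminal rate rates=[k_tail].
    """

    model: str
    amplitudes: list[float]
    rates: list[float]
    rss: float = 0.0
    samples: Optional[list[TimeActivitySample]] = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("all rate constants must be strictly positive")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "trapezoid_tail":
            raise ValueError("trapezoid_tail carries no parametric curve")
        out = np.zeros_like(t)
        for a, k in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-k * t)
        return out


@dataclass(frozen=True)
class DosimetryConfig:
    """Constants and choices for the dosimetry pipeline."""

    physical_half_life_h: float = LU177_HALF_LIFE_H
    dose_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_FACTORS)
    )
    ebrt_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EBRT_THRESHOLDS)
    )
    default_model: str = "monoexp"
    anchor_window_h: float = 3.0  # planar/SPECT time-matching window

    def __post_init__(self) -> None:
        if self.physical_half_life_h <= 0:
            raise ValueError("physical half-life must be positive")
        if any(v < 0 for v in self.dose_factors.values()):
            raise ValueError("dose factors must be non-negative")

    @property
    def lambda_phys(self) -> float:
        return math.log(2.0) / self.physical_half_life_h


@dataclass(frozen=True)
class OrganDoseResult:
    """Per-organ dosimetry output for one patient and dose level."""

    organ: str
    tiac_h: float
    adc_gy_per_gbq: float
    projected_cad_gy: float


@dataclass(frozen=True)
class EcaResult:
    """Maximum allowed cumulative administered activity from EBRT caps."""

    thresholds_gy: dict[str, float]
    max_activity_gbq: dict[str, float]
    limiting_organ: Optional[str]
    overall_max_activity_gbq: float


def rescale_hybrid(
    planar_series: Sequence[TimeActivitySample],
    spect_anchor: TimeActivitySample,
    window_h: float = 3.0,
) -> list[TimeActivitySample]:
    """Anchor a planar series to a quantitative SPECT measurement.

    Finds the planar sample closest in time to the anchor (within
    ``window_h``) and multiplies the whole series by
    anchor.fia / planar.fia at that time, preserving the shape of the
    kinetics while fixing its absolute scale.
    """
    if not planar_series:
        raise UnanchoredSeriesError("empty planar series")
    deltas = [abs(s.t - spect_anchor.t) for s in planar_series]
    i = int(np.argmin(deltas))
    if deltas[i] > window_h:
        raise UnanchoredSeriesError(
            f"no planar sample within {window_h} h of anchor at t={spect_anchor.t} h"
        )
    ref = planar_series[i]
    if ref.fia == 0:
        raise ZeroDivisionError(
            f"degenerate anchor: planar fia is zero at t={ref.t} h"
        )
    scale = spect_anchor.fia / ref.fia
    return [
        TimeActivitySample(s.organ, s.t, min(1.0, s.fia * scale), s.modality)
        for s in planar_series
    ]


def _monoexp_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares monoexponential fit, log-linear init then refinement."""
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        a0, k0 = math.exp(intercept), max(-slope, 1e-6)
    else:
        a0, k0 = max(float(y.max()), 1e-9), 1e-2
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, k: a * np.exp(-k * tt),
            t,
            y,
            p0=[a0, k0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
        a, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, k = a0, k0
    rss = float(np.sum((y - a * np.exp(-k * t)) ** 2))
    return a, k, rss


def _biexp_fit(t: np.ndarray, y: np.ndarray) -> tuple[list[float], list[float], float]:
    a0, k0, _ = _monoexp_fit(t, y)
    p0 = [0.7 * a0, max(k0, 2e-3), 0.3 * a0, 5 * max(k0, 2e-3)]

    def f(tt, a1, k1, a2, k2):
        return a1 * np.exp(-k1 * tt) + a2 * np.exp(-k2 * tt)

    popt, _ = optimize.curve_fit(
        f, t, y, p0=p0, bounds=([0, 1e-9, 0, 1e-9], [np.inf] * 4), maxfev=20000
    )
    rss = float(np.sum((y - f(t, *popt)) ** 2))
    return [float(popt[0]), float(popt[2])], [float(popt[1]), float(popt[3])], rss


def fit_kinetics(
    samples: Sequence[TimeActivitySample],
    model: str = "monoexp",
    config: Optional[DosimetryConfig] = None,
) -> KineticFit:
    """Fit a decay model to an organ time-activity series.

    Insufficient points trigger a model downgrade (biexp -> monoexp ->
    trapezoid_tail) with a logged warning rather than an error.  For
    ``trapezoid_tail`` the terminal rate is estimated from the last two
    samples; when that slope is non-positive the physical decay rate is
    used (activity cannot outlive the radionuclide).
    """
    config = config or DosimetryConfig()
    samples = sorted(samples, key=lambda s: s.t)
    times = [s.t for s in samples]
    if len(set(times)) != len(times):
        raise ValueError("sample times must be strictly increasing")
    t = np.array(times, dtype=float)
    y = np.array([s.fia for s in samples], dtype=float)

    if model == "biexp" and len(samples) < 4:
        logger.warning("biexp needs >= 4 points, have %d: downgrading to monoexp", len(samples))
        model = "monoexp"
    if model == "monoexp" and len(samples) < 2:
        logger.warning("monoexp needs >= 2 points, have %d: downgrading to trapezoid_tail", len(samples))
        model = "trapezoid_tail"

    if model == "monoexp":
        a, k, rss = _monoexp_fit(t, y)
        if not (math.isfinite(a) and math.isfinite(k)):
            raise RuntimeError("monoexponential fit did not converge")
        return KineticFit("monoexp", [a], [k], rss, list(samples))
    if model == "biexp":
        amps, rates, rss = _biexp_fit(t, y)
        if not all(map(math.isfinite, amps + rates)):
            raise RuntimeError("biexponential fit did not converge")
        return KineticFit("biexp", amps, rates, rss, list(samples))
    if model == "trapezoid_tail":
        if len(samples) >= 2 and y[-1] > 0 and y[-2] > 0 and y[-2] > y[-1]:
            k_tail = math.log(y[-2] / y[-1]) / (t[-1] - t[-2])
        else:
            k_tail = config.lambda_phys
        return KineticFit("trapezoid_tail", [], [k_tail], 0.0, list(samples))
    raise ValueError(f"unknown model {model!r}")


def compute_tiac(
    fit_or_samples: Union[KineticFit, Sequence[TimeActivitySample]],
    config: Optional[DosimetryConfig] = None,
) -> float:
    """Time-integrated activity coefficient in hours.

    Analytic integral sum(A_i / k_i) for exponential fits; trapezoid over
    the observed points plus a monoexponential tail (last value / tail
    rate) for the non-parametric route.
    """
    config = config or DosimetryConfig()
    if not isinstance(fit_or_samples, KineticFit):
        fit_or_samples = fit_kinetics(fit_or_samples, "trapezoid_tail", config)
    fit = fit_or_samples
    if fit.model in ("monoexp", "biexp"):
        return float(sum(a / k for a, k in zip(fit.amplitudes, fit.rates)))
    # trapezoid + tail
    if fit.samples is None or not fit.samples:
        return 0.0
    t = np.array([s.t for s in fit.samples], dtype=float)
    y = np.array([s.fia for s in fit.samples], dtype=float)
    k_tail = fit.rates[0]
    if k_tail <= 0:
        raise DivergentIntegralError("tail rate must be positive")
    body = float(np.trapezoid(y, t)) if len(t) > 1 else 0.0
    tail = float(y[-1] / k_tail)
    return body + tail


def absorbed_dose_coefficient(tiac_h: float, dose_factor: float) -> float:
    """Absorbed dose per unit administered activity, Gy/GBq.

    Product of the time-integrated activity coefficient (hours) and the
    organ dose factor (Gy per GBq x h).
    """
    if tiac_h < 0 or dose_factor < 0:
        raise ValueError("tiac and dose factor must be non-negative")
    return tiac_h * dose_factor


def projected_cad(adc_gy_per_gbq: float, planned_cumulative_activity_gbq: float) -> float:
    """Projected cumulative absorbed dose (Gy).

    Absorbed dose coefficient (Gy/GBq) x planned cumulative administered
    activity (GBq) over the planned cycles.
    """
    if adc_gy_per_gbq < 0 or planned_cumulative_activity_gbq < 0:
        raise ValueError("inputs must be non-negative")
    return adc_gy_per_gbq * planned_cumulative_activity_gbq


def max_allowed_cumulative_activity(
    adcs: Mapping[str, float],
    thresholds: Optional[Mapping[str, float]] = None,
) -> EcaResult:
    """Activity cap per organ: EBRT threshold (Gy) / dose coefficient.

    Only organs with a configured threshold gate escalation; the overall
    cap is the minimum across gated organs and the limiting organ is
    recorded.  A zero coefficient leaves that organ unbounded.
    """
    if not adcs:
        raise ValueError("need at least one organ dose coefficient")
    thresholds = dict(thresholds) if thresholds is not None else dict(DEFAULT_EBRT_THRESHOLDS)
    caps: dict[str, float] = {}
    used_thresholds: dict[str, float] = {}
    for organ, adc in adcs.items():
        if organ not in thresholds:
            continue  # organs without thresholds do not gate
        used_thresholds[organ] = thresholds[organ]
        caps[organ] = math.inf if adc == 0 else thresholds[organ] / adc
    if not caps:
        raise KeyError(
            f"no threshold configured for any supplied organ: {sorted(adcs)}"
        )
    limiting = min(caps, key=caps.get)
    overall = caps[limiting]
    if math.isinf(overall):
        limiting = None
    return EcaResult(used_thresholds, caps, limiting, overall)


def summarize_dosimetry(results: Iterable[dict]) -> pd.DataFrame:
    """Mean/SD tables of dose coefficients and projected CADs.

    ``results`` rows need keys: patient_id, dl, organ, adc, and optionally
    projected_cad.  Returns per-DL and pooled ('all') rows; the pooled
    mean is the mean of the concatenated values, not the mean of per-DL
    means.  SD is the sample SD and is absent (NaN) for n = 1.
    """
    df = pd.DataFrame(list(results))
    if df.empty:
        logger.warning("no evaluable dosimetry results")
        return pd.DataFrame(
            columns=["dl", "organ", "n", "adc_mean", "adc_sd"]
        )
    n_bad = df["adc"].isna().sum()
    if n_bad:
        logger.warning("excluding %d results without evaluable measurement", n_bad)
        df = df.dropna(subset=["adc"])
    value_cols = [c for c in ("adc", "projected_cad") if c in df.columns]

    def agg(g: pd.DataFrame) -> pd.Series:
        out = {"n": len(g)}
        for c in value_cols:
            out[f"{c}_mean"] = g[c].mean()
            out[f"{c}_sd"] = g[c].std(ddof=1) if len(g) > 1 else float("nan")
        return pd.Series(out)

    per_dl = (
        df.groupby(["dl", "organ"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    pooled = df.groupby("organ", sort=True).apply(agg, include_groups=False).reset_index()
    pooled.insert(0, "dl", "all")
    table = pd.concat([per_dl, pooled], ignore_index=True)
    table["n"] = table["n"].astype(int)
    return table


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    from decimal import Decimal, ROUND_HALF_UP

    exponent = math.floor(math.log10(abs(x)))
    quant = Decimal(1).scaleb(exponent - sig + 1)
    return float(Decimal(repr(x)).quantize(quant, rounding=ROUND_HALF_UP))
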