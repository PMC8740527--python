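"""DOC* formation, rate fitting, resolvability gates and growth efficiency.

The measured bulk organic carbon in an incubation contains the growing
bacterioplankton themselves; subtracting biomass carbon gives DOC*, the
dissolved pool actually being consumed.  Bacterial production (BP) is the
model-I (OLS) slope of biomass vs. time from T0 to the onset of stationary
phase; the DOC* removal rate is the positive magnitude of the OLS slope of
DOC* vs. time over the same window.  Growth efficiency is their quotient,

    BGE = BP / DOC* removal rate,

reported only when the drawdown exceeds twice the analytical precision of
the carbon analyzer (2 × 0.7 = 1.4 µmol C L⁻¹) and both regressions are
significant (two-tailed p < 0.05).  Uncertainty is propagated from the two
slope standard errors in relative terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    ImplausibleBiomassError,
    InsufficientDataError,
    NoGrowthError,
    UndefinedBGEError,
)


@dataclass(frozen=True)
class DetectionGates:
    """Resolvability thresholds for reporting a growth efficiency.

    ``min_delta_doc`` defaults to twice the analyzer precision.
    """

    instrument_precision: float = 0.7  # µmol C L⁻¹
    min_delta_doc: float = field(default=None)  # type: ignore[assignment]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_delta_doc is None:
            object.__setattr__(self, "min_delta_doc", 2.0 * self.instrument_precision)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RateFit:
    """OLS fit of a concentration series against time."""

    slope: float  # µmol C L⁻¹ d⁻¹ (signed)
    slope_se: float
    intercept: float
    n: int
    p_two_tailed: float
    window: str = "short_term"

    @property
    def magnitude(self) -> float:
        """Absolute rate, the convention for reporting removal rates."""
        return abs(self.slope)


@dataclass(frozen=True)
class GateResult:
    delta_doc_ok: bool
    p_bp_ok: bool
    p_doc_ok: bool

    @property
    def overall(self) -> bool:
        return self.delta_doc_ok and self.p_bp_ok and self.p_doc_ok


@dataclass(frozen=True)
class BGEResult:
    bge: float | None
    bge_error: float | None
    gates: GateResult
    conversion_name: str = "EXPORTS"


def doc_star(oc, bb):
    """DOC* (µmol C L⁻¹): measured organic carbon minus biomass carbon."""
    oc = np.asarray(oc, dtype=float)
    bb = np.asarray(bb, dtype=float)
    if np.any(oc <= 0):
        raise ImplausibleBiomassError("organic carbon must be positive")
    if np.any(bb < 0):
        raise ImplausibleBiomassError("biomass must be >= 0")
    if np.any(bb >= oc):
        raise ImplausibleBiomassError(
            "biomass carbon >= bulk organic carbon; check units/inputs"
        )
    out = oc - bb
    return float(out) if out.ndim == 0 else out


def _trailing_growth_p(times: np.ndarray, ln_abund: np.ndarray) -> float:
    """One-sided p that the OLS slope of ln(abundance) is positive."""
    fit = stats.linregress(times, ln_abund)
    if not fit.slope > 0:
        return 1.0
    if fit.stderr == 0:  # exact positive line
        return 0.0
    return float(fit.pvalue) / 2.0


def _sse(x: np.ndarray, y: np.ndarray, allow_positive_slope: bool = True) -> float:
    """Residual sum of squares of an OLS line (optionally slope-clipped <= 0)."""
    if len(x) < 2 or np.ptp(x) == 0:
        return float(np.sum((y - y.mean()) ** 2))
    fit = stats.linregress(x, y)
    slope = fit.slope if (allow_positive_slope or fit.slope <= 0) else 0.0
    intercept = fit.intercept if slope == fit.slope else y.mean()
    return float(np.sum((y - (intercept + slope * x)) ** 2))


def detect_stationary(
    times,
    abundance,
    alpha: float = 0.05,
    min_points: int = 3,
) -> float | None:
    """Time at which net growth stalls (onset of stationary phase).

    Stationary phase is the period demonstrating no cell growth with time,
    so the series is modelled as ln(abundance) rising linearly up to a
    breakpoint and flat (or declining — the death phase) afterwards.  The
    breakpoint among the observed times minimizing a BIC over both model
    pieces is chosen; the growth segment must then have a significantly
    positive slope (one-sided p < ``alpha``), otherwise
    :class:`NoGrowthError` is raised.  When a single growth line fits the
    whole series better than any breakpoint, the incubation is still
    growing and ``None`` is returned.
    """
    times = np.asarray(times, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if len(times) < 5:
        raise InsufficientDataError("need >= 5 time points to find stationary phase")
    if np.any(abundance <= 0):
        raise NoGrowthError("non-positive abundances")
    ln_a = np.log(abundance)
    n = len(times)

    def bic(sse: float, k: int) -> float:
        return n * np.log(max(sse, 1e-12) / n) + k * np.log(n)

    best_t, best_bic = None, bic(_sse(times, ln_a), k=2)  # growth-only model
    for i in range(min_points - 1, n - 1):
        pre = slice(0, i + 1)
        post = slice(i, n)  # breakpoint shared between both pieces
        sse = _sse(times[pre], ln_a[pre]) + _sse(
            times[post], ln_a[post], allow_positive_slope=False
        )
        b = bic(sse, k=4)
        if b < best_bic:
            best_t, best_bic = float(times[i]), b
    if best_t is None:
        # still growing, if it is growth at all
        if _trailing_growth_p(times, ln_a) < alpha:
            return None
        raise NoGrowthError("no significant net growth in the series")
    pre_sel = times <= best_t
    if _trailing_growth_p(times[pre_sel], ln_a[pre_sel]) >= alpha:
        raise NoGrowthError("no significant net growth before the breakpoint")
    return best_t


def fit_rate(times, values, window: str = "short_term") -> RateFit:
    """Model-I (OLS) regression of a concentration series on time."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise InsufficientDataError("rate fits require >= 3 points")
    if np.ptp(times) == 0:
        raise DegenerateDesignError("zero time variance")
    fit = stats.linregress(times, values)
    return RateFit(
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        n=len(times),
        p_two_tailed=float(fit.pvalue),
        window=window,
    )


def resolvable(
    delta_doc: float,
    p_bp: float,
    p_doc: float,
    gates: DetectionGates | None = None,
) -> GateResult:
    """Apply the drawdown and significance gates for reporting a BGE."""
    if gates is None:
        gates = DetectionGates()
    return GateResult(
        delta_doc_ok=bool(delta_doc > gates.min_delta_doc),
        p_bp_ok=bool(p_bp < gates.alpha),
        p_doc_ok=bool(p_doc < gates.alpha),
    )


def bge(bp_rate: float, doc_removal_rate: float) -> float:
    """Growth efficiency: production rate over DOC* removal rate."""
    if bp_rate <= 0 or doc_removal_rate <= 0:
        raise UndefinedBGEError("BGE requires positive BP and removal rates")
    return bp_rate / doc_removal_rate


def bge_error(
    bge_value: float,
    doc_rate: float,
    doc_rate_se: float,
    bp: float,
    bp_se: float,
    mode: str = "standard",
) -> float:
    """Propagated uncertainty on a growth efficiency.

    ``mode="standard"`` applies relative-error propagation for a quotient,
    BGE·√[(se_rate/rate)² + (se_BP/BP)²], which reproduces tabled
    uncertainties.  ``mode="literal"`` evaluates the published formula with
    the ratios inverted (rate/se instead of se/rate); it is retained to
    document that the printed form cannot yield the tabled values.
    """
    if doc_rate <= 0 or bp <= 0:
        raise UndefinedBGEError("rates must be positive")
    if doc_rate_se < 0 or bp_se < 0:
        raise ValueError("standard errors must be >= 0")
    if mode == "standard":
        rel = (doc_rate_se / doc_rate) ** 2 + (bp_se / bp) ** 2
    elif mode in ("literal", "literal_eq4"):
        if doc_rate_se == 0 or bp_se == 0:
            raise UndefinedBGEError("literal mode divides by the standard errors")
        rel = (doc_rate / doc_rate_se) ** 2 + (bp / bp_se) ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return math.sqrt(rel) * bge_value


def analyze_experiment(
    times_bb,
    bb,
    times_doc,
    doc,
    t_stationary: float | None = None,
    t_final: float | None = None,
    gates: DetectionGates | None = None,
    conversion_name: str = "EXPORTS",
) -> dict:
    """Short- and long-term rates plus gated BGE for one incubation.

    ``times_doc``/``doc`` may contain replicate observations (repeated
    times); replicates enter the regression as independent points.  If
    ``t_stationary`` is not given it is detected from the biomass series.
    Returns a dict with the two DOC* fits, the BP fit, the observed T0→
    stationary drawdown (difference of time-point means), gate results and
    the BGE with its propagated error (None when gated out).
    """
    times_bb = np.asarray(times_bb, dtype=float)
    bb = np.asarray(bb, dtype=float)
    times_doc = np.asarray(times_doc, dtype=float)
    doc = np.asarray(doc, dtype=float)
    if gates is None:
        gates = DetectionGates()
    if t_stationary is None:
        t_stationary = detect_stationary(times_bb, bb, alpha=gates.alpha)
        if t_stationary is None:
            raise NoGrowthError("series never reached stationary phase")

    short_bb = times_bb <= t_stationary
    bp_fit = fit_rate(times_bb[short_bb], bb[short_bb], window="short_term")

    short_doc = times_doc <= t_stationary
    doc_fit = fit_rate(times_doc[short_doc], doc[short_doc], window="short_term")

    long_fit = None
    long_sel = times_doc >= t_stationary
    if t_final is not None and np.sum(long_sel) >= 3 and np.ptp(times_doc[long_sel]) > 0:
        long_fit = fit_rate(times_doc[long_sel], doc[long_sel], window="long_term")

    t0 = times_doc.min()
    t_near_stat = times_doc[short_doc].max()
    delta_doc = float(
        doc[times_doc == t0].mean() - doc[times_doc == t_near_stat].mean()
    )

    gate = resolvable(delta_doc, bp_fit.p_two_tailed, doc_fit.p_two_tailed, gates)
    bge_val = err = None
    if gate.overall and bp_fit.slope > 0 and doc_fit.slope < 0:
        bge_val = bge(bp_fit.slope, doc_fit.magnitude)
        err = bge_error(
            bge_val, doc_fit.magnitude, doc_fit.slope_se, bp_fit.slope, bp_fit.slope_se
        )
    return {
        "t_stationary": float(t_stationary),
        "bp_fit": bp_fit,
        "doc_fit_short": doc_fit,
        "doc_fit_long": long_fit,
        "delta_doc": delta_doc,
        "gates": gate,
        "bge": BGEResult(bge_val, err, gate, conversion_name),
    }


# strata for the experiment summary: name -> (depth filter, treatment filter)
_STRATA: dict[str, tuple[str | None, str | None]] = {
    "all": (None, None),
    "surface": ("surface", None),
    "subsurface": ("subsurface", None),
    "diluted": (None, "diluted"),
    "undiluted": (None, "undiluted"),
    "surface_diluted": ("surface", "diluted"),
    "surface_undiluted": ("surface", "undiluted"),
    "subsurface_diluted": ("subsurface", "diluted"),
    "subsurface_undiluted": ("subsurface", "undiluted"),
}

SURFACE_MAX_DEPTH_M = 5.0


def summarize_experiments(
    results: pd.DataFrame,
    alpha: float = 0.05,
    quantities: dict[str, tuple[str, str | None]] | None = None,
) -> pd.DataFrame:
    """Mean ± sample SD of rates and efficiencies by depth/treatment stratum.

    ``results`` holds one row per experiment with at least ``depth_m`` and
    ``treatment`` plus the quantity columns.  By default summarizes
    ``short_rate`` (restricted to rows with ``short_p`` < alpha, the
    significance convention for removal rates), ``long_rate`` (``long_p`` <
    alpha), ``bp`` (all rows) and ``bge`` (rows where one was reported).
    Returns a tidy frame with columns quantity, stratum, mean, sd, n; the SD
    is NaN for singleton strata and empty strata are omitted.
    """
    if results.empty:
        return pd.DataFrame(columns=["quantity", "stratum", "mean", "sd", "n"])
    if quantities is None:
        quantities = {
            "short_rate": ("short_rate", "short_p"),
            "long_rate": ("long_rate", "long_p"),
            "bp": ("bp", None),
            "bge": ("bge", None),
        }
    rows = []
    is_surface = results["depth_m"] <= SURFACE_MAX_DEPTH_M
    for qname, (col, pcol) in quantities.items():
        if col not in results.columns:
            continue
        mask = results[col].notna()
        if pcol is not None and pcol in results.columns:
            mask &= results[pcol] < alpha
        for stratum, (depth_f, treat_f) in _STRATA.items():
            sel = mask.copy()
            if depth_f == "surface":
                sel &= is_surface
            elif depth_f == "subsurface":
                sel &= ~is_surface
            if treat_f is not None:
                sel &= results["treatment"] == treat_f
            vals = results.loc[sel, col].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "quantity": qname,
                    "stratum": stratum,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def summary_value(
    summary: pd.DataFrame, quantity: str, stratum: str, stat: str = "mean"
) -> float:
    """Convenience lookup into a :func:`summarize_experiments` frame."""
    sel = summary[(summary["quantity"] == quantity) & (summary["stratum"] == stratum)]
    if sel.empty:
        raise KeyError(f"no summary row for {quantity!r}/{stratum!r}")
    return float(sel.iloc[0][stat])
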