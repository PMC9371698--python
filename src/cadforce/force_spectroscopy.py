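"""AFM force-curve analysis: WLC tether fitting and event filtering.

A single-molecule unbinding measurement retracts a cantilever from a
surface at constant velocity; a specific receptor–ligand unbinding event
appears as a nonlinear polymer-tether stretch terminated by an abrupt force
drop.  This module detects such events, fits the stretch region to a
worm-like-chain (WLC) model with a bounded persistence length, reads out the
rupture force, and applies the acceptance filters used in single-molecule
practice: an RMS-error outlier rule (reject fits with rmse above the mean
plus one SD of all fit rmses in the condition) and a minimum tether contour
length (30 nm, the full PEG-tether length).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator

from .constants import DEFAULT_TEMPERATURE_K, KJ_PER_MOL_NM_TO_PN, kbt

__all__ = [
    "ForceCurve",
    "WLCFit",
    "UnbindingEvent",
    "RejectionReason",
    "wlc_force",
    "wlc_extension_at_force",
    "tip_sample_separation",
    "detect_events",
    "fit_wlc",
    "rupture_force",
    "filter_events",
    "thermal_spring_constant",
    "molar_force_to_piconewton",
    "CurveEventExtractor",
]

#: Default bounds on the WLC persistence length (nm) during fitting.
LP_BOUNDS: tuple[float, float] = (0.1, 1.0)

#: Default minimum accepted contour length (nm): full-length PEG tether.
LC_MIN_NM: float = 30.0


@dataclass
class ForceCurve:
    """One AFM approach/retract cycle.

    ``piezo_position`` is in nm, ``force`` in pN; ``segment_labels`` holds
    ``"approach"`` or ``"retract"`` per sample.
    """

    piezo_position: np.ndarray
    force: np.ndarray
    segment_labels: np.ndarray
    spring_constant: float  # pN/nm
    velocity: float = 1.0  # µm/s
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.piezo_position = np.asarray(self.piezo_position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype="U8")
        n = len(self.piezo_position)
        if n < 2:
            raise ValueError("curve must have at least 2 samples")
        if len(self.force) != n or len(self.segment_labels) != n:
            raise ValueError("curve arrays must have equal length")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if not (
            np.all(np.isfinite(self.piezo_position))
            and np.all(np.isfinite(self.force))
        ):
            raise ValueError("curve values must be finite")

    def segment(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.segment_labels == label)
        return idx


class RejectionReason(str, enum.Enum):
    NONE = "none"
    RMSE_OUTLIER = "rmse_outlier"
    SHORT_CONTOUR = "short_contour"
    FIT_FAILURE = "fit_failure"


@dataclass
class WLCFit:
    """A bounded WLC least-squares fit over a retract window."""

    Lp: float  # nm
    Lc: float  # nm
    rmse: float  # pN
    window: tuple[int, int]  # [start, end] inclusive indices into the curve
    converged: bool = True


@dataclass
class UnbindingEvent:
    rupture_force: float  # pN
    rupture_extension: float  # nm
    fit: WLCFit
    accepted: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        # invariant: accepted iff no rejection reason recorded
        self.accepted = self.rejection_reason == RejectionReason.NONE


def wlc_force(
    extension: float | np.ndarray,
    Lp: float,
    Lc: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float | np.ndarray:
    """Marko–Siggia interpolation force (pN) of a worm-like chain.

    F(x) = (kB·T / Lp) · [ 1/4·(1 − x/Lc)⁻² − 1/4 + x/Lc ]

    Parameters are the persistence length ``Lp`` and contour length ``Lc``
    (both nm).  The force is zero at zero extension, strictly increasing,
    and diverges as x → Lc.
    """
    if Lp <= 0 or Lc <= 0:
        raise ValueError("Lp and Lc must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= Lc):
        raise ValueError(f"extension must lie in [0, Lc={Lc}) nm")
    rel = x / Lc
    out = kbt(temperature) / Lp * (0.25 / (1.0 - rel) ** 2 - 0.25 + rel)
    return float(out) if np.isscalar(extension) else out


def wlc_extension_at_force(
    force: float, Lp: float, Lc: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Extension (nm) at which the WLC force equals ``force`` (pN)."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    hi = Lc * (1 - 1e-12)
    return brentq(
        lambda x: wlc_force(x, Lp, Lc, temperature) - force, 0.0, hi, xtol=1e-12
    )


def tip_sample_separation(curve: ForceCurve) -> np.ndarray:
    """Deflection-corrected tip–sample separation (nm).

    separation = piezo − force / spring_constant: a pulling force bends the
    cantilever toward the surface, so the tip lags the piezo.
    """
    return curve.piezo_position - curve.force / curve.spring_constant


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return force.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(force, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(force)]
    return out


def detect_events(
    curve: ForceCurve,
    drop_threshold: float = 20.0,
    smooth_window: int = 5,
) -> list[tuple[int, int]]:
    """Find candidate unbinding windows on the retract segment.

    A candidate is a maximal run of (smoothed) rising force ending in an
    abrupt force drop of at least ``drop_threshold`` pN.  The drop is
    assessed on the smoothed trace over a one-smoothing-window lookahead
    (an instantaneous raw drop spreads over ``smooth_window`` smoothed
    samples) and must be sustained: the smoothed force after the drop must
    stay ``drop_threshold`` below the pre-drop level, which separates
    ruptures (force returns to baseline) from noise excursions.  The drop
    must also clear six times the smoothed noise level estimated from the
    approach segment, so the effective threshold adapts to noisy curves.
    Returned windows are ``(start, end)`` index pairs into the curve
    arrays, ordered by extension; ``end`` is the last pre-drop sample,
    refined on the raw signal as the largest single-sample fall.
    """
    retract = curve.segment("retract")
    if len(retract) == 0:
        raise ValueError("curve has no retract segment")
    raw = curve.force[retract]
    f = _smooth(raw, smooth_window)
    n = len(f)
    # noise-adaptive threshold: the drop must also clear 6× the smoothed
    # noise level, estimated robustly from the approach segment
    approach = curve.segment("approach")
    if len(approach) >= 10:
        mad = np.median(np.abs(curve.force[approach] - np.median(curve.force[approach])))
        sigma = 1.4826 * mad / np.sqrt(smooth_window)
        threshold = max(drop_threshold, 6.0 * sigma)
    else:
        threshold = drop_threshold
    candidates: list[tuple[int, int]] = []
    lookahead = smooth_window + 2  # a 1-sample raw drop spans smooth_window
    i = 0
    while i < n - 1:
        ahead = f[i + 1 : i + 1 + lookahead]
        after = f[min(i + 2, n - 1) : i + 5 + lookahead]
        sustained = len(after) > 0 and after.mean() <= f[i] - threshold
        if len(ahead) and f[i] - ahead.min() >= threshold and sustained:
            # walk back through the rising stretch preceding the drop,
            # tolerating noise wiggles of up to a quarter of the threshold
            slack = 0.25 * threshold
            start = i
            while start > 0 and f[start - 1] <= f[start] + slack:
                start -= 1
            # refine the last pre-drop sample on the raw signal: the
            # rupture is the largest single-sample fall near the smoothed
            # drop position
            lo = max(start, i - smooth_window)
            hi = min(n - 2, i + lookahead + 2)
            end = lo + int(np.argmax(raw[lo : hi + 1] - raw[lo + 1 : hi + 2]))
            candidates.append((int(retract[start]), int(retract[end])))
            i += lookahead + smooth_window  # skip past the whole transition
        else:
            i += 1
    return candidates


def fit_wlc(
    separation: np.ndarray,
    force: np.ndarray,
    window: tuple[int, int],
    temperature: float = DEFAULT_TEMPERATURE_K,
    lp_bounds: tuple[float, float] = LP_BOUNDS,
) -> WLCFit:
    """Bounded least-squares WLC fit over a window of a retract curve.

    Lp is constrained to ``lp_bounds`` (default 0.1–1 nm) and Lc to exceed
    the largest extension in the window.  Deterministic multi-start from a
    fixed (Lp, Lc) grid; the rmse is the root-mean-square force residual in
    pN.  Non-convergence is reported via ``converged=False`` rather than an
    exception.
    """
    lo, hi = window
    x = np.asarray(separation[lo : hi + 1], dtype=float)
    y = np.asarray(force[lo : hi + 1], dtype=float)
    if len(x) < 5:
        raise ValueError(f"window must contain at least 5 samples, got {len(x)}")
    x_max = float(x.max())
    lc_lo = x_max * (1 + 1e-6)

    def residuals(params: np.ndarray) -> np.ndarray:
        lp, lc = params
        rel = np.clip(x / lc, 0.0, 1.0 - 1e-9)
        model = kbt(temperature) / lp * (0.25 / (1.0 - rel) ** 2 - 0.25 + rel)
        return model - y

    starts = [
        (lp0, lc_mult * x_max)
        for lp0 in (lp_bounds[0], 0.38, lp_bounds[1])
        for lc_mult in (1.05, 1.2, 1.5, 3.0)
    ]
    best = None
    for lp0, lc0 in starts:
        try:
            res = least_squares(
                residuals,
                x0=[np.clip(lp0, *lp_bounds), max(lc0, lc_lo * 1.01)],
                bounds=([lp_bounds[0], lc_lo], [lp_bounds[1], np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return WLCFit(Lp=np.nan, Lc=np.nan, rmse=np.inf, window=window, converged=False)
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return WLCFit(
        Lp=float(best.x[0]), Lc=float(best.x[1]), rmse=rmse, window=window
    )


def rupture_force(curve: ForceCurve, window: tuple[int, int]) -> float:
    """Rupture-force readout: last pre-drop sample, baseline-subtracted.

    The baseline is the median force of the approach segment (zero-force
    reference); if the curve has no approach segment the baseline is 0.
    """
    approach = curve.segment("approach")
    baseline = float(np.median(curve.force[approach])) if len(approach) else 0.0
    return float(curve.force[window[1]] - baseline)


def filter_events(
    events: list[UnbindingEvent],
    lc_min: float = LC_MIN_NM,
    rmse_sd_mult: float = 1.0,
    rule_order: tuple[str, ...] = ("rmse", "contour"),
) -> list[UnbindingEvent]:
    """Apply the specific-event acceptance filters, setting accept flags.

    Rules, in ``rule_order`` (first violated rule is recorded):

    * ``rmse``: reject events whose fit rmse exceeds the mean plus
      ``rmse_sd_mult``·SD of the rmses of all successfully fitted events in
      the input (the experimental condition).  Skipped when fewer than two
      fitted events exist (the SD is undefined).
    * ``contour``: reject fitted contour lengths below ``lc_min`` nm.

    Events whose fit never converged are marked ``fit_failure`` and are
    excluded from the rmse statistics.  The operation is idempotent on its
    accepted subset and independent of event order.
    """
    fitted = [e for e in events if e.fit.converged]
    rmses = np.array([e.fit.rmse for e in fitted])
    rmse_threshold = np.inf
    if len(rmses) >= 2:
        rmse_threshold = float(rmses.mean() + rmse_sd_mult * rmses.std(ddof=0))

    out: list[UnbindingEvent] = []
    for e in events:
        reason = RejectionReason.NONE
        if not e.fit.converged:
            reason = RejectionReason.FIT_FAILURE
        else:
            for rule in rule_order:
                if rule == "rmse" and e.fit.rmse > rmse_threshold:
                    reason = RejectionReason.RMSE_OUTLIER
                    break
                if rule == "contour" and e.fit.Lc < lc_min:
                    reason = RejectionReason.SHORT_CONTOUR
                    break
        out.append(
            UnbindingEvent(
                rupture_force=e.rupture_force,
                rupture_extension=e.rupture_extension,
                fit=e.fit,
                rejection_reason=reason,
            )
        )
    return out


def thermal_spring_constant(
    deflection: np.ndarray, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Cantilever spring constant (pN/nm) from thermal fluctuations.

    Equipartition: k = kB·T / Var(deflection), with deflection in nm.  The
    optical-lever geometric correction factor is not applied.
    """
    deflection = np.asarray(deflection, dtype=float)
    if len(deflection) < 100:
        raise ValueError("need at least 100 deflection samples")
    var = float(np.var(deflection, ddof=1))
    if var == 0:
        raise ValueError("deflection variance is zero")
    return kbt(temperature) / var


def molar_force_to_piconewton(value: float) -> float:
    """Convert a force from kJ·mol⁻¹·nm⁻¹ (MD convention) to pN.

    400 kJ·mol⁻¹·nm⁻¹ ≈ 664.2 pN.
    """
    if value < 0:
        raise ValueError("force magnitude must be non-negative")
    return value * KJ_PER_MOL_NM_TO_PN


class CurveEventExtractor(BaseEstimator):
    """Transformer mapping raw force curves to filtered unbinding events.

    Stateless in the scikit-learn sense: ``fit`` only validates parameters;
    ``transform`` runs detection → WLC fitting → rupture readout → the
    condition-level acceptance filters, and returns a pandas DataFrame with
    one row per detected event (columns ``rupture_force_pN``, ``Lc_nm``,
    ``Lp_nm``, ``rmse_pN``, ``accepted``, ``rejection_reason``, ``curve``).

    Parameters
    ----------
    drop_threshold : float, pN
        Minimum force drop marking a candidate rupture.
    smooth_window : int
        Moving-average width (samples) for event detection.
    lc_min : float, nm
        Minimum accepted contour length.
    rmse_sd_mult : float
        Multiplier on the rmse SD in the outlier rule (mean + mult·SD).
    temperature : float, K
    """

    def __init__(
        self,
        drop_threshold: float = 20.0,
        smooth_window: int = 5,
        lc_min: float = LC_MIN_NM,
        rmse_sd_mult: float = 1.0,
        temperature: float = DEFAULT_TEMPERATURE_K,
        rule_order: tuple[str, ...] = ("rmse", "contour"),
    ) -> None:
        self.drop_threshold = drop_threshold
        self.smooth_window = smooth_window
        self.lc_min = lc_min
        self.rmse_sd_mult = rmse_sd_mult
        self.temperature = temperature
        self.rule_order = rule_order

    def fit(self, X=None, y=None) -> "CurveEventExtractor":
        if self.drop_threshold <= 0:
            raise ValueError("drop_threshold must be positive")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        return self

    def extract_events(self, curves: list[ForceCurve]) -> tuple[list, list]:
        """Return (events, curve indices) before filtering."""
        self.fit()
        events: list[UnbindingEvent] = []
        origin: list[int] = []
        for ci, curve in enumerate(curves):
            sep = tip_sample_separation(curve)
            for window in detect_events(
                curve, self.drop_threshold, self.smooth_window
            ):
                if window[1] - window[0] + 1 < 5:
                    # too short to fit: noise-triggered candidate
                    fit = WLCFit(
                        Lp=np.nan,
                        Lc=np.nan,
                        rmse=np.inf,
                        window=window,
                        converged=False,
                    )
                else:
                    fit = fit_wlc(sep, curve.force, window, self.temperature)
                events.append(
                    UnbindingEvent(
                        rupture_force=rupture_force(curve, window),
                        rupture_extension=float(sep[window[1]]),
                        fit=fit,
                    )
                )
                origin.append(ci)
        return events, origin

    def transform(self, curves: list[ForceCurve]):
        import pandas as pd

        events, origin = self.extract_events(curves)
        events = filter_events(
            events,
            lc_min=self.lc_min,
            rmse_sd_mult=self.rmse_sd_mult,
            rule_order=self.rule_order,
        )
        self.n_curves_ = len(curves)
        self.n_candidates_ = len(events)
        self.n_accepted_ = sum(e.accepted for e in events)
        if not events:
            warnings.warn("no unbinding events detected", stacklevel=2)
        return pd.DataFrame(
            {
                "curve": origin,
                "rupture_force_pN": [e.rupture_force for e in events],
                "rupture_extension_nm": [e.rupture_extension for e in events],
                "Lc_nm": [e.fit.Lc for e in events],
                "Lp_nm": [e.fit.Lp for e in events],
                "rmse_pN": [e.fit.rmse for e in events],
                "accepted": [e.accepted for e in events],
                "rejection_reason": [e.rejection_reason.value for e in events],
            }
        )

    def fit_transform(self, curves: list[ForceCurve], y=None):
        return self.fit().transform(curves)
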