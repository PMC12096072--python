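"""Triplex dissociation-constant estimation from melting and gel titrations.

Two experimental routes measure the TFO--duplex dissociation constant:

* **Tm route** — fluorescent thermal denaturation of duplex + TFO
  mixtures.  The negative first derivative of fluorescence vs
  temperature shows a duplex dissociation peak near 50 C and, when a
  triplex forms, a second peak at lower temperature (39-44 C).  The
  triplex/duplex peak-height ratio rises with TFO concentration along a
  single-site binding isotherm; the concentration at the symmetry point
  of a logistic fit estimates Kd.
* **EMSA route** — electrophoretic duplex-band depletion: the duplex
  band intensity, normalised to the zero-TFO lane, falls with TFO
  concentration; Kd is the concentration at half-depletion.  Staining
  bias makes this route systematically underestimate Kd.

Concentrations are handled in nM internally; all Kd estimates are
reported in uM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from scipy.special import expit


class AffinityInputError(ValueError):
    pass


class NoStableTriplexError(RuntimeError):
    """The titration shows no resolvable triplex transition.

    Raised when no triplex-attributable response exists at any
    concentration (single-peak melts, flat titrations) or when the
    fitted transition amplitude is indistinguishable from noise.
    """


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltCurve:
    """One fluorescence-vs-temperature denaturation ramp."""

    tfo_concentration: float            # nM
    temperatures: np.ndarray            # C, strictly increasing
    fluorescence: np.ndarray            # a.u.

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        f = np.asarray(self.fluorescence, float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size < 20 or t.size != f.size:
            raise AffinityInputError("melt curve needs >=20 matched samples")
        if np.any(np.diff(t) <= 0):
            raise AffinityInputError("temperatures must be strictly increasing")
        if np.any(~np.isfinite(f)):
            raise AffinityInputError("fluorescence contains missing values")


@dataclass(frozen=True)
class DerivativeProfile:
    temperatures: np.ndarray
    neg_dF_dT: np.ndarray


@dataclass(frozen=True)
class PeakCall:
    tm: float                           # C
    height: float                       # a.u./C
    prominence: float
    role: str                           # "duplex" | "triplex" | "unassigned"


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration-response points for sigmoid fitting."""

    response_kind: str                  # "tm_peak_ratio" | "emsa_duplex_intensity"
    points: tuple[tuple[float, float, float], ...]  # (conc nM, response, replicate sd)

    def __post_init__(self) -> None:
        concs = [p[0] for p in self.points]
        if any(c < 0 for c in concs):
            raise AffinityInputError("concentrations must be non-negative")
        if 0.0 not in concs:
            raise AffinityInputError("series must include a zero-TFO reference point")
        if len(set(concs)) < 5:
            raise AffinityInputError("need >=5 distinct concentrations for fitting")


@dataclass(frozen=True)
class LogisticFit:
    bottom: float
    top: float
    log_ec50: float                     # log10(nM)
    hill: float
    covariance: np.ndarray | None


@dataclass(frozen=True)
class KdEstimate:
    kd: float                           # uM
    stderr: float                       # uM
    method: str                         # "tm" | "emsa"
    fit: LogisticFit

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise AffinityInputError("kd must be positive")


@dataclass(frozen=True)
class GelLane:
    lane_index: int
    tfo_concentration: float            # nM
    band_intensities: dict              # role -> a.u.; roles duplex/triplex/free_tfo

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.band_intensities.values()):
            raise AffinityInputError("band intensities must be >= 0")


# ---------------------------------------------------------------------------
# Derivative profile and peak calling
# ---------------------------------------------------------------------------

def smooth_and_derivative(
    curve: MeltCurve, window: int = 9, polyorder: int = 2
) -> DerivativeProfile:
    """Savitzky-Golay smoothing followed by a negated central-difference
    derivative; half a window is trimmed from each end to drop edge
    artefacts of the local polynomial fit.
    """
    if window % 2 == 0 or window >= curve.temperatures.size:
        raise AffinityInputError("window must be odd and smaller than the curve")
    if polyorder >= window:
        raise AffinityInputError("polyorder must be < window")
    smoothed = signal.savgol_filter(curve.fluorescence, window, polyorder)
    deriv = -np.gradient(smoothed, curve.temperatures)
    half = window // 2
    return DerivativeProfile(
        temperatures=curve.temperatures[half:-half],
        neg_dF_dT=deriv[half:-half],
    )


def detect_peaks(
    profile: DerivativeProfile, min_prominence_frac: float = 0.05
) -> list[PeakCall]:
    """Call dissociation peaks in a -dF/dT profile.

    Local maxima with prominence >= ``min_prominence_frac`` x the global
    maximum are kept and sorted by Tm descending.  The hottest peak is
    the duplex transition; the most prominent remaining peak below it is
    the triplex; anything else is unassigned.  Profiles with a single
    peak indicate a sample incapable of forming a stable triplex.
    """
    y = np.asarray(profile.neg_dF_dT, float)
    if y.size == 0:
        raise AffinityInputError("empty profile")
    gmax = float(np.max(y))
    if gmax <= 0:
        return []
    thr = min_prominence_frac * gmax
    idx, props = signal.find_peaks(y, prominence=thr)
    if idx.size == 0:
        return []
    order = np.argsort(profile.temperatures[idx])[::-1]
    idx, prom = idx[order], props["prominences"][order]
    calls = [
        PeakCall(tm=float(profile.temperatures[i]), height=float(y[i]),
                 prominence=float(p), role="unassigned")
        for i, p in zip(idx, prom)
    ]
    calls[0] = PeakCall(calls[0].tm, calls[0].height, calls[0].prominence, "duplex")
    rest = calls[1:]
    if rest:
        j = int(np.argmax([c.prominence for c in rest]))
        rest[j] = PeakCall(rest[j].tm, rest[j].height, rest[j].prominence, "triplex")
    return [calls[0], *rest]


def peak_ratio(peaks: Sequence[PeakCall]) -> float | None:
    """Triplex/duplex derivative peak-height ratio; ``None`` when no
    triplex peak was called (recorded as response 0 in titrations)."""
    duplex = next((p for p in peaks if p.role == "duplex"), None)
    if duplex is None:
        raise AffinityInputError("no duplex peak present")
    if duplex.height == 0:
        raise AffinityInputError("duplex peak height is zero")
    triplex = next((p for p in peaks if p.role == "triplex"), None)
    return None if triplex is None else triplex.height / duplex.height


# ---------------------------------------------------------------------------
# Logistic titration fitting
# ---------------------------------------------------------------------------

def _logistic4(logc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) * expit(hill * math.log(10) * (logc - log_ec50))


def fit_titration(series: TitrationSeries) -> KdEstimate:
    """Fit a four-parameter logistic in log10(concentration).

    The zero-concentration point cannot sit on the log axis; it anchors
    the plateau the response starts from (bottom for a rising peak-ratio
    response, top for falling duplex-band depletion).  ``kd`` is
    10**log_ec50 converted to uM, its standard error propagated from the
    fit covariance.  A transition amplitude below 3x the residual sd is
    reported as :class:`NoStableTriplexError`.
    """
    pts = sorted(series.points)
    zero = [p for p in pts if p[0] == 0.0]
    nz = [(c, r, s) for c, r, s in pts if c > 0]
    anchor = float(np.mean([p[1] for p in zero]))
    conc = np.array([p[0] for p in nz])
    resp = np.array([p[1] for p in nz])
    if np.ptp(resp) == 0 and np.ptp([p[1] for p in pts]) == 0:
        raise NoStableTriplexError("flat titration: no concentration response")
    rising = series.response_kind != "emsa_duplex_intensity"
    logc = np.log10(conc)

    span = float(resp.max() - resp.min()) or 1.0
    mid0 = float(logc[np.argmin(np.abs(resp - (resp.min() + span / 2)))])
    if rising:
        def f(logc, top, log_ec50, hill):
            return _logistic4(logc, anchor, top, log_ec50, hill)
        p0 = [float(resp.max()), mid0, 1.0]
        lb = [anchor, logc.min() - 3, 0.05]
        ub = [anchor + 10 * span + 1e-9, logc.max() + 3, 10.0]
    else:
        def f(logc, bottom, log_ec50, hill):
            return _logistic4(logc, anchor, bottom, log_ec50, hill)
        p0 = [float(resp.min()), mid0, 1.0]
        lb = [anchor - 10 * span - 1e-9, logc.min() - 3, 0.05]
        ub = [anchor, logc.max() + 3, 10.0]
    p0 = np.clip(p0, lb, ub)
    try:
        popt, pcov = optimize.curve_fit(f, logc, resp, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(f"titration fit did not converge: {exc}",
                                  residuals=resp - f(logc, *p0)) from exc
    resid = resp - f(logc, *popt)
    sd = float(np.std(resid, ddof=min(len(resid) - 1, 3))) if len(resid) > 3 else float(np.std(resid))
    amplitude = abs(popt[0] - anchor)
    if amplitude < 3 * sd:
        raise NoStableTriplexError(
            f"transition amplitude {amplitude:.3g} < 3x residual sd {sd:.3g}"
        )
    log_ec50 = float(popt[1])
    kd_um = 10.0 ** log_ec50 / 1000.0
    var = float(pcov[1, 1]) if np.all(np.isfinite(pcov)) else float("nan")
    stderr = math.log(10) * kd_um * math.sqrt(var) if math.isfinite(var) else float("nan")
    if rising:
        fit = LogisticFit(bottom=anchor, top=float(popt[0]), log_ec50=log_ec50,
                          hill=float(popt[2]), covariance=pcov)
    else:
        fit = LogisticFit(bottom=float(popt[0]), top=anchor, log_ec50=log_ec50,
                          hill=-float(popt[2]), covariance=pcov)
    method = "tm" if series.response_kind == "tm_peak_ratio" else "emsa"
    return KdEstimate(kd=kd_um, stderr=stderr, method=method, fit=fit)


# ---------------------------------------------------------------------------
# End-to-end estimators
# ---------------------------------------------------------------------------

def _average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if c.temperatures.shape != t0.shape or not np.allclose(c.temperatures, t0):
            raise AffinityInputError("replicate curves must share a temperature grid")
    f = np.mean([c.fluorescence for c in curves], axis=0)
    return MeltCurve(curves[0].tfo_concentration, t0, f)


def estimate_kd_tm(
    curves: Sequence[MeltCurve],
    window: int = 9,
    polyorder: int = 2,
    min_prominence_frac: float = 0.05,
    duplex_tm_range: tuple[float, float] = (45.0, 60.0),
) -> KdEstimate:
    """Kd from a melt titration: replicate curves are averaged per
    concentration, peak ratios extracted, and the ratio-vs-concentration
    logistic fitted.  Concentrations where no triplex peak is called
    contribute a zero response.
    """
    by_conc: dict[float, list[MeltCurve]] = {}
    for c in curves:
        by_conc.setdefault(c.tfo_concentration, []).append(c)
    if len(by_conc) < 5:
        raise AffinityInputError("need >=5 TFO concentrations")
    points = []
    warnings: list[str] = []
    for conc, group in sorted(by_conc.items()):
        avg = _average_replicates(group)
        profile = smooth_and_derivative(avg, window, polyorder)
        peaks = detect_peaks(profile, min_prominence_frac)
        if not peaks:
            points.append((conc, 0.0, 0.0))
            continue
        duplex = peaks[0]
        if not duplex_tm_range[0] <= duplex.tm <= duplex_tm_range[1]:
            warnings.append(
                f"duplex Tm {duplex.tm:.1f} C outside {duplex_tm_range} at {conc} nM"
            )
        ratio = peak_ratio(peaks)
        points.append((conc, 0.0 if ratio is None else ratio, 0.0))
    series = TitrationSeries(response_kind="tm_peak_ratio", points=tuple(points))
    return fit_titration(series)


def estimate_kd_emsa(lanes: Sequence[GelLane]) -> KdEstimate:
    """Kd from duplex-band depletion, normalised to the zero-TFO lane."""
    zero = [l for l in lanes if l.tfo_concentration == 0.0]
    if not zero:
        raise AffinityInputError("lanes must include a zero-TFO reference")
    ref = float(np.mean([l.band_intensities["duplex"] for l in zero]))
    if ref == 0:
        raise AffinityInputError("zero-TFO duplex intensity is zero")
    points = [
        (l.tfo_concentration, l.band_intensities["duplex"] / ref, 0.0) for l in lanes
    ]
    series = TitrationSeries(response_kind="emsa_duplex_intensity", points=tuple(points))
    return fit_titration(series)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Long-format CSV: curve_id, tfo_conc_nM, temperature_C, fluorescence."""
    import pandas as pd

    df = pd.read_csv(path)
    curves = []
    for (_, conc), grp in df.groupby(["curve_id", "tfo_conc_nM"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(MeltCurve(float(conc), grp["temperature_C"].to_numpy(),
                                grp["fluorescence"].to_numpy()))
    return curves


def read_gel_tsv(path: str | Path) -> list[GelLane]:
    """TSV columns: lane, tfo_conc_nM, duplex, triplex, free_tfo."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        GelLane(int(r.lane), float(r.tfo_conc_nM),
                {"duplex": float(r.duplex), "triplex": float(r.triplex),
                 "free_tfo": float(r.free_tfo)})
        for r in df.itertuples()
    ]


def kd_report(estimate: KdEstimate) -> dict:
    """JSON-serialisable fit report."""
    cov = estimate.fit.covariance
    return {
        "kd_uM": estimate.kd,
        "stderr_uM": estimate.stderr,
        "method": estimate.method,
        "fit": {
            "bottom": estimate.fit.bottom,
            "top": estimate.fit.top,
            "log_ec50": estimate.fit.log_ec50,
            "hill": estimate.fit.hill,
            "covariance": None if cov is None else np.asarray(cov).tolist(),
        },
    }


def write_kd_json(estimate: KdEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(kd_report(estimate), indent=2) + "\n")
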