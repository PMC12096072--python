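"""Transcription / TX-TL rate fitting and modulation statistics.

Reporter fluorescence (Broccoli--DFHBI-1T for transcription-only runs,
sfGFP for coupled transcription-translation) grows linearly once the
reaction reaches steady state.  Rates are ordinary least-squares slopes
over a mode-specific time window: 120 min starting 1 h after reaction
start for transcription, shifted a further hour later for TX-TL to skip
the ribosomal accumulation lag.  Modulation is the percent change of the
mean replicate rate versus a no-TFO reference, with a two-sample t-test
and the usual significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class KineticsInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTrace:
    sample_id: str
    condition: str                      # "no_tfo_reference" | "purine_tfo" | "pyrimidine_tfo"
    replicate: int
    times: np.ndarray                   # minutes, strictly increasing
    fluorescence: np.ndarray            # a.u.

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        f = np.asarray(self.fluorescence, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)
        if t.size != f.size or t.size < 2:
            raise KineticsInputError("trace needs >=2 matched samples")
        if np.any(np.diff(t) <= 0):
            raise KineticsInputError("times must be strictly increasing")


@dataclass(frozen=True)
class FitWindow:
    start: float                        # minutes
    end: float
    mode: str                           # "transcription" | "txtl"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise KineticsInputError("window end must exceed start")


@dataclass(frozen=True)
class RateEstimate:
    slope: float                        # a.u./min
    intercept: float
    r_squared: float
    window: FitWindow
    n_points: int


@dataclass(frozen=True)
class ModulationResult:
    percent: float                      # % change vs reference mean
    sd: float                           # % (propagated from replicate slope sds)
    n_sample: int
    n_reference: int
    p_value: float
    stars: str                          # "ns" | "*" | "**" | "***"
    direction: str                      # "enhancement" | "inhibition" | "ns"


@dataclass(frozen=True)
class BlotQuantification:
    sample_id: str
    mean: float                         # band intensity ratio to reference
    sd: float
    n: int
    p_value: float
    stars: str


#: default fit windows (minutes): transcription starts 60 min in and spans
#: 120 min; TX-TL is the same span shifted 1 h later for the translation lag.
DEFAULT_WINDOWS = {"transcription": (60.0, 180.0), "txtl": (120.0, 240.0)}


def stars_for(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_window(
    trace: KineticTrace,
    mode: str,
    start_override: float | None = None,
) -> FitWindow:
    """Mode-specific linear-fit window; ``start_override`` shifts the
    window keeping its 120-min duration."""
    if mode not in DEFAULT_WINDOWS:
        raise KineticsInputError(f"unknown mode {mode!r}")
    start, end = DEFAULT_WINDOWS[mode]
    if start_override is not None:
        duration = end - start
        start, end = float(start_override), float(start_override) + duration
    if trace.times[-1] < end:
        raise KineticsInputError(
            f"trace spans {trace.times[-1]:.0f} min; mode {mode!r} requires >= {end:.0f} min"
        )
    return FitWindow(start=start, end=end, mode=mode)


def fit_rate(trace: KineticTrace, window: FitWindow) -> RateEstimate:
    """OLS slope of fluorescence over in-window time points."""
    mask = (trace.times >= window.start) & (trace.times <= window.end)
    if int(mask.sum()) < 2:
        raise KineticsInputError("fewer than 2 points inside the fit window")
    t, f = trace.times[mask], trace.fluorescence[mask]
    res = stats.linregress(t, f)
    r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 1.0  # constant trace
    return RateEstimate(slope=float(res.slope), intercept=float(res.intercept),
                        r_squared=float(r2), window=window, n_points=int(mask.sum()))


def modulation(
    sample_rates: Sequence[RateEstimate],
    reference_rates: Sequence[RateEstimate],
    equal_var: bool = True,
) -> ModulationResult:
    """Percent rate change vs the no-TFO reference with t-test stars.

    ``percent = (mean_sample - mean_ref) / mean_ref * 100``; its sd is
    first-order ratio propagation of the replicate slope sds.  The
    t-test is two-sample two-sided, pooled variance by default (Welch
    with ``equal_var=False``).
    """
    if len(sample_rates) < 3 or len(reference_rates) < 3:
        raise KineticsInputError("need >=3 replicates per group")
    s = np.array([r.slope for r in sample_rates])
    r = np.array([r.slope for r in reference_rates])
    mr = float(np.mean(r))
    if mr <= 0:
        raise KineticsInputError("reference rate non-positive")
    ms = float(np.mean(s))
    percent = (ms - mr) / mr * 100.0
    sd_s, sd_r = float(np.std(s, ddof=1)), float(np.std(r, ddof=1))
    sd = 100.0 * np.hypot(sd_s / mr, ms * sd_r / mr**2)
    if np.var(s) == 0 and np.var(r) == 0:
        # degenerate replicates: no within-group spread to test against
        p = 1.0 if ms == mr else float("nan")
    else:
        p = float(stats.ttest_ind(s, r, equal_var=equal_var).pvalue)
    star = stars_for(p)
    if star == "ns":
        direction = "ns"
    else:
        direction = "enhancement" if percent > 0 else "inhibition"
    return ModulationResult(percent=percent, sd=sd, n_sample=len(s), n_reference=len(r),
                            p_value=p, stars=star, direction=direction)


def quantify_blot(
    band_values: Mapping[str, Sequence[float]],
    reference_id: str,
) -> list[BlotQuantification]:
    """End-point blot band intensities normalised to the reference.

    When replicate counts match, sample replicate *i* is divided by
    reference replicate *i* (paired normalisation); otherwise by the
    reference mean.  Significance is a one-sample t-test of the ratios
    against 1.0.  The reference itself normalises to exactly 1.0.
    """
    if reference_id not in band_values or len(band_values[reference_id]) < 1:
        raise KineticsInputError(f"reference {reference_id!r} absent or empty")
    ref = np.asarray(band_values[reference_id], float)
    if np.any(ref == 0):
        raise KineticsInputError("zero reference intensity")
    out = []
    for sid, vals in band_values.items():
        v = np.asarray(vals, float)
        ratios = v / ref if (sid != reference_id and v.size == ref.size) else v / float(np.mean(ref))
        if sid == reference_id:
            ratios = np.ones_like(v) if v.size > 1 else np.array([1.0])
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
        if ratios.size > 1 and np.ptp(ratios) > 0:
            p = float(stats.ttest_1samp(ratios, 1.0).pvalue)
        else:
            p = float("nan")
        out.append(BlotQuantification(sample_id=sid, mean=mean, sd=sd,
                                      n=int(ratios.size), p_value=p, stars=stars_for(p)))
    return out


#: placement-level direction rule: a triplex downstream of the consensus
#: tends to enhance transcription, one within the consensus to inhibit.
DEFAULT_RULE_TABLE = {
    ("A", "purine"): "enhancement", ("A", "pyrimidine"): "enhancement",
    ("B", "purine"): "enhancement", ("B", "pyrimidine"): "enhancement",
    ("C", "purine"): "inhibition", ("C", "pyrimidine"): "inhibition",
    ("D", "purine"): "inhibition", ("D", "pyrimidine"): "inhibition",
}


def predict_direction(tu, rule_table: Mapping | None = None) -> str:
    """Expected modulation direction for a TU geometry/motif pair.

    Consistency reporting only; never alters measured modulation.
    """
    table = DEFAULT_RULE_TABLE if rule_table is None else rule_table
    key = (tu.geometry, tu.tfo_motif)
    if key not in table:
        raise KineticsInputError(f"rule table has no entry for {key}")
    return table[key]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_kinetics_csv(path: str | Path) -> list[KineticTrace]:
    """Long CSV: sample_id, condition, replicate, time_min, fluorescence."""
    import pandas as pd

    df = pd.read_csv(path)
    traces = []
    for (sid, cond, rep), grp in df.groupby(["sample_id", "condition", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(KineticTrace(str(sid), str(cond), int(rep),
                                   grp["time_min"].to_numpy(), grp["fluorescence"].to_numpy()))
    return traces


def write_modulation_tsv(
    rows: Sequence[tuple[str, str, ModulationResult]], path: str | Path
) -> None:
    """Rows of (template, tfo_motif, result) as a table of normalised rates."""
    with open(path, "w") as fh:
        fh.write("template\ttfo\tnorm_rate_percent\tsd_percent\tp_value\tstars\tdirection\n")
        for template, tfo, m in rows:
            fh.write(f"{template}\t{tfo}\t{m.percent:+.1f}\t{m.sd:.1f}\t"
                     f"{m.p_value:.4g}\t{m.stars}\t{m.direction}\n")
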