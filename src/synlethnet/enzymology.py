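"""Flap-endonuclease screen analytics.

The in vitro assay reads enzyme activity as rising fluorescence after
cleavage of a fluorophore-quencher flap substrate. This module estimates
initial rates from kinetic traces, converts them to percent inhibition
against vehicle, fits four-parameter logistic (4PL) dose-response curves for
IC50 determination, and applies the two screening-funnel filters: the
quencherless-substrate counterscreen (removes fluorescent/quenching
artifacts) and Lipinski's rule-of-five drug-likeness triage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "RateEstimate",
    "DoseResponseFit",
    "CompoundDescriptors",
    "SelectivityResult",
    "FunnelResult",
    "traces_from_frame",
    "initial_rate",
    "percent_inhibition",
    "fit_ic50",
    "counterscreen_filter",
    "lipinski_filter",
    "selectivity_test",
    "screen_funnel",
]


@dataclass(frozen=True)
class KineticTrace:
    """One compound x concentration fluorescence time course."""

    compound_id: str
    conc: float  # molar
    times: tuple[float, ...]  # minutes, strictly increasing
    rfu: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "rfu", tuple(float(f) for f in self.rfu))
        if len(self.times) != len(self.rfu):
            raise ValueError("times and rfu must have equal length")
        if len(self.times) < 3:
            raise ValueError("a kinetic trace needs at least 3 points")
        if self.conc < 0:
            raise ValueError(f"conc must be >= 0, got {self.conc}")
        if not all(b > a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of fluorescence vs time over the fitted window."""

    slope: float  # RFU / min
    intercept: float
    r_squared: float
    window: tuple[float, float]


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit: activity = bottom + (top - bottom) / (1 + (C/IC50)^hill)."""

    ic50: float  # molar
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    ic50_in_range: bool  # IC50 within the tested dose span


@dataclass(frozen=True)
class CompoundDescriptors:
    """Physicochemical descriptors used by the rule-of-five filter."""

    compound_id: str
    mw: float  # Daltons
    clogp: float
    hbd: int
    hba: int


def traces_from_frame(traces: pd.DataFrame) -> list[KineticTrace]:
    """Split a long ``compound, conc_M, time_min, rfu`` table into traces."""
    out = []
    for (compound, conc), grp in traces.groupby(["compound", "conc_M"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            KineticTrace(str(compound), float(conc), grp["time_min"].tolist(), grp["rfu"].tolist())
        )
    return out


def initial_rate(trace: KineticTrace, window_fraction: float = 1.0) -> RateEstimate:
    """Least-squares slope of RFU vs time over the leading window.

    ``window_fraction`` restricts the fit to the first fraction of the trace
    span (1.0 = whole trace), useful when the exponential approach to plateau
    makes the full trace visibly curved.
    """
    if not 0 < window_fraction <= 1.0:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    t = np.asarray(trace.times)
    y = np.asarray(trace.rfu)
    t_end = t[0] + window_fraction * (t[-1] - t[0])
    mask = t <= t_end + 1e-12
    if mask.sum() < 3:
        raise ValueError(
            f"window [{t[0]}, {t_end}] holds {int(mask.sum())} points; at least 3 required"
        )
    t_w, y_w = t[mask], y[mask]
    if np.ptp(t_w) == 0:
        raise ValueError("zero time variance in the fit window")
    res = stats.linregress(t_w, y_w)
    r2 = 0.0 if math.isnan(res.rvalue) else float(np.clip(res.rvalue**2, 0.0, 1.0))
    return RateEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        window=(float(t_w[0]), float(t_w[-1])),
    )


def percent_inhibition(rate: RateEstimate, vehicle_rate: RateEstimate) -> float:
    """Rate loss relative to vehicle, in percent; capped above at 100."""
    if vehicle_rate.slope <= 0:
        raise ValueError(f"degenerate vehicle: slope {vehicle_rate.slope} <= 0")
    return min(100.0, 100.0 * (1.0 - rate.slope / vehicle_rate.slope))


def _four_pl(logc: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_ic50(
    concentrations: Sequence[float],
    pct_activity: Sequence[float],
    weighting: str = "relative",
) -> DoseResponseFit:
    """Fit a four-parameter logistic dose-response curve.

    Activity (percent of vehicle) is modeled as
    ``bottom + (top - bottom) / (1 + (C/IC50)^hill)`` with ``hill > 0`` and
    ``bottom >= -10`` (slightly negative floor tolerates noise). The fit is
    performed in log10 concentration, which makes the result equivariant
    under unit rescaling: scaling every concentration by a factor scales the
    fitted IC50 by the same factor.

    ``weighting="relative"`` (default) refines the initial unweighted fit
    with two reweighted passes using ``sigma = |fitted| + 1`` — the usual
    1/Y^2-style weighting for readouts whose error scales with signal (a 1%
    floor guards the zero-activity plateau). ``"uniform"`` keeps plain OLS.
    On noiseless data both give identical results.

    Poor fits set ``converged=False`` rather than raising; an IC50 landing
    outside the tested dose span is flagged via ``ic50_in_range``
    (inactive/flat series typically trip one of the two).
    """
    if weighting not in ("relative", "uniform"):
        raise ValueError(f"weighting must be 'relative' or 'uniform', got {weighting!r}")
    conc = np.asarray(concentrations, dtype=float)
    act = np.asarray(pct_activity, dtype=float)
    if conc.shape != act.shape:
        raise ValueError("concentrations and pct_activity must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 for dose-response fitting")
    if len(np.unique(conc)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")

    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()
    p0 = [max(float(act.min()), -10.0), float(act.max()), float(np.median(logc)), 1.0]
    bounds = ([-10.0, -1e4, lo - 6.0, 1e-3], [1e4, 1e4, hi + 6.0, 20.0])
    nan_fit = DoseResponseFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, False)
    try:
        popt, _ = optimize.curve_fit(_four_pl, logc, act, p0=p0, bounds=bounds, maxfev=20000)
        if weighting == "relative":
            for _ in range(2):
                sigma = np.abs(_four_pl(logc, *popt)) + 1.0
                popt, _ = optimize.curve_fit(
                    _four_pl, logc, act, p0=popt, bounds=bounds, sigma=sigma, maxfev=20000
                )
    except (RuntimeError, ValueError):
        return nan_fit
    bottom, top, log_ic50, hill = (float(p) for p in popt)
    resid = act - _four_pl(logc, *popt)
    ic50 = 10.0**log_ic50
    # a span-less curve (flat/inactive series) leaves the IC50 unidentifiable
    span = abs(top - bottom)
    identifiable = span > max(1e-6 * max(1.0, abs(top)), 0.05 * float(np.ptp(act)))
    return DoseResponseFit(
        ic50=ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        rss=float(np.sum(resid**2)),
        converged=identifiable,
        ic50_in_range=bool(conc.min() <= ic50 <= conc.max()),
    )


def counterscreen_filter(
    primary_hits: Iterable[str],
    quencherless_inhibition: Mapping[str, float],
    threshold: float = 50.0,
) -> list[str]:
    """Drop hits whose apparent inhibition persists against the quencherless substrate.

    A compound still "inhibiting" when cleavage cannot change the signal is a
    fluorescence artifact (autofluorescent or quenching), not an enzyme
    inhibitor. Hits at or above ``threshold`` percent apparent inhibition in
    the counterscreen are removed; order of the retained hits is preserved.
    """
    retained = []
    for compound in primary_hits:
        if compound not in quencherless_inhibition:
            raise ValueError(f"no counterscreen entry for compound {compound!r}")
        if quencherless_inhibition[compound] < threshold:
            retained.append(compound)
    return retained


_LIPINSKI_RULES = (
    ("mw", lambda v: v < 500.0, "mw >= 500"),
    ("clogp", lambda v: v <= 5.0, "clogp > 5"),
    ("hbd", lambda v: v <= 5, "hbd > 5"),
    ("hba", lambda v: v <= 10, "hba > 10"),
)


def lipinski_filter(descriptors: pd.DataFrame) -> pd.DataFrame:
    """Rule-of-five triage: MW < 500, cLogP <= 5, HBD <= 5, HBA <= 10.

    Any single violation fails the compound. Returns a DataFrame
    ``compound_id, passes, violations`` (violations semicolon-joined).
    """
    required = ["compound_id", "mw", "clogp", "hbd", "hba"]
    missing = [c for c in required if c not in descriptors.columns]
    if missing:
        raise ValueError(f"descriptor table missing column(s): {', '.join(missing)}")
    if descriptors[required].isna().any().any():
        bad = descriptors.loc[descriptors[required].isna().any(axis=1), "compound_id"].tolist()
        raise ValueError(f"missing descriptor values for: {', '.join(map(str, bad))}")
    rows = []
    for r in descriptors.itertuples():
        violations = [label for col, ok, label in _LIPINSKI_RULES if not ok(getattr(r, col))]
        rows.append({"compound_id": r.compound_id, "passes": not violations, "violations": ";".join(violations)})
    return pd.DataFrame(rows, columns=["compound_id", "passes", "violations"])


@dataclass(frozen=True)
class SelectivityResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons across genotypes."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, significant


def selectivity_test(
    viability_by_genotype: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> SelectivityResult:
    """Compare viability across genotypes: one-way ANOVA then Tukey HSD.

    Thin wrapper over :func:`scipy.stats.f_oneway` and
    :func:`scipy.stats.tukey_hsd`; ``mean_diff`` is mean(a) - mean(b).
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in viability_by_genotype.items()}
    if len(groups) < 2:
        raise ValueError("at least 2 genotypes are required")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"genotype {name!r} has {len(vals)} replicates; at least 2 required")
    names = list(groups)
    samples = [groups[n] for n in names]
    f_stat, p_val = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return SelectivityResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj", "significant"]),
    )


@dataclass(frozen=True)
class FunnelResult:
    """Stagewise outcome of the primary screen -> counterscreen -> rule-of-five funnel."""

    primary_inhibition: dict[str, float]
    primary_hits: list[str]
    after_counterscreen: list[str]
    final_hits: list[str]
    tallies: dict[str, int]


def screen_funnel(
    traces: pd.DataFrame,
    quencherless_inhibition: Mapping[str, float],
    descriptors: pd.DataFrame,
    screening_conc: float,
    hit_threshold: float = 50.0,
    counterscreen_threshold: float = 50.0,
    window_fraction: float = 1.0,
) -> FunnelResult:
    """Run the full hit-triage funnel on a screened library.

    Primary hits are compounds whose initial-rate inhibition at
    ``screening_conc`` (vs their own vehicle trace, conc 0) meets
    ``hit_threshold``; the counterscreen then removes fluorescence artifacts
    and the rule-of-five filter removes non-drug-like compounds.
    """
    rates: dict[str, dict[float, RateEstimate]] = {}
    for trace in traces_from_frame(traces):
        rates.setdefault(trace.compound_id, {})[trace.conc] = initial_rate(trace, window_fraction)
    inhibition = {}
    for compound, by_conc in rates.items():
        if 0.0 not in by_conc:
            raise ValueError(f"no vehicle (conc 0) trace for compound {compound!r}")
        if screening_conc not in by_conc:
            raise ValueError(f"no trace at screening dose for compound {compound!r}")
        inhibition[compound] = percent_inhibition(by_conc[screening_conc], by_conc[0.0])
    primary_hits = [c for c, pct in inhibition.items() if pct >= hit_threshold]
    after_counter = counterscreen_filter(primary_hits, quencherless_inhibition, counterscreen_threshold)
    lipinski = lipinski_filter(descriptors)
    druglike = set(lipinski.loc[lipinski["passes"], "compound_id"].astype(str))
    final = [c for c in after_counter if c in druglike]
    return FunnelResult(
        primary_inhibition=inhibition,
        primary_hits=primary_hits,
        after_counterscreen=after_counter,
        final_hits=final,
        tallies={
            "screened": len(inhibition),
            "primary_hits": len(primary_hits),
            "after_counterscreen": len(after_counter),
            "final_hits": len(final),
        },
    )
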