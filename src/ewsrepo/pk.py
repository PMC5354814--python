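"""Non-compartmental analysis (NCA) of blood gold concentration-time data.

Auranofin dissociates immediately in blood, so its pharmacokinetics are
followed through elemental gold.  Gold is 196.97/678.48 = 29% of auranofin
by mass, which drives the dose and molar conversions here.  The NCA itself
is model-free: Cmax/Tmax read off the observed profile, AUC by the linear
trapezoid rule, the terminal elimination rate Kel from a log-linear
regression over a terminal window, and derived quantities
T1/2 = ln2/Kel, AUC(0-inf) = AUC(0-t) + C_last/Kel, and apparent clearance
Cl/F = gold dose / AUC(0-inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GOLD_MW",
    "AURANOFIN_MW",
    "gold_mass_fraction",
    "gold_dose",
    "to_molar",
    "ConcTimeProfile",
    "NCAResult",
    "auc_trapezoid",
    "terminal_slope",
    "nca",
    "trough_summary",
]

GOLD_MW = 196.97        # g/mol, elemental gold
AURANOFIN_MW = 678.48   # g/mol, gold(I) triethylphosphine thioglucose tetraacetate


def gold_mass_fraction() -> float:
    """Mass fraction of gold in auranofin (~0.29)."""
    return GOLD_MW / AURANOFIN_MW


def gold_dose(auranofin_dose_mg_per_kg: float) -> float:
    """Gold dose (mg/kg) delivered by an auranofin dose (mg/kg)."""
    if auranofin_dose_mg_per_kg < 0:
        raise ValueError("dose must be nonnegative")
    return auranofin_dose_mg_per_kg * gold_mass_fraction()


def to_molar(conc_ug_per_ml: float) -> float:
    """Convert a gold concentration from ug/mL to umol/L.

    ug/mL / (g/mol) = mmol/L, hence the factor 1000 to umol/L; e.g.
    12.43 ug/mL -> 63.10 umol/L.
    """
    if np.any(np.asarray(conc_ug_per_ml) < 0):
        raise ValueError("concentration must be nonnegative")
    return conc_ug_per_ml / GOLD_MW * 1000.0


@dataclass
class ConcTimeProfile:
    """Mean blood concentration-time data for one treatment."""

    times_hr: np.ndarray
    conc_ug_per_ml: np.ndarray
    auranofin_dose_mg_per_kg: float = 12.0
    route: str = "ip_suspension"
    body_weight_kg: float | None = None

    def __post_init__(self) -> None:
        self.times_hr = np.asarray(self.times_hr, dtype=float)
        self.conc_ug_per_ml = np.asarray(self.conc_ug_per_ml, dtype=float)
        if self.times_hr.shape != self.conc_ug_per_ml.shape:
            raise ValueError("times and concentrations differ in length")
        if self.times_hr.size < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times_hr) <= 0) or self.times_hr[0] < 0:
            raise ValueError("times must be strictly increasing and nonnegative")
        if self.times_hr[0] != 0:
            raise ValueError("profile must include the pre-dose t=0 sample")
        if np.any(self.conc_ug_per_ml < 0):
            raise ValueError("concentrations must be nonnegative")

    @classmethod
    def from_csv(cls, path, **meta) -> "ConcTimeProfile":
        df = pd.read_csv(path)
        return cls(df["time_hr"].to_numpy(), df["conc_ug_per_ml"].to_numpy(), **meta)


@dataclass
class NCAResult:
    """One row of non-compartmental parameters (the summary-table layout)."""

    cmax_ug_per_ml: float
    cmax_umol_l: float
    tmax_hr: float
    auc_0_t: float                    # ug*hr/mL over the observed window
    auc_0_inf: float | None
    kel_per_hr: float | None
    t_half_hr: float | None
    cl_f_ml_hr_kg: float | None
    gold_dose_mg_per_kg: float
    auranofin_dose_mg_per_kg: float
    terminal_points_used: int
    terminal_r2: float | None
    extrapolation_refused: bool = False
    note: str = ""

    def to_series(self) -> pd.Series:
        return pd.Series({
            "Auranofin Dose (mg/kg)": self.auranofin_dose_mg_per_kg,
            "Gold Dose (mg/kg)": self.gold_dose_mg_per_kg,
            "Cmax (ug/mL)": self.cmax_ug_per_ml,
            "Cmax (umol/L)": self.cmax_umol_l,
            "Tmax (hr)": self.tmax_hr,
            "AUC0-inf (ug*hr/mL)": self.auc_0_inf,
            "Kel (1/hr)": self.kel_per_hr,
            "T1/2 (hr)": self.t_half_hr,
            "Cl/F (mL/hr/kg)": self.cl_f_ml_hr_kg,
        })


def auc_trapezoid(times, conc) -> float:
    """Linear-trapezoid area under the concentration-time curve."""
    return float(np.trapezoid(np.asarray(conc, float), np.asarray(times, float)))


def terminal_slope(times, conc, rule: str = "best_r2",
                   min_points: int = 3, max_points: int = 6):
    """Terminal log-linear regression; returns (kel, n_points, r2) or None.

    Candidate windows are the last ``min_points``..``max_points`` observed
    positive concentrations strictly after Tmax.  ``rule='best_r2'`` picks
    the window maximizing adjusted R^2; ``rule='last_3'`` (or ``last_k``)
    pins the window size.  Returns None when fewer than ``min_points``
    qualify or no window yields a positive elimination rate.
    """
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    imax = int(np.argmax(c))
    post = np.flatnonzero((np.arange(t.size) > imax) & (c > 0))
    if post.size < min_points:
        return None
    if rule.startswith("last_"):
        sizes = [min(int(rule.split("_")[1]), post.size)]
    elif rule == "best_r2":
        sizes = range(min_points, min(max_points, post.size) + 1)
    else:
        raise ValueError(f"unknown terminal rule {rule!r}")
    best = None
    for k in sizes:
        idx = post[-k:]
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best[0]:
            best = (adj, -float(slope), k, float(r2))
    if best is None:
        return None
    _, kel, k, r2 = best
    return kel, k, r2


def nca(profile: ConcTimeProfile, terminal_rule: str = "best_r2") -> NCAResult:
    """Full non-compartmental summary of a single-dose profile.

    When no valid elimination phase exists (fewer than 3 positive post-Tmax
    points, or a non-negative terminal slope), extrapolation to infinity is
    refused and only the observed-window quantities are reported.
    """
    t, c = profile.times_hr, profile.conc_ug_per_ml
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_t = auc_trapezoid(t, c)
    gdose = gold_dose(profile.auranofin_dose_mg_per_kg)

    fit = terminal_slope(t, c, terminal_rule)
    if fit is None:
        return NCAResult(cmax, to_molar(cmax), tmax, auc_t, None, None, None,
                         None, gdose, profile.auranofin_dose_mg_per_kg, 0, None,
                         extrapolation_refused=True,
                         note="no usable terminal elimination phase")
    kel, npts, r2 = fit
    c_last = float(c[c > 0][-1])
    auc_inf = auc_t + c_last / kel
    t_half = float(np.log(2) / kel)
    cl_f = gdose * 1000.0 / auc_inf          # ug/kg over ug*hr/mL -> mL/hr/kg
    return NCAResult(cmax, to_molar(cmax), tmax, auc_t, float(auc_inf),
                     float(kel), t_half, float(cl_f), gdose,
                     profile.auranofin_dose_mg_per_kg, npts, r2)


def trough_summary(multidose: pd.DataFrame, single: ConcTimeProfile | None = None,
                   interval_hr: float = 24.0, n_doses: int = 5) -> dict:
    """Trough (pre-dose) concentrations under once-daily repeat dosing.

    ``multidose`` has columns time_hr, conc_ug_per_ml sampled at least at
    the end of each dosing interval.  Returns the per-interval troughs and,
    when a single-dose profile sampled at ``interval_hr`` is supplied, the
    accumulation ratio trough_n / C_single(interval).  Missing trough times
    are reported absent rather than interpolated.
    """
    troughs = {}
    tt = multidose["time_hr"].to_numpy(float)
    cc = multidose["conc_ug_per_ml"].to_numpy(float)
    for k in range(1, n_doses + 1):
        target = k * interval_hr
        j = np.flatnonzero(np.isclose(tt, target))
        troughs[target] = float(cc[j[0]]) if j.size else None
    out = {"troughs_ug_per_ml": troughs,
           "final_trough_ug_per_ml": troughs.get(n_doses * interval_hr)}
    missing = [t for t, v in troughs.items() if v is None]
    if missing:
        out["missing_times_hr"] = missing
    if single is not None and out["final_trough_ug_per_ml"] is not None:
        j = np.flatnonzero(np.isclose(single.times_hr, interval_hr))
        if j.size:
            ref = float(single.conc_ug_per_ml[j[0]])
            if ref > 0:
                out["accumulation_ratio"] = out["final_trough_ug_per_ml"] / ref
    if "accumulation_ratio" not in out:
        out["accumulation_flagged"] = "single-dose reference unavailable"
    return out
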