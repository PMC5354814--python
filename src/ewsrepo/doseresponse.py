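"""Median-effect dose-response fitting and Chou–Talalay combination index.

The median-effect model relates dose D to fraction affected fa through
``fa/fu = (D/Dm)^m`` (fu = 1 - fa), i.e. a straight line of slope m and
intercept -m*log10(Dm) in log10(fa/(1-fa)) vs log10(D) coordinates.  Dm is
the dose producing 50% effect and equals the IC50; m measures
sigmoidicity.  Curves never crossing 50% effect inside the tested range
are reported censored ("> top dose" or "< bottom dose") rather than
extrapolated.

For a two-drug combination at doses (d1, d2) producing effect fa, the
(mutually exclusive, Loewe-type) combination index is::

    CI = d1/Dx1 + d2/Dx2,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i)

where Dx_i is the dose of drug i alone needed for the same effect.
CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseFit",
    "fit_median_effect",
    "summarize_replicate_fits",
    "combination_index",
    "combination_index_table",
    "classify_ci",
    "CI_CLASSES",
]

#: effect levels eligible for the logit regression; cells outside are
#: excluded (too close to 0 or 1 for the transform to be informative)
FA_CLIP = (0.01, 0.99)

#: CI bands: < 0.5 strong synergy, < 0.9 synergy, an explicit additive band
#: around 1 (the published convention gives only "=1 additive"; [0.9, 1.1]
#: pins the open interval), > 1.1 antagonism.
CI_CLASSES = ("strong_synergy", "synergy", "additive", "antagonism", "undefined")


@dataclass
class DoseResponseFit:
    """Median-effect parameters for one compound on one cell line."""

    compound_id: str = "DRUG"
    cell_line: str = ""
    dm: float | None = None            # umol/L; IC50 when uncensored
    m: float | None = None
    fit_sse: float | None = None
    ic50_censored: str = "none"        # none | above_max | below_min | failed
    censor_bound: float | None = None  # the boundary dose when censored
    n_points_used: int = 0
    note: str = ""

    @property
    def ic50(self) -> float | None:
        return self.dm

    @property
    def ic50_display(self) -> str:
        if self.ic50_censored == "above_max":
            return f"> {self.censor_bound:g}"
        if self.ic50_censored == "below_min":
            return f"< {self.censor_bound:g}"
        if self.dm is None:
            return "NA"
        return f"{self.dm:.4g}"

    def dx(self, fa: float) -> float:
        """Dose of this agent alone producing effect level ``fa``."""
        if self.dm is None or self.m is None:
            raise ValueError("censored or failed fit has no dose-effect curve")
        if not 0 < fa < 1:
            raise ValueError("fa must be strictly inside (0, 1)")
        return self.dm * (fa / (1 - fa)) ** (1 / self.m)

    def fa(self, dose: float) -> float:
        if self.dm is None or self.m is None:
            raise ValueError("censored or failed fit has no dose-effect curve")
        if dose <= 0:
            return 0.0
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)


def fit_median_effect(doses, fractions_affected, compound_id: str = "DRUG",
                      cell_line: str = "", eps: tuple = FA_CLIP) -> DoseResponseFit:
    """Fit (Dm, m) by the median-effect linearization.

    Ordinary least squares of log10(fa/(1-fa)) on log10(D).  Points with
    fa outside ``eps`` (including stimulation, fa <= 0, and saturated
    cells) are excluded from the regression rather than clipped: clipping
    would drag near-boundary points off the median-effect line, while on
    noiseless model data every retained point is exactly on it.  Censoring:

    * all observed fa <= 0.5  ->  ``above_max`` at the top tested dose
    * fa >= 0.5 already at the lowest dose -> ``below_min`` there
    * fewer than 4 usable points -> ``failed`` with reason
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(fractions_affected, dtype=float)
    if d.shape != fa.shape:
        raise ValueError("doses and fractions differ in length")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    if np.nanmax(fa) <= 0.5:
        return DoseResponseFit(compound_id, cell_line, ic50_censored="above_max",
                               censor_bound=float(d.max()),
                               note="no dose reached 50% effect")
    if fa[np.argmin(d)] >= 0.5:
        return DoseResponseFit(compound_id, cell_line, ic50_censored="below_min",
                               censor_bound=float(d.min()),
                               note="50% effect already at the lowest dose")

    usable = (fa >= eps[0]) & (fa <= eps[1])
    d_u, fa_u = d[usable], fa[usable]
    if usable.sum() < 4:
        return DoseResponseFit(compound_id, cell_line, ic50_censored="failed",
                               note=f"only {int(usable.sum())} usable points")
    x = np.log10(d_u)
    y = np.log10(fa_u / (1.0 - fa_u))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        return DoseResponseFit(compound_id, cell_line, ic50_censored="failed",
                               note="non-positive slope; no dose dependence")
    dm = 10.0 ** (-intercept / m)
    sse = float(np.sum((np.polyval([m, intercept], x) - y) ** 2))
    return DoseResponseFit(compound_id, cell_line, dm=float(dm), m=float(m),
                           fit_sse=sse, n_points_used=int(usable.sum()))


def summarize_replicate_fits(fits: list[DoseResponseFit]) -> dict:
    """Mean +/- SD of IC50 across replicate fits (censored fits reported as-is).

    Mirrors the convention of publishing IC50 as mean +/- SD over >= 3
    independent experiments, with censored replicates collapsing the summary
    to the censoring bound.
    """
    censored = [f for f in fits if f.ic50_censored != "none"]
    clean = [f for f in fits if f.ic50_censored == "none"]
    if censored and not clean:
        return {"display": censored[0].ic50_display, "n": len(fits),
                "censored": censored[0].ic50_censored}
    vals = np.array([f.dm for f in clean])
    out = {"mean": float(vals.mean()),
           "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
           "n": len(clean), "censored": "none"}
    out["display"] = f"{out['mean']:.3g} ± {out['sd']:.2g}"
    return out


# ---------------------------------------------------------------------------
# Combination index


def combination_index(d1: float, d2: float, fa: float,
                      fit1: DoseResponseFit, fit2: DoseResponseFit) -> float:
    """Chou–Talalay CI at one combination cell; NaN when undefined.

    Undefined when fa is outside (0, 1) — including negative inhibition,
    which carries no dose-equivalent — or when either single-agent fit is
    censored.
    """
    if fit1.ic50_censored != "none" or fit2.ic50_censored != "none":
        raise ValueError("CI requires uncensored single-agent fits")
    if not 0.0 < fa < 1.0:
        return float("nan")
    return d1 / fit1.dx(fa) + d2 / fit2.dx(fa)


def combination_index_table(matrix: pd.DataFrame, fit1: DoseResponseFit,
                            fit2: DoseResponseFit,
                            additive_band: tuple = (0.9, 1.1)) -> pd.DataFrame:
    """CI and class per interior cell of a 9x9 dose-matrix table.

    ``matrix`` columns: dose1_nmol_l, dose2_nmol_l, percent_inhibition
    (replicates averaged if a ``replicate`` column repeats cells).  Doses
    are nmol/L while fits are umol/L; converted here.  Zero-dose rows and
    columns anchor the single-agent axes and carry no CI.
    """
    df = (matrix.groupby(["dose1_nmol_l", "dose2_nmol_l"], as_index=False)
          ["percent_inhibition"].mean())
    out_rows = []
    for _, r in df.iterrows():
        d1n, d2n, pct = r["dose1_nmol_l"], r["dose2_nmol_l"], r["percent_inhibition"]
        fa = pct / 100.0
        interior = d1n > 0 and d2n > 0
        if not interior:
            ci = float("nan")
            label = "single_agent" if (d1n > 0 or d2n > 0) else "untreated"
        elif pct < 0:
            ci = float("nan")
            label = "undefined"      # negative inhibition has no CI
        else:
            ci = combination_index(d1n / 1000.0, d2n / 1000.0, fa, fit1, fit2)
            label = classify_ci(ci, additive_band)
        out_rows.append({"dose1_nmol_l": d1n, "dose2_nmol_l": d2n,
                         "fa": fa, "ci": ci, "ci_class": label})
    return pd.DataFrame(out_rows)


def classify_ci(ci: float, additive_band: tuple = (0.9, 1.1)) -> str:
    """Band a CI value: <0.5 strong synergy, <0.9 synergy, ~1 additive, >1.1 antagonism."""
    if ci is None or not np.isfinite(ci):
        return "undefined"
    lo, hi = additive_band
    if ci < 0.5:
        return "strong_synergy"
    if ci < lo:
        return "synergy"
    if ci <= hi:
        return "additive"
    return "antagonism"
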