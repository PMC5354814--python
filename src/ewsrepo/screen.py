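"""High-throughput screen normalization, quality gating, and hit calling.

The primary screen measures luminescent viability signal in 384-well
plates at a single concentration (1 umol/L).  Signals are normalized to
percent inhibition against the per-plate vehicle-control mean; plates must
pass the Z' >= 0.5 quality gate before any hit is called.  A compound is a
*hit* when it inhibits any tumor (EWS) line by more than the threshold
(strictly > 50%); hits that also kill a non-tumorigenic counter-screen
line, or that are already prescribed for the disease (blacklist), are not
nominated for validation.

Screen readouts published as "< 50" are *left-censored*: all the hit logic
needs is the predicate ``value > 50``, which a censored value answers
(False) without pretending to a numeric measurement.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CensoredBelow",
    "percent_inhibition",
    "z_prime",
    "qc_plates",
    "plate_inhibition",
    "call_hits",
    "load_screen_hits_table",
    "EWS_LINES",
    "CONTROL_LINES",
    "PRESCRIBED_EWS_DRUGS",
]

#: tumor lines carrying an EWSR1 fusion, and the non-tumorigenic /
#: benign counter-screen lines
EWS_LINES = ("A673", "TC-71", "SK-ES-1", "RD-ES", "CHLA-258", "COG-E-352")
CONTROL_LINES = ("HS 822.T", "HS 863.T", "HS 919.T")

#: drugs already prescribed for the disease, removed from nomination
PRESCRIBED_EWS_DRUGS = ("vincristine", "doxorubicin", "etoposide")


@dataclass(frozen=True)
class CensoredBelow:
    """A measurement reported only as "< bound" (left-censored)."""

    bound: float

    def __gt__(self, other: float) -> bool:
        # a value known to lie below `bound` cannot exceed any x >= bound;
        # comparisons against x < bound are genuinely unknown
        if other >= self.bound:
            return False
        raise ValueError(
            f"'< {self.bound}' vs threshold {other}: comparison indeterminate")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"< {self.bound:g}"


def parse_inhibition(value) -> float | CensoredBelow:
    """Parse a percent-inhibition cell; '< X' becomes a censored value."""
    if isinstance(value, (int, float, np.floating)):
        return float(value)
    s = str(value).strip()
    if s.startswith("<"):
        return CensoredBelow(float(s.lstrip("<").strip()))
    return float(s)


def exceeds(value, threshold: float) -> bool:
    """``value > threshold`` honouring censored entries."""
    if isinstance(value, CensoredBelow):
        return value > threshold
    return float(value) > threshold


# ---------------------------------------------------------------------------
# Normalization and QC


def percent_inhibition(signal, vehicle_mean: float):
    """``100 * (1 - signal / vehicle_mean)``; negative = stimulation."""
    if vehicle_mean <= 0:
        raise ValueError("vehicle mean must be positive")
    return 100.0 * (1.0 - np.asarray(signal, dtype=float) / vehicle_mean)


def z_prime(pos_signals, neg_signals) -> float:
    """Z' = 1 - 3(sd_p + sd_n) / |mean_p - mean_n| (sample SDs).

    >= 0.5 denotes an excellent assay window.  Identical control means make
    the statistic undefined and raise.
    """
    p = np.asarray(pos_signals, dtype=float)
    n = np.asarray(neg_signals, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("need >= 2 wells per control group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ValueError("control means coincide; Z' undefined, plate rejected")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def qc_plates(plates: pd.DataFrame, z_min: float = 0.5) -> pd.DataFrame:
    """Per-plate Z' table with a pass/fail flag (fail = excluded downstream).

    Plates whose Z' is undefined (coincident control means) fail with the
    reason recorded.
    """
    rows = []
    for plate_id, grp in plates.groupby("plate_id"):
        pos = grp.loc[grp["well_type"] == "positive_control", "signal"]
        neg = grp.loc[grp["well_type"] == "vehicle", "signal"]
        try:
            z = z_prime(pos, neg)
            rows.append({"plate_id": plate_id, "z_prime": z,
                         "passed": bool(z >= z_min), "reason": ""})
        except ValueError as exc:
            rows.append({"plate_id": plate_id, "z_prime": np.nan,
                         "passed": False, "reason": str(exc)})
    return pd.DataFrame(rows)


def plate_inhibition(plates: pd.DataFrame, z_min: float = 0.5) -> pd.DataFrame:
    """Percent inhibition for sample wells of plates passing the Z' gate.

    Vehicle means are computed per plate (absorbing plate effects).
    Returns columns compound_id, cell_line, conc_umol_l, inhibition.
    """
    qc = qc_plates(plates, z_min).set_index("plate_id")
    rows = []
    for plate_id, grp in plates.groupby("plate_id"):
        if not qc.loc[plate_id, "passed"]:
            continue
        vmean = grp.loc[grp["well_type"] == "vehicle", "signal"].mean()
        samples = grp[grp["well_type"] == "sample"]
        inh = percent_inhibition(samples["signal"].to_numpy(), vmean)
        for (_, r), pi in zip(samples.iterrows(), inh):
            rows.append({"compound_id": r["compound_id"],
                         "cell_line": r["cell_line"],
                         "conc_umol_l": r["conc_umol_l"],
                         "inhibition": pi})
    return pd.DataFrame(rows,
                        columns=["compound_id", "cell_line", "conc_umol_l",
                                 "inhibition"])


# ---------------------------------------------------------------------------
# Hit calling


def call_hits(inhibition: pd.DataFrame, threshold: float = 50.0,
              blacklist=PRESCRIBED_EWS_DRUGS,
              ews_lines=EWS_LINES, control_lines=CONTROL_LINES) -> pd.DataFrame:
    """Classify compounds from a compound x cell-line inhibition table.

    ``inhibition`` has columns compound_id, cell_line, inhibition (numeric
    or censored '< X' strings).  The rule set:

    * ``is_hit_any_ews``    — inhibition strictly > threshold in >= 1 EWS line
    * ``control_cytotoxic`` — inhibition > threshold in >= 1 counter-screen line
    * ``blacklisted``       — compound on the prescribed-drug list
    * ``nominated``         — hit AND not cytotoxic AND not blacklisted

    Compounds missing any counter-screen measurement are flagged
    ``incomplete`` and never nominated.
    """
    ews = {l.upper() for l in ews_lines}
    ctrl = {l.upper() for l in control_lines}
    black = {str(b).strip().lower() for b in (blacklist or [])}
    rows = []
    for comp, grp in inhibition.groupby("compound_id", sort=False):
        lines = {str(r["cell_line"]).strip().upper().rstrip("."):
                 parse_inhibition(r["inhibition"]) for _, r in grp.iterrows()}
        seen_ews = [l for l in lines if l in ews]
        seen_ctrl = [l for l in lines if l in ctrl]
        incomplete = not seen_ews or not seen_ctrl
        hit = any(exceeds(lines[l], threshold) for l in seen_ews)
        toxic = any(exceeds(lines[l], threshold) for l in seen_ctrl)
        bl = str(comp).strip().lower() in black
        rows.append({
            "compound_id": comp,
            "is_hit_any_ews": hit,
            "control_cytotoxic": toxic,
            "blacklisted": bl,
            "incomplete": incomplete,
            "nominated": hit and not toxic and not bl and not incomplete,
        })
    return pd.DataFrame(rows)


def load_screen_hits_table() -> pd.DataFrame:
    """Published primary-screen hit table in long form.

    One row per (compound, cell line) with the printed percent inhibition
    at 1 umol/L; "< 50" entries kept verbatim (left-censored).  Hs 919.T is
    the benign-osteoid counter-screen line of that table.
    """
    ref = importlib.resources.files("ewsrepo.data") / "screen_hits_table.tsv"
    with importlib.resources.as_file(ref) as path:
        wide = pd.read_csv(path, sep="\t", dtype=str)
    long = wide.melt(id_vars="drug", var_name="cell_line",
                     value_name="inhibition")
    long = long.rename(columns={"drug": "compound_id"})
    # preserve the table's row order for compounds
    order = {d: i for i, d in enumerate(wide["drug"])}
    return long.sort_values(by="compound_id", key=lambda s: s.map(order),
                            kind="stable").reset_index(drop=True)
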