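"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its config and seed: identical seeds
give bit-identical outputs.  The generators emulate, structurally, the data
the analysis consumes — rank-transformed drug perturbation profiles with
replicate instances and planted reverser/mimic drugs, up/down disease
signatures, responder vs non-responder expression matrices, 384-well plates
with controls sized for Z' >= 0.5, median-effect dose-response curves and
9x9 dose matrices with a controllable Loewe deviation, one-compartment
absorption PK profiles, and exponential survival with per-arm hazards.

Rank convention: rank 1 = most up-regulated gene of the instance.  A
*reverser* drug down-regulates the signature's up-genes (pushing them to
the bottom ranks) and up-regulates its down-genes; a *mimic* does the
opposite.  Profiles are built by rank-transforming a latent
differential-expression vector in which signature genes are shifted by
+/- 1 and every gene carries gaussian jitter of scale ``noise_sd`` —
at ``noise_sd=0`` the planted structure is exact, and it degrades
monotonically as the jitter grows.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .signatures import DrugProfileDB, GeneSignature

__all__ = [
    "SynConfig",
    "PAPER_PK_TIMES_HR",
    "gen_signature",
    "gen_drug_profiles",
    "gen_responder_matrix",
    "gen_plate",
    "gen_dose_response",
    "gen_dose_matrix",
    "gen_pk_profile",
    "gen_pk_profile_multidose",
    "gen_survival",
    "twofold_doses",
    "write_bundle",
]

#: blood-sampling grid used for the single-dose gold PK study (hours):
#: pre-dose, 5/15/30/60 min, then 2, 4, 8, 12, 24 and 48 h.
PAPER_PK_TIMES_HR = (0.0, 5 / 60, 15 / 60, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)


@dataclass
class SynConfig:
    """Knobs for every generator; defaults define the study conditions.

    The gene-universe and drug-library sizes mimic a CMap-style resource
    scaled to desk size: 2000 genes, 200 drugs with 1-5 replicate instances
    each.  Signature sizes per direction default to 50 — the source study
    does not state its signature sizes, so this is a convention (typical of
    connectivity-map queries) and is flagged as such here.
    """

    seed: int = 0
    n_genes: int = 2000
    n_drugs: int = 200
    instances_per_drug: tuple[int, int] = (1, 5)   # inclusive range, mixed
    n_planted_reversers: int = 5
    n_planted_mimics: int = 5
    signature_size: int = 50                        # per direction
    noise_sd: float = 0.0                           # latent jitter scale

    # responder matrix
    n_per_group: int = 10
    n_diff_genes: int = 100
    group_effect_sd: float = 2.0                    # shift in baseline SDs

    # plates
    plate_rows: int = 16
    plate_cols: int = 24
    n_control_wells: int = 32                       # per control type
    vehicle_mean: float = 10000.0
    plate_noise_cv: float = 0.05

    # PK (one-compartment, first-order absorption).  ke is the reported
    # terminal gold elimination rate; dose is the gold fraction of a
    # 12 mg/kg auranofin dose; ka and V/F follow from the reported Tmax
    # (~8 hr) and exposure (AUC = F*Dose/(V*ke)) of the same study.
    pk_ka: float = 0.33                             # 1/hr
    pk_ke: float = 0.029                            # 1/hr
    pk_v_f: float = 224.0                           # mL/kg (V/F)
    pk_dose_ug_per_kg: float = 3480.0               # absorbed gold F*Dose, ug/kg

    # survival
    arm_hazards: dict = field(default_factory=lambda: {
        "vehicle": 1 / 20, "auranofin": 1 / 30,
        "ganetespib": 1 / 30, "combination": 1 / 40})  # events/day
    n_per_arm: int = 12
    censor_day: float = 120.0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_drugs, self.n_per_group, self.n_diff_genes]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_planted_reversers + self.n_planted_mimics > self.n_drugs:
            raise ValueError("more planted drugs than drugs")
        if self.signature_size < 0 or 2 * self.signature_size > self.n_genes:
            raise ValueError("signature_size must fit twice in the gene universe")
        if self.noise_sd < 0 or self.plate_noise_cv < 0:
            raise ValueError("noise scales must be nonnegative")

    def rng(self, *stream) -> np.random.Generator:
        """Independent, reproducible stream keyed by (seed, *stream).

        Stream labels are hashed with crc32, which is stable across
        processes (unlike built-in str hashing).
        """
        keys = tuple(zlib.crc32(str(s).encode()) for s in stream)
        return np.random.default_rng(np.random.SeedSequence((self.seed,) + keys))

    @property
    def gene_universe(self) -> list[str]:
        return [f"G{i}" for i in range(1, self.n_genes + 1)]


# ---------------------------------------------------------------------------
# Signatures and drug profiles


def gen_signature(cfg: SynConfig, kind: str = "disease") -> GeneSignature:
    """Random disjoint up/down gene sets of ``cfg.signature_size`` each."""
    if 2 * cfg.signature_size > cfg.n_genes:
        raise ValueError("signature_size too large for the gene universe")
    rng = cfg.rng("signature", kind)
    picked = rng.choice(cfg.n_genes, size=2 * cfg.signature_size, replace=False)
    genes = cfg.gene_universe
    up = [genes[i] for i in picked[:cfg.signature_size]]
    down = [genes[i] for i in picked[cfg.signature_size:]]
    return GeneSignature(up, down, label=kind)


def gen_drug_profiles(cfg: SynConfig, sig: GeneSignature) -> DrugProfileDB:
    """Drug instance rank profiles with planted reversers and mimics.

    Drugs D001..D{n_planted_reversers} are reversers, the next block mimics,
    the rest background (exchangeable rankings).  Each drug gets a number of
    replicate instances drawn uniformly from ``cfg.instances_per_drug``.

    Replicates of one drug share a drug-specific latent expression vector
    (uniform on [-1/2, 1/2) per gene) on top of which the planted signature
    shift (+/- 1) and per-instance jitter (``noise_sd``) act.  The bounded
    base keeps the noiseless planting exact — every up-gene of a reverser
    ranks below every non-signature gene — while giving replicate instances
    realistic genome-wide agreement for the robustness filter to assess.
    """
    genes = cfg.gene_universe
    idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in sig.up + sig.down if g not in idx]
    if missing:
        raise ValueError(f"signature genes outside universe: {missing[:5]}")
    up_idx = np.array([idx[g] for g in sig.up], dtype=int)
    dn_idx = np.array([idx[g] for g in sig.down], dtype=int)

    rng = cfg.rng("drug_profiles")
    lo, hi = cfg.instances_per_drug
    n_inst_per_drug = rng.integers(lo, hi + 1, size=cfg.n_drugs)

    cols, meta_rows = {}, []
    width = max(3, len(str(cfg.n_drugs)))
    for d in range(cfg.n_drugs):
        drug_id = f"D{d + 1:0{width}d}"
        role = ("reverser" if d < cfg.n_planted_reversers else
                "mimic" if d < cfg.n_planted_reversers + cfg.n_planted_mimics
                else "background")
        base = rng.uniform(-0.5, 0.5, cfg.n_genes)    # shared by replicates
        for k in range(int(n_inst_per_drug[d])):
            inst_id = f"{drug_id}_i{k + 1}"
            latent = base + cfg.noise_sd * rng.normal(0.0, 1.0, cfg.n_genes)
            if role == "reverser":
                latent[up_idx] -= 1.0   # drug suppresses disease up-genes
                latent[dn_idx] += 1.0
            elif role == "mimic":
                latent[up_idx] += 1.0
                latent[dn_idx] -= 1.0
            # rank 1 = most up-regulated; random tie-break keeps columns
            # honest permutations even in the noiseless degenerate case
            order = np.lexsort((rng.random(cfg.n_genes), -latent))
            ranks = np.empty(cfg.n_genes, dtype=int)
            ranks[order] = np.arange(1, cfg.n_genes + 1)
            cols[inst_id] = ranks
            meta_rows.append({"instance_id": inst_id, "drug_id": drug_id,
                              "experiment": f"exp{k + 1}", "role": role})
    ranks = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(meta_rows)
    return DrugProfileDB(ranks, meta)


def gen_responder_matrix(cfg: SynConfig) -> tuple[pd.DataFrame, pd.Series, GeneSignature]:
    """Expression matrix with genes shifted between two response groups.

    Returns (genes x samples matrix, sample->group labels, planted truth as
    a GeneSignature: 'up' = higher in non-responders).  With
    ``group_effect_sd=0`` the planted signature is empty.
    """
    if cfg.n_per_group < 3:
        raise ValueError("need >= 3 samples per group (rank test degenerate)")
    rng = cfg.rng("responder")
    genes = cfg.gene_universe
    samples = ([f"R{i + 1}" for i in range(cfg.n_per_group)]
               + [f"NR{i + 1}" for i in range(cfg.n_per_group)])
    mat = rng.normal(0.0, 1.0, (cfg.n_genes, 2 * cfg.n_per_group))
    up_planted: list[str] = []
    dn_planted: list[str] = []
    if cfg.group_effect_sd > 0:
        picked = rng.choice(cfg.n_genes, size=cfg.n_diff_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_diff_genes)
        nr = slice(cfg.n_per_group, 2 * cfg.n_per_group)
        for i, s in zip(picked, signs):
            mat[i, nr] += s * cfg.group_effect_sd
            (up_planted if s > 0 else dn_planted).append(genes[i])
    expr = pd.DataFrame(mat, index=genes, columns=samples)
    labels = pd.Series(["responder"] * cfg.n_per_group
                       + ["non_responder"] * cfg.n_per_group, index=samples)
    truth = GeneSignature(up_planted, dn_planted, label="resistance_truth")
    return expr, labels, truth


# ---------------------------------------------------------------------------
# Plates


def gen_plate(cfg: SynConfig, potency_map: dict[str, float],
              plate_id: str = "P1", cell_line: str = "A673",
              concentration: float = 1.0) -> pd.DataFrame:
    """One 384-well plate of luminescence signals.

    ``potency_map`` gives fraction inhibition at the screening concentration
    per compound.  Vehicle (negative control, inhibition 0) and kill
    (positive control, inhibition 1) wells fill the first
    ``2 * n_control_wells`` wells; compounds follow.  Signal model:
    ``vehicle_mean * (1 - inhibition) * (1 + cv * N(0,1))``, floored at 0 —
    multiplicative noise because luminescence noise scales with signal.
    """
    bad = {c: f for c, f in potency_map.items() if not 0 <= f <= 1}
    if bad:
        raise ValueError(f"potency values outside [0,1]: {bad}")
    n_wells = cfg.plate_rows * cfg.plate_cols
    if 2 * cfg.n_control_wells + len(potency_map) > n_wells:
        raise ValueError("plate cannot hold controls plus all compounds")
    if cfg.plate_noise_cv >= 1 / 3:
        import warnings
        warnings.warn("plate noise this large makes expected Z' negative",
                      stacklevel=2)
    rng = cfg.rng("plate", plate_id, cell_line)
    wells = [(r, c) for c in range(1, cfg.plate_cols + 1)
             for r in range(cfg.plate_rows)]
    records = []
    layout = ([("vehicle", "DMSO", 0.0)] * cfg.n_control_wells
              + [("positive_control", "KILL", 1.0)] * cfg.n_control_wells
              + [("sample", comp, float(f)) for comp, f in potency_map.items()])
    for (row, col), (wtype, comp, inhib) in zip(wells, layout):
        noise = cfg.plate_noise_cv * rng.standard_normal()
        signal = max(0.0, cfg.vehicle_mean * (1.0 - inhib) * (1.0 + noise))
        records.append({
            "plate_id": plate_id, "well": f"{chr(ord('A') + row)}{col:02d}",
            "row": chr(ord("A") + row), "col": col, "well_type": wtype,
            "compound_id": comp, "conc_umol_l": concentration,
            "signal": signal, "cell_line": cell_line})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Dose-response and dose matrices


def twofold_doses(top: float = 1000.0, n: int = 8) -> np.ndarray:
    """``n`` serial two-fold dilutions from ``top`` downward (nmol/L).

    Default grid 7.8125..1000 nmol/L matches an 8-step dilution series
    from 1 umol/L.
    """
    return top / (2.0 ** np.arange(n - 1, -1, -1))


def _median_effect_fa(dose: np.ndarray, dm: float, m: float) -> np.ndarray:
    """fa = 1 / (1 + (Dm/D)^m); fa(0) = 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(dose > 0, 1.0 / (1.0 + (dm / np.maximum(dose, 1e-300)) ** m), 0.0)
    return out


def gen_dose_response(dm: float, m: float, doses, noise_sd: float = 0.0,
                      seed: int = 0, replicates: int = 1,
                      compound_id: str = "DRUG", cell_line: str = "A673") -> pd.DataFrame:
    """Fraction-affected table from the median-effect model.

    Columns: compound_id, cell_line, replicate, conc_umol_l,
    fraction_affected.  Gaussian noise of scale ``noise_sd`` is added on the
    fa scale and clipped to [-0.2, 1].
    """
    if dm <= 0 or m <= 0:
        raise ValueError("Dm and m must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        fa = _median_effect_fa(doses, dm, m)
        if noise_sd > 0:
            fa = np.clip(fa + rng.normal(0, noise_sd, fa.shape), -0.2, 1.0)
        for d, f in zip(doses, fa):
            rows.append({"compound_id": compound_id, "cell_line": cell_line,
                         "replicate": rep, "conc_umol_l": d,
                         "fraction_affected": float(f)})
    return pd.DataFrame(rows)


def gen_dose_matrix(dm1: float, m1: float, dm2: float, m2: float,
                    doses1=None, doses2=None, alpha: float = 1.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    drug1: str = "auranofin", drug2: str = "ganetespib") -> pd.DataFrame:
    """9x9 combination block (8 two-fold dilutions per drug + zero row/col).

    Single-agent axes follow the median-effect model.  Interior cells follow
    a Loewe-type interaction: the observed fa solves
    ``d1/Dx1(fa) + d2/Dx2(fa) = alpha`` with ``Dx_i = Dm_i (fa/(1-fa))^{1/m_i}``,
    so the downstream combination index recovers ``alpha`` exactly at zero
    noise (alpha < 1 plants synergy, alpha > 1 antagonism, alpha = 1 Loewe
    additivity).  Doses in the emitted table are nmol/L.
    """
    if min(dm1, m1, dm2, m2) <= 0:
        raise ValueError("Dm and m must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d1 = np.concatenate([[0.0], twofold_doses()]) if doses1 is None else np.asarray(doses1, float)
    d2 = np.concatenate([[0.0], twofold_doses()]) if doses2 is None else np.asarray(doses2, float)
    rng = np.random.default_rng(seed)
    # fits below work in umol/L; the dose grid here is nmol/L
    dm1_n, dm2_n = dm1 * 1000.0, dm2 * 1000.0
    rows = []
    for a in d1:
        for b in d2:
            if a == 0 and b == 0:
                fa = 0.0
            elif b == 0:
                fa = float(_median_effect_fa(np.array([a]), dm1_n, m1)[0])
            elif a == 0:
                fa = float(_median_effect_fa(np.array([b]), dm2_n, m2)[0])
            else:
                fa = _loewe_fa(a, b, dm1_n, m1, dm2_n, m2, alpha)
            if noise_sd > 0:
                fa = float(np.clip(fa + rng.normal(0, noise_sd), -0.2, 1.0))
            rows.append({"drug1": drug1, "drug2": drug2,
                         "dose1_nmol_l": float(a), "dose2_nmol_l": float(b),
                         "replicate": 1, "percent_inhibition": 100.0 * fa})
    return pd.DataFrame(rows)


def _loewe_fa(d1: float, d2: float, dm1: float, m1: float,
              dm2: float, m2: float, alpha: float) -> float:
    """Effect level where the interaction sum equals alpha."""
    if m1 == m2:
        r = ((d1 / dm1 + d2 / dm2) / alpha) ** m1
        return r / (1.0 + r)

    def gap(log_r: float) -> float:
        r = math.exp(log_r)
        return d1 / (dm1 * r ** (1 / m1)) + d2 / (dm2 * r ** (1 / m2)) - alpha

    return 1.0 / (1.0 + math.exp(-brentq(gap, -60.0, 60.0, xtol=1e-12)))


# ---------------------------------------------------------------------------
# Pharmacokinetics and survival


def gen_pk_profile(cfg: SynConfig, times=None, noise_cv: float = 0.0,
                   seed: int | None = None) -> pd.DataFrame:
    """One-compartment, first-order-absorption concentration-time table.

    ``C(t) = (F*Dose*ka) / (V*(ka-ke)) * (exp(-ke t) - exp(-ka t))`` with
    F*Dose in ug/kg and V/F in mL/kg, so C is ug/mL.  ``ka == ke`` (the
    flip-flop degenerate case) is rejected.
    """
    ka, ke = cfg.pk_ka, cfg.pk_ke
    if ka == ke:
        raise ValueError("ka == ke is degenerate for this closed form")
    t = np.asarray(PAPER_PK_TIMES_HR if times is None else times, dtype=float)
    conc = (cfg.pk_dose_ug_per_kg * ka) / (cfg.pk_v_f * (ka - ke)) * (
        np.exp(-ke * t) - np.exp(-ka * t))
    conc = np.maximum(conc, 0.0)
    if noise_cv > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        conc = np.maximum(conc * (1 + noise_cv * rng.standard_normal(len(t))), 0.0)
    return pd.DataFrame({"time_hr": t, "conc_ug_per_ml": conc})


def gen_pk_profile_multidose(cfg: SynConfig, n_doses: int = 5,
                             interval_hr: float = 24.0,
                             times=None) -> pd.DataFrame:
    """Repeat-dose profile by superposition of single-dose curves."""
    if times is None:
        times = np.arange(0.0, interval_hr * (n_doses + 5) + 1e-9, interval_hr)
    t = np.asarray(times, dtype=float)
    ka, ke = cfg.pk_ka, cfg.pk_ke
    if ka == ke:
        raise ValueError("ka == ke is degenerate for this closed form")
    scale = (cfg.pk_dose_ug_per_kg * ka) / (cfg.pk_v_f * (ka - ke))
    conc = np.zeros_like(t)
    for k in range(n_doses):
        dt = t - k * interval_hr
        mask = dt > 0
        conc[mask] += scale * (np.exp(-ke * dt[mask]) - np.exp(-ka * dt[mask]))
    return pd.DataFrame({"time_hr": t, "conc_ug_per_ml": np.maximum(conc, 0.0)})


def gen_survival(cfg: SynConfig) -> pd.DataFrame:
    """Exponential event times per arm with administrative censoring.

    Columns: subject, group, time_days, event (1 = death/sacrifice,
    0 = censored at ``censor_day``).
    """
    rng = cfg.rng("survival")
    rows = []
    for arm, hazard in cfg.arm_hazards.items():
        if hazard < 0:
            raise ValueError("hazards must be nonnegative")
        for i in range(cfg.n_per_arm):
            t = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
            event = int(t <= cfg.censor_day)
            rows.append({"subject": f"{arm}_{i + 1}", "group": arm,
                         "time_days": float(min(t, cfg.censor_day)),
                         "event": event})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle writer (files in the dialects the analysis modules read)


def write_bundle(cfg: SynConfig, out_dir) -> dict[str, str]:
    """Generate and write every synthetic input; returns name -> path."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    sig = gen_signature(cfg, "disease")
    sig.to_tsv(out / "disease_signature.tsv")
    paths["disease_signature"] = str(out / "disease_signature.tsv")

    sirna = gen_signature(cfg, "sirna")
    sirna.to_tsv(out / "sirna_signature.tsv")
    paths["sirna_signature"] = str(out / "sirna_signature.tsv")

    db = gen_drug_profiles(cfg, sig)
    db.to_tsv(out / "rank_matrix.tsv", out / "instance_map.tsv")
    paths["rank_matrix"] = str(out / "rank_matrix.tsv")
    paths["instance_map"] = str(out / "instance_map.tsv")

    expr, labels, _ = gen_responder_matrix(cfg)
    expr.insert(0, "gene", expr.index)
    expr.to_csv(out / "responder_matrix.tsv", sep="\t", index=False)
    labels.rename("group").rename_axis("sample").to_frame().to_csv(
        out / "responder_groups.tsv", sep="\t")
    paths["responder_matrix"] = str(out / "responder_matrix.tsv")
    paths["responder_groups"] = str(out / "responder_groups.tsv")

    pk = gen_pk_profile(cfg)
    pk.to_csv(out / "pk_profile.csv", index=False)
    paths["pk_profile"] = str(out / "pk_profile.csv")

    surv = gen_survival(cfg)
    surv.to_csv(out / "survival.csv", index=False)
    paths["survival"] = str(out / "survival.csv")
    return paths
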