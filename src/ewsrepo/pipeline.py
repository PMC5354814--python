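"""End-to-end orchestration and the survival-comparison stage.

``run_all`` chains every stage on a synthetic study bundle: signature
construction -> connectivity scoring for the three approaches (disease
reversal, fusion-silencing mimicry, resistance reversal) -> hit merge ->
primary screen hit calling with counter-screen and blacklist filters ->
dose-response fits on nominated drugs -> combination-index synergy on a
configured pair -> gold NCA -> four-arm survival comparison.  Outputs are
a pure function of (config, seed): one TSV per stage plus a JSON manifest
recording parameters, package version, seed, and file hashes.

The survival stage implements the Kaplan-Meier product-limit estimator
``S(t) = prod_{t_i <= t} (1 - d_i/n_i)`` and the two-sample log-rank test
(1-df chi-square over shared risk sets) directly; both are elementary and
keeping them in-package lets an external survival library act purely as a
cross-check.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity, doseresponse, pk, screen, signatures, syndata

logger = logging.getLogger("ewsrepo")

__all__ = ["RunConfig", "run_all", "km_estimate", "logrank"]


# ---------------------------------------------------------------------------
# Survival


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve for one arm.

    Returns a step table with columns time, n_at_risk, n_events,
    survival; S(0) = 1, non-increasing, right-continuous.  Censored
    subjects leave the risk set without stepping the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [{"time": 0.0, "n_at_risk": t.size, "n_events": 0, "survival": 1.0}]
    surv = 1.0
    for ti in np.unique(t[e == 1]):
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        surv *= 1.0 - d_i / n_i
        rows.append({"time": float(ti), "n_at_risk": n_i, "n_events": d_i,
                     "survival": surv})
    return pd.DataFrame(rows)


def logrank(table: pd.DataFrame, arm_a: str, arm_b: str,
            time_col: str = "time_days", event_col: str = "event",
            group_col: str = "group") -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value).

    Observed-minus-expected events in arm A accumulated over the shared
    risk sets at each distinct event time, with the hypergeometric
    variance.  Symmetric in the arm labels; identical arms give statistic
    0 and p = 1.
    """
    sub = table[table[group_col].isin([arm_a, arm_b])]
    t = sub[time_col].to_numpy(float)
    e = sub[event_col].to_numpy(int)
    in_a = (sub[group_col] == arm_a).to_numpy()
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n_i = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        died = (t == ti) & (e == 1)
        d_i = int(died.sum())
        d_a = int((died & in_a).sum())
        o_minus_e += d_a - d_i * n_a / n_i
        if n_i > 1:
            var += d_i * (n_a / n_i) * (1 - n_a / n_i) * (n_i - d_i) / (n_i - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything run_all needs; serialized alongside the outputs.

    When an input path is None the corresponding synthetic generator
    supplies the data (the default, fully self-contained mode).  Paths that
    are set must exist before execution.
    """

    seed: int = 0
    out_dir: str = "ewsrepo_run"
    syn: syndata.SynConfig | None = None

    # optional external inputs (TSV/CSV dialects of the stage modules)
    disease_signature: str | None = None
    rank_matrix: str | None = None
    instance_map: str | None = None
    plate_csv: str | None = None
    pk_csv: str | None = None
    survival_csv: str | None = None

    # thresholds
    n_perm: int = 1000
    fdr_cut: float = 0.05
    top_k: int = 20
    hit_threshold_pct: float = 50.0
    min_corr: float = 0.3
    z_min: float = 0.5
    additive_band: tuple = (0.9, 1.1)
    synergy_alpha: float = 0.5           # planted interaction for the pair
    exclusion: list = field(default_factory=list)
    blacklist: list = field(default_factory=lambda: list(screen.PRESCRIBED_EWS_DRUGS))

    def __post_init__(self) -> None:
        if self.syn is None:
            self.syn = syndata.SynConfig(seed=self.seed)
        for name in ("disease_signature", "rank_matrix", "instance_map",
                     "plate_csv", "pk_csv", "survival_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {name} missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn_raw = raw.pop("syn", None)
        cfg = cls(**raw)
        if syn_raw:
            cfg.syn = syndata.SynConfig(seed=raw.get("seed", 0), **syn_raw)
        return cfg


# ---------------------------------------------------------------------------
# Orchestration


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = cfg.syn
    manifest: dict = {"seed": cfg.seed, "parameters": _jsonable(asdict(cfg)),
                      "stages": {}, "files": {}}

    # -- stage 1: signatures -------------------------------------------------
    logger.info("stage signatures: constructing the three query signatures")
    if cfg.disease_signature:
        disease = signatures.GeneSignature.from_tsv(cfg.disease_signature, "disease")
    else:
        disease = syndata.gen_signature(syn, "disease")
    # silencing the driver fusion reverses the disease expression program,
    # so the mimicry query is the disease signature with directions swapped
    sirna = disease.swapped()
    sirna.label = "sirna"
    expr, groups, truth = syndata.gen_responder_matrix(syn)
    resistance = signatures.derive_resistance_signature(
        expr, groups, fdr_cut=cfg.fdr_cut, top_n=syn.signature_size)

    # -- stage 2: drug database + robustness ---------------------------------
    if cfg.rank_matrix and cfg.instance_map:
        db = signatures.DrugProfileDB.from_tsv(cfg.rank_matrix, cfg.instance_map)
    else:
        db = syndata.gen_drug_profiles(syn, disease)
    db, rob = signatures.robustness_filter(db, min_corr=cfg.min_corr)
    manifest["stages"]["robustness"] = {
        "dropped": rob.dropped["drug_id"].tolist(),
        "singletons": rob.singletons}

    # -- stage 3: connectivity, three approaches ------------------------------
    logger.info("stage connectivity: scoring %d instances x 3 approaches",
                db.n_instances)
    if "role" in db.instance_meta.columns:
        planted = db.instance_meta.loc[db.instance_meta["role"] == "reverser",
                                       "drug_id"].unique().tolist()
    else:
        planted = []
    approaches = [("disease", disease, "negative_tail"),
                  ("sirna", sirna, "positive_tail"),
                  ("resistance", resistance, "negative_tail")]
    hitlists = []
    for name, sig, direction in approaches:
        if sig.is_empty() or not sig.up or not sig.down:
            logger.warning("approach %s skipped: signature empty", name)
            continue
        res = connectivity.score_database(sig, db, n_perm=cfg.n_perm,
                                          seed=cfg.seed, approach=name)
        _write(res.drop(columns=["instance_scores"]),
               out / f"connectivity_{name}.tsv")
        hitlists.append(connectivity.select_hits(
            res, name, direction, k=cfg.top_k, fdr_cut=cfg.fdr_cut))
    merged = connectivity.merge_hits(hitlists, exclusion=cfg.exclusion)
    _write(merged, out / "merged_hits.tsv")
    manifest["stages"]["connectivity"] = {
        "planted_reversers": planted,
        "merged_drugs": merged["drug_id"].tolist(),
        "excluded": merged.attrs.get("excluded_drugs", [])}

    # -- stage 4: primary screen ----------------------------------------------
    logger.info("stage screen: plating, QC, hit calling")
    if cfg.plate_csv:
        plates = pd.read_csv(cfg.plate_csv)
    else:
        plates = _synthetic_screen_plates(syn, planted, merged["drug_id"])
    qc = screen.qc_plates(plates, cfg.z_min)
    inh = screen.plate_inhibition(plates, cfg.z_min)
    calls = screen.call_hits(inh, threshold=cfg.hit_threshold_pct,
                             blacklist=cfg.blacklist)
    _write(qc, out / "plate_qc.tsv")
    _write(calls, out / "hit_calls.tsv")
    nominated = calls.loc[calls["nominated"], "compound_id"].tolist()
    manifest["stages"]["screen"] = {
        "plates_passed": int(qc["passed"].sum()), "plates": len(qc),
        "nominated": nominated}

    # -- stage 5: dose-response + synergy --------------------------------------
    logger.info("stage doseresponse: fits on %d nominated drugs", len(nominated))
    doses = np.geomspace(0.001, 50.0, 12)   # 12-point grid, 1 nmol/L..50 umol/L
    fit_rows = []
    rng = np.random.default_rng(cfg.seed + 17)
    for comp in nominated:
        dm = float(rng.uniform(0.05, 2.0))
        m = float(rng.uniform(0.8, 2.5))
        table = syndata.gen_dose_response(dm, m, doses, compound_id=comp)
        fit = doseresponse.fit_median_effect(
            table["conc_umol_l"], table["fraction_affected"], comp)
        fit_rows.append({"compound_id": comp, "dm_true": dm, "m_true": m,
                         "ic50": fit.ic50_display, "m": fit.m,
                         "censored": fit.ic50_censored})
    _write(pd.DataFrame(fit_rows), out / "dose_response_fits.tsv")

    fit1 = doseresponse.fit_median_effect(
        doses, syndata.gen_dose_response(0.3, 1.5, doses)["fraction_affected"],
        "auranofin")
    fit2 = doseresponse.fit_median_effect(
        doses, syndata.gen_dose_response(0.05, 1.5, doses)["fraction_affected"],
        "ganetespib")
    matrix = syndata.gen_dose_matrix(0.3, 1.5, 0.05, 1.5, alpha=cfg.synergy_alpha,
                                     seed=cfg.seed)
    ci = doseresponse.combination_index_table(matrix, fit1, fit2,
                                              cfg.additive_band)
    _write(ci, out / "combination_index.tsv")
    interior = ci[np.isfinite(ci["ci"])]
    manifest["stages"]["synergy"] = {
        "median_ci": float(interior["ci"].median()),
        "class_counts": interior["ci_class"].value_counts().to_dict()}

    # -- stage 6: pharmacokinetics ---------------------------------------------
    logger.info("stage pk: NCA on the blood-gold profile")
    if cfg.pk_csv:
        profile = pk.ConcTimeProfile.from_csv(cfg.pk_csv)
    else:
        t = syndata.gen_pk_profile(syn)
        profile = pk.ConcTimeProfile(t["time_hr"], t["conc_ug_per_ml"])
    result = pk.nca(profile)
    result.to_series().rename_axis("parameter").rename("value").to_frame() \
        .to_csv(out / "nca.tsv", sep="\t")
    multi = syndata.gen_pk_profile_multidose(syn)
    trough = pk.trough_summary(multi, single=profile)
    manifest["stages"]["pk"] = {
        "t_half_hr": result.t_half_hr, "cl_f_ml_hr_kg": result.cl_f_ml_hr_kg,
        "accumulation_ratio": trough.get("accumulation_ratio")}

    # -- stage 7: survival -------------------------------------------------------
    logger.info("stage survival: KM + pairwise log-rank")
    if cfg.survival_csv:
        surv = pd.read_csv(cfg.survival_csv)
    else:
        surv = syndata.gen_survival(syn)
    km_rows = []
    for arm, grp in surv.groupby("group"):
        km = km_estimate(grp["time_days"], grp["event"])
        km.insert(0, "group", arm)
        km_rows.append(km)
    _write(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
    lr_rows = []
    arms = sorted(surv["group"].unique())
    ref = "vehicle" if "vehicle" in arms else arms[0]
    for arm in arms:
        if arm == ref:
            continue
        stat, p = logrank(surv, arm, ref)
        lr_rows.append({"arm": arm, "reference": ref, "chi2": stat,
                        "p_value": p, "significant": p < 0.05})
    _write(pd.DataFrame(lr_rows), out / "logrank.tsv")
    manifest["stages"]["survival"] = {
        r["arm"]: {"p": r["p_value"], "significant": bool(r["significant"])}
        for r in lr_rows}

    # -- manifest -----------------------------------------------------------------
    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    from . import __version__
    manifest["version"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _synthetic_screen_plates(syn: syndata.SynConfig, planted: list[str],
                             all_drugs) -> pd.DataFrame:
    """One plate per cell line; planted drugs potent on tumor lines only."""
    lines = [("A673", True), ("SK-ES-1", True), ("RD-ES", True),
             ("Hs 919.T", False)]
    rng = syn.rng("screen_potency")
    frames = []
    drugs = list(all_drugs)
    for i, (line, is_ews) in enumerate(lines):
        pot = {}
        for d in drugs:
            if d in planted and is_ews:
                pot[d] = float(rng.uniform(0.85, 1.0))
            else:
                pot[d] = float(rng.uniform(0.0, 0.3))
        frames.append(syndata.gen_plate(syn, pot, plate_id=f"P{i + 1}",
                                        cell_line=line))
    return pd.concat(frames, ignore_index=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
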