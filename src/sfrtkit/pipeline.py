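"""End-to-end orchestration: simulate/load -> fit -> delays -> PFS -> qPCR -> dose.

``run_pipeline`` drives the whole analysis from a single RunConfig and emits
a machine-readable StudyReport (JSON) plus tidy CSV tables.  The run is
deterministic given the config and seed; provenance (config hash, seed,
package version) is embedded in the report.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import (
    ArmSpec,
    StudyDesign,
    generate_cohort,
    REFERENCE_KINETICS,
)
from .dose import (
    A549_LQ,
    BeamGeometry,
    LQParams,
    build_ideal_profile,
    count_beams,
    eud,
    profile_pvdr,
    solve_peak_for_eud,
)
from .endpoints import (
    build_pfs_dataset,
    growth_delay,
    km_estimate,
    logrank_test,
)
from .io import read_measurements_csv, write_measurements_csv, write_pfs_csv
from .qpcr import fold_change, read_ct_csv
from .regrowth import (
    InsufficientDataError,
    MouseRecord,
    RegrowthParams,
    fit_regrowth,
    fit_regrowth_pooled,
    tripling_time,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("sfrtkit")

CONTROL_ARM = "control"


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``measurements_csv`` (real data) or ``simulate`` (a
    simulation design block) must be provided; ``seed`` is required when
    simulating.
    """

    measurements_csv: str | None = None
    ct_csv: str | None = None
    simulate: dict | None = None
    seed: int | None = None
    fit_scope: str = "mouse"  # "mouse" | "group"
    tripling_method: str = "raw"  # "raw" | "model"
    followup_cap: float = 90.0
    endpoint_multiple: float = 3.0
    control_group: str = CONTROL_ARM
    strata: dict | None = None
    holm_correction: bool = False
    reference_genes: tuple = ("GAPDH", "B2M", "ACTB")
    dose: dict | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.measurements_csv is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of measurements_csv or simulate must be given"
            )
        if self.simulate is not None and self.seed is None:
            raise ValueError("seed is required when simulating")
        if self.fit_scope not in ("mouse", "group"):
            raise ValueError("fit_scope must be 'mouse' or 'group'")
        if self.tripling_method not in ("raw", "model"):
            raise ValueError("tripling_method must be 'raw' or 'model'")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (identical schema)."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig(**data)


def _design_from_block(block: dict, seed: int) -> StudyDesign:
    arms = []
    for arm_block in block["arms"]:
        name = arm_block["arm"]
        if "params" in arm_block:
            p = arm_block["params"]
            params = RegrowthParams.from_free(p["a1"], p["alpha1"], p["alpha2"])
        else:
            params = REFERENCE_KINETICS[name]
        arms.append(
            ArmSpec(
                arm=name,
                true_params=params,
                n=int(arm_block.get("n", 9)),
                noise_cv=float(arm_block.get("noise_cv", 0.15)),
                enrollment_volume_range=tuple(
                    arm_block.get("enrollment_volume_range", (60.0, 100.0))
                ),
            )
        )
    return StudyDesign(
        arms=tuple(arms),
        seed=seed,
        followup_cap=float(block.get("followup_cap", 90.0)),
        endpoint_multiple=float(block.get("endpoint_multiple", 3.0)),
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dose_summary(block: dict) -> dict:
    geom = BeamGeometry(
        beam_width_um=float(block["beam_width_um"]),
        ctc_um=float(block["ctc_um"]),
        field_mm=float(block["field_mm"]),
        modality=str(block.get("modality", "")),
    )
    lq = LQParams(float(block.get("alpha", A549_LQ.alpha)),
                  float(block.get("beta", A549_LQ.beta)))
    pvdr = float(block["pvdr"])
    out = {
        "modality": geom.modality,
        "n_beams": count_beams(geom),
        "pvdr": pvdr,
        "alpha": lq.alpha,
        "beta": lq.beta,
    }
    if "peak_gy" in block:
        peak = float(block["peak_gy"])
        profile = build_ideal_profile(geom, peak, pvdr)
        out.update(
            peak_gy=peak,
            valley_gy=peak / pvdr,
            profile_pvdr=profile_pvdr(profile),
            eud_gy=eud(profile, lq),
        )
    if "target_eud_gy" in block:
        target = float(block["target_eud_gy"])
        solved = solve_peak_for_eud(geom, pvdr, lq, target)
        out.update(target_eud_gy=target, solved_peak_gy=solved,
                   solved_valley_gy=solved / pvdr)
    return out


def _fit_all(records: list[MouseRecord], scope: str) -> dict:
    """Per-mouse fits always; per-group pooled fits when scope='group'."""
    fits = {}
    for rec in records:
        try:
            fits[rec.mouse_id] = fit_regrowth(rec)
        except InsufficientDataError as exc:
            log.warning("fit skipped: %s", exc)
            fits[rec.mouse_id] = None
    pooled = {}
    if scope == "group":
        arms = sorted({r.arm for r in records})
        for arm in arms:
            arm_recs = [r for r in records if r.arm == arm]
            try:
                pooled[arm] = fit_regrowth_pooled(arm_recs)
            except InsufficientDataError as exc:
                log.warning("pooled fit skipped for %s: %s", arm, exc)
                pooled[arm] = None
    return {"per_mouse": fits, "pooled": pooled}


def _holm(pairs: list[tuple[tuple, float]]) -> dict:
    ordered = sorted(pairs, key=lambda kv: kv[1])
    m = len(ordered)
    adj = {}
    running = 0.0
    for i, (key, p) in enumerate(ordered):
        running = max(running, min(1.0, (m - i) * p))
        adj[key] = running
    return adj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config enables and return the StudyReport dict."""
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        }
    }

    # --- input stage -----------------------------------------------------
    if config.simulate is not None:
        design = _design_from_block(config.simulate, config.seed)
        records = generate_cohort(design)
        log.info("simulated %d animals in %d arms", len(records),
                 len(design.arms))
    else:
        records = read_measurements_csv(
            config.measurements_csv,
            endpoint_multiple=config.endpoint_multiple,
            followup_cap=config.followup_cap,
        )
        log.info("loaded %d animals from %s", len(records),
                 config.measurements_csv)

    arms = sorted({r.arm for r in records})

    # --- fitting ---------------------------------------------------------
    fits = _fit_all(records, config.fit_scope)
    report["fits"] = {
        mid: (
            None
            if f is None
            else {
                "a1": f.params.a1,
                "a2": f.params.a2,
                "alpha1": f.params.alpha1,
                "alpha2": f.params.alpha2,
                "sse": f.sse,
                "t_min": f.t_min,
                "regrowth_start_day": f.regrowth_start_day,
                "n_points": f.n_points,
            }
        )
        for mid, f in fits["per_mouse"].items()
    }

    # --- growth times and delays ----------------------------------------
    growth_times: dict[str, list[float]] = {a: [] for a in arms}
    censored: dict[str, int] = {a: 0 for a in arms}
    for rec in records:
        if config.tripling_method == "model":
            f = fits["per_mouse"].get(rec.mouse_id)
            gt = None if f is None else tripling_time(
                None, method="model", fit=f, multiple=config.endpoint_multiple
            )
        else:
            gt = tripling_time(rec, method="raw",
                               multiple=config.endpoint_multiple)
        if gt is None or gt > config.followup_cap:
            censored[rec.arm] += 1
        else:
            growth_times[rec.arm].append(gt)

    report["growth_times"] = {
        a: {"times": growth_times[a], "n_censored": censored[a]} for a in arms
    }

    delays = {}
    ctrl = config.control_group
    if ctrl in arms and growth_times[ctrl]:
        for arm in arms:
            if arm == ctrl or not growth_times[arm]:
                continue
            res = growth_delay(growth_times[arm], growth_times[ctrl],
                               arm=arm, n_censored=censored[arm])
            delays[arm] = {
                "mean_delay": res.mean_delay,
                "sd": res.sd,
                "ci95_halfwidth": res.ci95_halfwidth,
                "p_vs_control": res.p_vs_control,
                "p_delay_vs_zero": res.p_delay_vs_zero,
                "n": res.n,
                "n_censored": res.n_censored,
            }
        ctrl_times = np.array(growth_times[ctrl])
        delays[ctrl] = {
            "mean_growth_time": float(ctrl_times.mean()),
            "sd": float(ctrl_times.std(ddof=1)) if ctrl_times.size > 1 else 0.0,
            "n": int(ctrl_times.size),
            "n_censored": censored[ctrl],
        }
    report["delays"] = delays

    # --- PFS -------------------------------------------------------------
    fit_list = [fits["per_mouse"].get(r.mouse_id) for r in records]
    pfs = build_pfs_dataset(records, fit_list, config.followup_cap)
    report["pfs_records"] = [
        {"mouse_id": r.mouse_id, "arm": r.arm, "time_days": r.time,
         "event": r.event}
        for r in pfs
    ]
    km = {}
    for arm in arms:
        arm_recs = [r for r in pfs if r.arm == arm]
        if not arm_recs:
            continue
        curve = km_estimate(arm_recs)
        km[arm] = {
            "times": curve.times.tolist(),
            "survival": curve.survival.tolist(),
            "at_risk": curve.at_risk.tolist(),
            "median": curve.median,
        }
    report["km"] = km

    logrank = {}
    raw_ps = []
    treated_arms = [a for a in arms if a != ctrl]
    for a, b in itertools.combinations(treated_arms, 2):
        ra = [r for r in pfs if r.arm == a]
        rb = [r for r in pfs if r.arm == b]
        try:
            res = logrank_test(ra, rb, strata=config.strata)
        except ValueError as exc:
            log.warning("log-rank %s vs %s skipped: %s", a, b, exc)
            continue
        logrank[f"{a} vs {b}"] = {"chi2": res.chi2, "p": res.p}
        raw_ps.append(((a, b), res.p))
    if config.holm_correction and raw_ps:
        adj = _holm(raw_ps)
        for (a, b), _ in raw_ps:
            logrank[f"{a} vs {b}"]["p_holm"] = adj[(a, b)]
    report["logrank"] = logrank

    # --- qPCR ------------------------------------------------------------
    if config.ct_csv is not None:
        table = read_ct_csv(config.ct_csv, reference_genes=config.reference_genes)
        folds = fold_change(table, config.control_group)
        report["qpcr"] = [
            {"gene": f.gene, "group": f.group, "mean_fold": f.mean_fold,
             "sd_fold": f.sd_fold, "n": f.n}
            for f in folds
        ]

    # --- dose ------------------------------------------------------------
    if config.dose is not None:
        blocks = config.dose if isinstance(config.dose, list) else [config.dose]
        report["dose"] = [_dose_summary(b) for b in blocks]

    # --- outputs ---------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))
        write_measurements_csv(records, out / "measurements.csv")
        write_pfs_csv(pfs, out / "pfs.csv")
        log.info("report written to %s", out / "report.json")

    return report
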