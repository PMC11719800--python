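"""Seed-reproducible synthetic cohorts emulating the study's measurement design.

Each arm of animals carries known bi-exponential regrowth kinetics; tumors
are enrolled at 60-100 mm^3, measured three times a week (Mon/Wed/Fri
pattern: day offsets {0, 2, 4} modulo 7 from irradiation), perturbed by
multiplicative lognormal caliper noise, euthanized the first measurement day
the observed volume reaches 3x the irradiation volume V0, and censored at a
90-day follow-up cap.  Euthanasia is triggered by the observed (noisy)
volume, mirroring real caliper-triggered endpoints and the selection effect
they induce on growth-time estimates.

Per-animal random substreams are keyed by (seed, arm label, animal index),
so cohorts are stable under arm reordering.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .regrowth import GrowthMeasurement, MouseRecord, RegrowthParams, eval_regrowth

__all__ = [
    "ArmSpec",
    "StudyDesign",
    "generate_cohort",
    "generate_ct_table",
    "measurement_schedule",
    "reference_design",
    "REFERENCE_KINETICS",
]

# Arm kinetics used as the package's reference study conditions: a control
# arm tripling in 33 days (pure exponential) and three treated arms whose
# regrowth rates put the model-based tripling at 33 + {11.1, 20.2, 34.9}
# days with a 60% killed fraction shrinking at 0.15/day.
REFERENCE_KINETICS = {
    "control": RegrowthParams.pure_exponential(0.0332913),
    "CRT": RegrowthParams.from_free(0.6, 0.15, 0.045683),
    "MBRT": RegrowthParams.from_free(0.6, 0.15, 0.037873),
    "MRT": RegrowthParams.from_free(0.6, 0.15, 0.029674),
}


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: its size, true kinetics and noise level."""

    arm: str
    true_params: RegrowthParams
    n: int = 9
    noise_cv: float = 0.15
    enrollment_volume_range: tuple = (60.0, 100.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        lo, hi = self.enrollment_volume_range
        if not (0 < lo <= hi):
            raise ValueError("enrollment volume range must be positive, ordered")


@dataclass(frozen=True)
class StudyDesign:
    """Full cohort design: arms, schedule, follow-up and endpoint rules."""

    arms: tuple
    seed: int
    schedule_offsets: tuple = (0, 2, 4)
    followup_cap: float = 90.0
    endpoint_multiple: float = 3.0

    def __post_init__(self) -> None:
        if not self.endpoint_multiple > 1:
            raise ValueError("endpoint_multiple must exceed 1")
        if not self.followup_cap > 0:
            raise ValueError("followup_cap must be positive")
        object.__setattr__(self, "arms", tuple(self.arms))


def reference_design(seed: int, noise_cv: float = 0.15, n: int = 9) -> StudyDesign:
    """The four-arm, 9-mice-per-arm design with the reference kinetics."""
    arms = tuple(
        ArmSpec(arm=name, true_params=p, n=n, noise_cv=noise_cv)
        for name, p in REFERENCE_KINETICS.items()
    )
    return StudyDesign(arms=arms, seed=seed)


def measurement_schedule(followup_cap: float,
                         offsets=(0, 2, 4)) -> np.ndarray:
    """Post-irradiation measurement days: three times a week.

    Days t in (0, cap] with t mod 7 in ``offsets``; day 0 is the irradiation
    itself, so the first measurement falls on day 2 under the default
    Mon/Wed/Fri pattern.
    """
    days = np.arange(1, int(math.floor(followup_cap)) + 1)
    return days[np.isin(days % 7, np.asarray(offsets))].astype(float)


def _animal_rng(seed: int, arm: str, index: int) -> np.random.Generator:
    # stable per-animal substream: keyed on the arm label, not its position
    arm_key = zlib.crc32(arm.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(arm_key, index))
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def generate_cohort(design: StudyDesign) -> list[MouseRecord]:
    """Simulate every animal of the design; identical seeds give identical cohorts."""
    schedule = measurement_schedule(design.followup_cap, design.schedule_offsets)
    records: list[MouseRecord] = []
    for spec in design.arms:
        lo, hi = spec.enrollment_volume_range
        for i in range(spec.n):
            rng = _animal_rng(design.seed, spec.arm, i)
            v0 = float(rng.uniform(lo, hi))
            measurements: list[GrowthMeasurement] = []
            reached = False
            for day in schedule:
                true_v = v0 * eval_regrowth(spec.true_params, day)
                obs = true_v * _lognormal_factor(rng, spec.noise_cv)
                measurements.append(GrowthMeasurement(day=float(day),
                                                      volume_mm3=obs))
                if obs >= design.endpoint_multiple * v0:
                    reached = True
                    break
            records.append(
                MouseRecord(
                    mouse_id=f"{spec.arm}-{i + 1:02d}",
                    arm=spec.arm,
                    v0=v0,
                    measurements=measurements,
                    reached_endpoint=reached,
                    last_followup_day=(
                        measurements[-1].day if reached else design.followup_cap
                    ),
                    endpoint_multiple=design.endpoint_multiple,
                )
            )
    return records


def generate_ct_table(
    groups,
    true_folds: dict,
    n_per_group: int = 4,
    seed: int = 0,
    target_genes=("GPx1", "SOD1"),
    reference_genes=("GAPDH", "B2M", "ACTB"),
    ref_ct_mean: float = 20.0,
    ref_ct_sd: float = 0.3,
    target_ct_sd: float = 0.3,
    baseline_delta_ct: float = 5.0,
):
    """Synthesize a replicate-level Ct table with known expression folds.

    ``true_folds`` maps group -> fold (applied to every target gene) or
    group -> {gene: fold}; the control group's fold should be 1.  Reference
    Ct ~ Normal(ref_ct_mean, ref_ct_sd); a target's Ct is the sample's mean
    reference Ct plus a baseline dCt minus log2(true fold), plus
    Normal(0, target_ct_sd) measurement noise.
    """
    import pandas as pd

    from .qpcr import CtTable

    rows = []
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(0x9C7,)))
    for group in groups:
        folds = true_folds.get(group, 1.0)
        for rep in range(n_per_group):
            sample = f"{group}-s{rep + 1}"
            ref_cts = {
                g: float(rng.normal(ref_ct_mean, ref_ct_sd))
                for g in reference_genes
            }
            for g, ct in ref_cts.items():
                rows.append({"sample_id": sample, "group": group,
                             "gene": g, "ct": ct})
            ref_mean = float(np.mean(list(ref_cts.values())))
            for gene in target_genes:
                fold = folds[gene] if isinstance(folds, dict) else folds
                if not fold > 0:
                    raise ValueError("true folds must be positive")
                ct = (ref_mean + baseline_delta_ct - math.log2(fold)
                      + float(rng.normal(0.0, target_ct_sd)))
                rows.append({"sample_id": sample, "group": group,
                             "gene": gene, "ct": ct})
    return CtTable(pd.DataFrame(rows), reference_genes=reference_genes,
                   target_genes=tuple(target_genes))
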