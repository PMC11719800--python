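"""Idealized SFRT dose profiles and LQ-based equivalent uniform dose.

Spatially fractionated radiotherapy (SFRT) delivers dose through an array of
narrow planar beams, producing alternating high-dose "peak" and low-dose
"valley" regions.  This module models the lateral 1-D dose distribution of
such a field as an ideal top-hat profile, computes the peak-to-valley dose
ratio (PVDR) and beam count from the collimator geometry, and converts a
nonuniform profile into the equivalent uniform dose (EUD) — the uniform dose
producing the same mean clonogenic survival under the linear-quadratic (LQ)
model S(D) = exp(-alpha*D - beta*D^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "BeamGeometry",
    "DoseProfile",
    "LQParams",
    "build_ideal_profile",
    "count_beams",
    "profile_pvdr",
    "lq_survival",
    "eud",
    "solve_peak_for_eud",
    "read_profile_csv",
    "write_profile_csv",
]

#: Grid-regularity tolerance (relative) for DoseProfile positions.
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class BeamGeometry:
    """Multislit collimator geometry of an SFRT field.

    Parameters
    ----------
    beam_width_um : float
        Width of a single planar beam, in micrometers.
    ctc_um : float
        Center-to-center distance between adjacent beams, in micrometers.
    field_mm : float
        Lateral width of the treatment field, in millimeters.
    modality : str
        Free-text label, e.g. ``"MRT"`` (microbeam) or ``"MBRT"`` (minibeam).
    """

    beam_width_um: float
    ctc_um: float
    field_mm: float
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.beam_width_um > 0:
            raise ValueError("beam_width_um must be positive")
        if not self.ctc_um > self.beam_width_um:
            raise ValueError("ctc_um must exceed beam_width_um")
        if not self.field_mm > 0:
            raise ValueError("field_mm must be positive")
        if self.ctc_um > self.field_mm * 1000.0:
            raise ValueError("ctc_um must not exceed the field width")


# Reference geometries of the two collimators used throughout the package:
# 50 um beams at 400 um spacing (microbeam) and 500 um beams at 2000 um
# spacing (minibeam), both in a 10 x 10 mm^2 field.
MRT_GEOMETRY = BeamGeometry(50.0, 400.0, 10.0, "MRT")
MBRT_GEOMETRY = BeamGeometry(500.0, 2000.0, 10.0, "MBRT")


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic cell-survival parameters.

    ``alpha`` in 1/Gy, ``beta`` in 1/Gy^2.  The A549 (human NSCLC) values
    used for SFRT dose matching are alpha=0.4460, beta=0.0115.
    """

    alpha: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


#: LQ parameters of the A549 lung-adenocarcinoma line.
A549_LQ = LQParams(alpha=0.4460, beta=0.0115)


@dataclass(frozen=True)
class DoseProfile:
    """A sampled 1-D lateral dose distribution.

    ``positions_mm`` must be a strictly increasing regular grid; ``doses_gy``
    holds the dose at each position, all non-negative.
    """

    positions_mm: np.ndarray
    doses_gy: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        dose = np.asarray(self.doses_gy, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "doses_gy", dose)
        if pos.ndim != 1 or dose.ndim != 1 or pos.size != dose.size:
            raise ValueError("positions and doses must be 1-D of equal length")
        if pos.size < 1:
            raise ValueError("profile must contain at least one sample")
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        if pos.size > 1:
            steps = np.diff(pos)
            if np.any(steps <= 0):
                raise ValueError("positions must be strictly increasing")
            h = steps.mean()
            if np.any(np.abs(steps - h) > _GRID_RTOL * abs(h)):
                raise ValueError("positions must form a regular grid")

    def __len__(self) -> int:
        return int(self.positions_mm.size)


def count_beams(geometry: BeamGeometry) -> int:
    """Number of beam centers that fit in the field at the given spacing.

    Beams are placed on a grid of pitch ``ctc_um`` centered symmetrically in
    the field; the count is ``floor(field_width / ctc)``.  The reference
    microbeam collimator (400 um CTC, 10 mm field) yields 25 beams, the
    minibeam collimator (2000 um CTC) yields 5.
    """
    return int(math.floor(geometry.field_mm * 1000.0 / geometry.ctc_um + 1e-9))


def _beam_centers_um(geometry: BeamGeometry) -> np.ndarray:
    n = count_beams(geometry)
    # symmetric about the field center (taken as position 0)
    return (np.arange(n) - (n - 1) / 2.0) * geometry.ctc_um


def default_resolution_um(geometry: BeamGeometry) -> float:
    """Default sampling step: >= 10 samples per beam, never coarser than 25 um."""
    return min(geometry.beam_width_um / 10.0, 25.0)


def build_ideal_profile(
    geometry: BeamGeometry,
    peak_gy: float,
    pvdr: float,
    resolution_um: float | None = None,
) -> DoseProfile:
    """Construct an ideal top-hat dose profile for an SFRT field.

    Dose equals ``peak_gy`` inside each beam (width ``beam_width_um``,
    centers on a symmetric grid of pitch ``ctc_um``) and the valley plateau
    ``peak_gy / pvdr`` elsewhere.  ``pvdr=1`` yields a uniform field.

    Raises
    ------
    ValueError
        If the resolution is coarser than ``beam_width / 5`` (a beam would
        be represented by fewer than ~5 samples).
    """
    if not peak_gy > 0:
        raise ValueError("peak_gy must be positive")
    if pvdr < 1:
        raise ValueError("pvdr must be >= 1")
    if resolution_um is None:
        resolution_um = default_resolution_um(geometry)
    if resolution_um > geometry.beam_width_um / 5.0:
        raise ValueError(
            f"resolution {resolution_um} um too coarse: must be <= "
            f"beam_width/5 = {geometry.beam_width_um / 5.0} um to resolve a beam"
        )
    half_um = geometry.field_mm * 1000.0 / 2.0
    n = int(round(2 * half_um / resolution_um)) + 1
    pos_um = np.linspace(-half_um, half_um, n)
    doses = np.full(n, peak_gy / pvdr)
    half_beam = geometry.beam_width_um / 2.0
    for c in _beam_centers_um(geometry):
        doses[np.abs(pos_um - c) <= half_beam + 1e-9] = peak_gy
    return DoseProfile(pos_um / 1000.0, doses)


def profile_pvdr(profile: DoseProfile) -> float:
    """Peak-to-valley dose ratio: max dose divided by min dose."""
    if len(profile) < 2:
        raise ValueError("profile must contain at least two samples")
    valley = float(profile.doses_gy.min())
    if valley <= 0:
        raise ValueError("valley dose is zero: PVDR undefined")
    return float(profile.doses_gy.max()) / valley


def lq_survival(dose, lq: LQParams):
    """LQ surviving fraction exp(-alpha*D - beta*D^2); scalar or array."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-lq.alpha * d - lq.beta * d * d)
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


def eud(profile: DoseProfile, lq: LQParams) -> float:
    """Equivalent uniform dose of a profile under the LQ model.

    The mean surviving fraction S-bar is averaged over all grid samples with
    uniform weights (computed in log space, so peak doses of hundreds of Gy
    do not underflow), and the EUD is the unique uniform dose with the same
    survival:

        EUD = 2 * (-ln S-bar) / (alpha + sqrt(alpha^2 - 4*beta*ln(S-bar)))

    which is the rationalized root of beta*D^2 + alpha*D + ln(S-bar) = 0 and
    degrades gracefully to ``-ln(S-bar)/alpha`` at beta = 0.
    """
    d = profile.doses_gy
    log_surv = -lq.alpha * d - lq.beta * d * d
    log_sbar = float(logsumexp(log_surv) - math.log(d.size))
    neg_ln_sbar = -log_sbar  # >= 0
    disc = math.sqrt(lq.alpha * lq.alpha + 4.0 * lq.beta * neg_ln_sbar)
    return 2.0 * neg_ln_sbar / (lq.alpha + disc)


def solve_peak_for_eud(
    geometry: BeamGeometry,
    pvdr: float,
    lq: LQParams,
    target_eud_gy: float,
    resolution_um: float | None = None,
) -> float:
    """Peak dose whose ideal profile has the requested EUD.

    Solves ``eud(build_ideal_profile(geometry, P, pvdr)) = target_eud_gy``
    for P by bracketed root search on [target, 1e4] Gy, to 1e-9 Gy.
    """
    if not target_eud_gy > 0:
        raise ValueError("target_eud_gy must be positive")
    if pvdr < 1:
        raise ValueError("pvdr must be >= 1")

    def objective(peak: float) -> float:
        prof = build_ideal_profile(geometry, peak, pvdr, resolution_um)
        return eud(prof, lq) - target_eud_gy

    # EUD <= max dose, so at P = target the EUD is <= target: lower bracket.
    lo = target_eud_gy
    f_lo = objective(lo)
    if abs(f_lo) < 1e-12:
        return lo
    hi = max(2.0 * target_eud_gy, 40.0)
    f_hi = objective(hi)
    while f_hi < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(
                "no peak dose below 1e4 Gy achieves the target EUD"
            )
        f_hi = objective(hi)
    return float(brentq(objective, lo, hi, xtol=1e-9, rtol=8.9e-16))


def read_profile_csv(path) -> DoseProfile:
    """Read a two-column ``position_mm,dose_gy`` CSV into a DoseProfile."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"position_mm", "dose_gy"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing column(s): {sorted(missing)}")
    return DoseProfile(df["position_mm"].to_numpy(), df["dose_gy"].to_numpy())


def write_profile_csv(profile: DoseProfile, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"position_mm": profile.positions_mm, "dose_gy": profile.doses_gy}
    ).to_csv(path, index=False)
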