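"""Seeded synthetic gait datasets with known ground truth.

The recordings behind the original study are not public, so this module
emulates their statistical structure: five experimental groups (control,
sham, ischemia, ischemia + treatment, pre-treatment + ischemia) of 10
animals, three joints on two hindlimbs, sessions at 0/3/7 days
post-injury, 240 fps video, several steps per session.

The per-step template is deliberately minimal so that every parameter is
recoverable by the analysis:

* horizontal displacement ``x = stride_length * s(phase)`` with ``s`` a
  monotone piecewise-linear progression, slower during stance (fraction
  ``duty_factor`` of the cycle) and faster during swing;
* vertical displacement ``y`` a raised-cosine swing bump of height
  ``swing_peak_height`` centered at ``swing_peak_phase`` with width
  ``1 - duty_factor``, zero on the ground.

Injury is expressed as attenuation of the swing peak, a circular phase
delay of the bump, an additive offset over a window of cycle bins, and
extra per-sample noise; effects can be lateralized (the study found the
left limb more affected).  Noise is i.i.d. Gaussian per sample plus a
per-animal random intercept on the amplitude parameters (stride length
and peak height), which survives onset re-zeroing and makes curves from
one animal more alike than curves from different animals.

All randomness derives from one root seed through per-(group, animal,
day, side, joint, step) child seeds, so any subset of the dataset is
reproducible independently and identical configs yield identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Homography, apply_homography, invert_homography
from .io_tracks import (
    DAYS,
    GROUPS,
    JOINTS,
    SIDES,
    CalibrationSet,
    GroupDataset,
    PointTrack,
    StepInterval,
)
from .normalize import RawStepCurve

#: Swing-peak heights (cm) per joint: distal joints move most.
JOINT_PEAK_HEIGHT = {"metatarsus": 1.5, "ankle": 1.0, "knee": 0.6}

_GAP_FRAMES = 12  # frames between consecutive steps in an emitted track


@dataclass(frozen=True)
class GaitParams:
    """Template and noise parameters of one joint's step curve (cm, s)."""

    step_duration_s: float = 0.2
    stride_length_cm: float = 8.0
    swing_peak_height_cm: float = 1.5
    swing_peak_phase: float = 0.75
    duty_factor: float = 0.6
    stance_slowdown: float = 0.4  # stance slope as a fraction of swing slope
    step_noise_cm: float = 0.08
    animal_sigma_cm: float = 0.1

    def __post_init__(self) -> None:
        if self.step_duration_s <= 0 or self.stride_length_cm <= 0:
            raise ValueError("durations and lengths must be positive")
        if not 0 < self.duty_factor < 1:
            raise ValueError(f"duty_factor must be in (0, 1), got {self.duty_factor}")
        if not 0 < self.swing_peak_phase < 1:
            raise ValueError(f"swing_peak_phase must be in (0, 1), got {self.swing_peak_phase}")
        if self.swing_peak_height_cm <= 0 or self.stance_slowdown <= 0:
            raise ValueError("peak height and stance_slowdown must be positive")
        if self.step_noise_cm < 0 or self.animal_sigma_cm < 0:
            raise ValueError("noise sigmas must be non-negative")


@dataclass(frozen=True)
class InjuryEffect:
    """Programmed deviation of a lesioned group from the healthy template."""

    amplitude_attenuation: float = 0.0  # fraction of swing peak removed, in [0, 1)
    phase_delay: float = 0.0  # circular shift of the swing bump, cycle fraction
    perturbation_window: tuple[int, int] | None = None  # 1-based bin range
    perturbation_offset_cm: float = 0.0  # additive y offset inside the window
    extra_noise_cm: float = 0.0
    laterality: str = "both"  # "left" | "right" | "both"
    contralateral_scale: float = 0.0  # effect fraction applied to the other side

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude_attenuation < 1:
            raise ValueError("amplitude_attenuation must be in [0, 1)")
        if self.perturbation_window is not None:
            lo, hi = self.perturbation_window
            if not (1 <= lo <= hi <= 100):
                raise ValueError(f"perturbation window {self.perturbation_window} outside 1..100")
        if self.laterality not in ("left", "right", "both"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def is_null(self) -> bool:
        return (
            self.amplitude_attenuation == 0
            and self.phase_delay == 0
            and self.perturbation_offset_cm == 0
            and self.extra_noise_cm == 0
        )

    def scaled(self, factor: float) -> "InjuryEffect":
        return replace(
            self,
            amplitude_attenuation=self.amplitude_attenuation * factor,
            phase_delay=self.phase_delay * factor,
            perturbation_offset_cm=self.perturbation_offset_cm * factor,
            extra_noise_cm=self.extra_noise_cm * factor,
        )

    def for_side(self, side: str) -> "InjuryEffect":
        """Effect as felt by one limb given the programmed laterality."""
        if self.laterality == "both" or side == self.laterality:
            return self
        return self.scaled(self.contralateral_scale)


NULL_EFFECT = InjuryEffect()


@dataclass
class ScenarioConfig:
    """Full description of one synthetic experiment."""

    effects: dict[tuple[str, int], InjuryEffect] = field(default_factory=dict)
    groups: tuple[str, ...] = GROUPS
    days: tuple[int, ...] = DAYS
    sides: tuple[str, ...] = SIDES
    joints: tuple[str, ...] = JOINTS
    n_animals: int = 10
    steps_per_session: int = 5
    fps: float = 240.0
    params: GaitParams = field(default_factory=GaitParams)
    seed: int = 0
    h_true: Homography | None = None

    def effect_for(self, group: str, day: int) -> InjuryEffect:
        return self.effects.get((group, day), NULL_EFFECT)


def gait_waveform(params: GaitParams, phase) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic step template evaluated at cycle phase in [0, 1].

    Returns (x, y) in cm.  x rises monotonically from 0 to stride length
    (slow stance, fast swing); y is the raised-cosine swing bump.
    """
    phase = np.asarray(phase, dtype=np.float64)
    if np.any(phase < 0) or np.any(phase > 1):
        raise ValueError("phase must lie in [0, 1]")
    d = params.duty_factor
    r = params.stance_slowdown
    # stance slope a = r * b; a*d + b*(1-d) = 1
    b = 1.0 / (r * d + (1.0 - d))
    a = r * b
    s = np.where(phase <= d, a * phase, a * d + b * (phase - d))
    x = params.stride_length_cm * s
    y = _swing_bump(phase, params.swing_peak_phase, 1.0 - d) * params.swing_peak_height_cm
    return x, y


def _swing_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of unit height; circular in phase."""
    dist = np.mod(phase - center + 0.5, 1.0) - 0.5
    inside = np.abs(dist) <= width / 2.0
    out = np.zeros_like(phase, dtype=np.float64)
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * dist[inside] / width))
    return out


def simulate_step(
    params: GaitParams,
    effect: InjuryEffect,
    rng: np.random.Generator,
    *,
    animal_id: str = "a0",
    group: str = "control",
    day: int = 0,
    side: str = "left",
    joint: str = "metatarsus",
    step_id: int = 0,
    fps: float = 240.0,
) -> RawStepCurve:
    """One noisy step of one joint, with the injury effect applied.

    Order of operations: swing-peak attenuation, circular phase delay of
    the bump, additive offset over the perturbation window, then i.i.d.
    Gaussian sample noise on both axes (step noise and extra injury noise
    combined in quadrature).
    """
    n = int(round(params.step_duration_s * fps)) + 1
    t = np.arange(n) / fps
    phase = t / t[-1]

    x, _ = gait_waveform(params, phase)
    peak = params.swing_peak_height_cm * (1.0 - effect.amplitude_attenuation)
    center = np.mod(params.swing_peak_phase + effect.phase_delay, 1.0)
    y = peak * _swing_bump(phase, center, 1.0 - params.duty_factor)

    if effect.perturbation_window is not None and effect.perturbation_offset_cm != 0.0:
        lo, hi = effect.perturbation_window
        win = (phase >= (lo - 1) / 99.0) & (phase <= (hi - 1) / 99.0)
        y = y + np.where(win, effect.perturbation_offset_cm, 0.0)

    sigma = float(np.hypot(params.step_noise_cm, effect.extra_noise_cm))
    if sigma > 0:
        x = x + rng.normal(0.0, sigma, size=n)
        y = y + rng.normal(0.0, sigma, size=n)

    return RawStepCurve(
        animal_id=animal_id,
        group=group,
        day=day,
        side=side,
        joint=joint,
        step_id=step_id,
        t=t,
        x=x,
        y=y,
        fps=fps,
        units="cm",
    )


def _animal_rng(seed: int, gi: int, ai: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, gi, ai)))


def _step_rng(seed: int, gi: int, ai: int, day: int, si: int, ji: int, step: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2, gi, ai, day, si, ji, step))
    )


@dataclass
class GroundTruth:
    """Programmed effects and per-animal random intercepts of a dataset."""

    effects: pd.DataFrame  # one row per (group, day, side) with effect fields
    animal_effects: pd.DataFrame  # per-animal stride/peak intercepts (cm)


def simulate_dataset(sc: ScenarioConfig) -> tuple[GroupDataset, GroundTruth]:
    """Generate the full dataset for a scenario plus its ground-truth sidecar.

    If ``sc.h_true`` is given, emitted coordinates are pre-distorted into
    pixels by its inverse and a matching four-point calibration table is
    included, so the geometry stage must recover the arena coordinates.
    """
    params0 = sc.params
    step_frames = int(round(params0.step_duration_s * sc.fps)) + 1
    stride_frames = step_frames + _GAP_FRAMES

    h_inv = invert_homography(sc.h_true) if sc.h_true is not None else None
    units = "px" if h_inv is not None else "cm"

    tracks: list[PointTrack] = []
    intervals: list[StepInterval] = []
    animal_rows = []
    effect_rows = []

    for gi, group in enumerate(sc.groups):
        for ai in range(sc.n_animals):
            animal_id = f"{group}_{ai:02d}"
            arng = _animal_rng(sc.seed, gi, ai)
            d_stride = float(arng.normal(0.0, params0.animal_sigma_cm))
            d_peak = float(arng.normal(0.0, params0.animal_sigma_cm))
            animal_rows.append((group, animal_id, d_stride, d_peak))
            for day in sc.days:
                effect_day = sc.effect_for(group, day)
                for si, side in enumerate(sc.sides):
                    effect = effect_day.for_side(side)
                    for ji, joint in enumerate(sc.joints):
                        peak = max(
                            JOINT_PEAK_HEIGHT.get(joint, params0.swing_peak_height_cm)
                            + d_peak,
                            0.05,
                        )
                        params = replace(
                            params0,
                            stride_length_cm=max(params0.stride_length_cm + d_stride, 0.5),
                            swing_peak_height_cm=peak,
                        )
                        frames_all = []
                        xy_all = []
                        for step in range(sc.steps_per_session):
                            rng = _step_rng(sc.seed, gi, ai, day, si, ji, step)
                            raw = simulate_step(
                                params,
                                effect,
                                rng,
                                animal_id=animal_id,
                                group=group,
                                day=day,
                                side=side,
                                joint=joint,
                                step_id=step,
                                fps=sc.fps,
                            )
                            f0 = step * stride_frames
                            frames_all.append(f0 + np.arange(step_frames))
                            # advance along the tunnel by one stride per step
                            xy = np.column_stack(
                                [raw.x + step * params.stride_length_cm, raw.y]
                            )
                            xy_all.append(xy)
                            if ji == 0:  # intervals are per session, shared by joints
                                intervals.append(
                                    StepInterval(
                                        animal_id=animal_id,
                                        day=day,
                                        side=side,
                                        step_id=step,
                                        start_frame=f0,
                                        end_frame=f0 + step_frames - 1,
                                    )
                                )
                        frames = np.concatenate(frames_all)
                        xy = np.concatenate(xy_all)
                        if h_inv is not None:
                            xy = apply_homography(h_inv, xy)
                        tracks.append(
                            PointTrack(
                                animal_id=animal_id,
                                group=group,
                                day=day,
                                side=side,
                                joint=joint,
                                fps=sc.fps,
                                frames=frames,
                                xy=xy,
                                units=units,
                            )
                        )
        for day in sc.days:
            for side in sc.sides:
                e = sc.effect_for(group, day).for_side(side)
                effect_rows.append(
                    {
                        "group": group,
                        "day": day,
                        "side": side,
                        "amplitude_attenuation": e.amplitude_attenuation,
                        "phase_delay": e.phase_delay,
                        "perturbation_window": (
                            f"{e.perturbation_window[0]}-{e.perturbation_window[1]}"
                            if e.perturbation_window
                            else ""
                        ),
                        "perturbation_offset_cm": e.perturbation_offset_cm,
                        "extra_noise_cm": e.extra_noise_cm,
                    }
                )

    calibrations: dict[str, CalibrationSet] = {}
    if sc.h_true is not None:
        # reference rectangle on the tunnel floor, arena cm
        dst = np.array([[0.0, 0.0], [50.0, 0.0], [50.0, 12.0], [0.0, 12.0]])
        src = apply_homography(h_inv, dst)
        for side in sc.sides:
            calibrations[side] = CalibrationSet(camera_id=side, src=src, dst=dst)

    ds = GroupDataset(
        tracks=tracks,
        intervals=intervals,
        calibrations=calibrations,
        provenance={"seed": sc.seed, "synthetic": True},
    )
    gt = GroundTruth(
        effects=pd.DataFrame(effect_rows),
        animal_effects=pd.DataFrame(
            animal_rows, columns=["group", "animal_id", "d_stride_cm", "d_peak_cm"]
        ),
    )
    return ds, gt


def default_paper_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Scenario emulating the qualitative structure of the study's findings.

    Effect sizes are calibrated (via the DF pipeline itself) so that at 3
    and 7 days post-injury the group mean DF orders as
    ischemia > ischemia_nanopso > pre_nanopso_ischemia > sham ~ control,
    effects are stronger on the left limb, and injury worsens slightly from
    day 3 to day 7.  It makes no claim to reproduce the study's numeric
    percentages, which depend on the unavailable recordings.
    """
    mk = lambda att, delay, off=0.0, extra=0.0: InjuryEffect(
        amplitude_attenuation=att,
        phase_delay=delay,
        perturbation_window=(41, 60) if off else None,
        perturbation_offset_cm=off,
        extra_noise_cm=extra,
        laterality="left",
        contralateral_scale=0.35,
    )
    effects = {
        ("ischemia", 3): mk(0.45, 0.05, off=0.35, extra=0.04),
        ("ischemia", 7): mk(0.52, 0.06, off=0.40, extra=0.05),
        ("ischemia_nanopso", 3): mk(0.28, 0.03),
        ("ischemia_nanopso", 7): mk(0.30, 0.035),
        ("pre_nanopso_ischemia", 3): mk(0.18, 0.02),
        ("pre_nanopso_ischemia", 7): mk(0.19, 0.022),
    }
    return ScenarioConfig(effects=effects, seed=seed, **overrides)


def null_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """No injury effects and no animal random intercepts.

    Every step curve is then an independent draw around the shared
    template, which is the sampling model under which nominal test levels
    can be checked (the animal intercept would otherwise correlate curves
    within animals and the curve-level tests would not be calibrated).
    """
    params = overrides.pop("params", GaitParams(animal_sigma_cm=0.0))
    return ScenarioConfig(effects={}, params=params, seed=seed, **overrides)
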