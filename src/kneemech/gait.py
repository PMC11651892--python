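"""Synthetic level-walking gait cycle and instrumented-implant-like reference.

This module replaces the upstream motion-capture / inverse-kinematics /
inverse-dynamics pipeline: it emits, per percent of gait cycle (%GC), the
primary knee flexion angle and the external intersegmental load acting on
the femur at the knee centre, in the tibial frame.  The default parameters
emulate level walking of the modelled subject (70 kg, 172 cm): peak knee
flexion of ~57 degrees in swing (~72 %GC) and a two-peaked stance axial
load with maxima near 15 and 50 %GC; toe-off is at 63 %GC.

Curves are sums of Gaussian bumps plus a bounded, seeded low-order Fourier
perturbation, so every draw satisfies the shape contract (flexion
non-negative with a single dominant swing peak; compressive axial load with
exactly two stance maxima, near-zero in swing) while no two seeds are
identical.

A synthetic "instrumented-implant-like" reference force dataset is derived
from the same axial load for exercising the validation (RMSE) machinery;
its medial/lateral split is carried by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

GRAVITY = 9.81
N_FRAMES = 100
TOE_OFF_PERCENT = 63


class GaitError(ValueError):
    pass


def subject_scalars(mass_kg: float, height_cm: float) -> tuple[float, float]:
    """Body weight (N) and height (m) used for KCF / KCM normalisation."""
    if mass_kg <= 0 or height_cm <= 0:
        raise GaitError("mass and height must be positive")
    return mass_kg * GRAVITY, height_cm / 100.0


@dataclass
class GaitParams:
    """Shape parameters of the synthetic walking cycle (defaults are the
    study conditions; magnitudes in BW / N*m, timings in %GC)."""

    mass_kg: float = 70.0
    height_cm: float = 172.0
    # flexion curve (deg)
    flexion_base_deg: float = 5.0
    flexion_stance_peak_deg: float = 13.0
    flexion_swing_peak_deg: float = 52.0
    flexion_stance_center: float = 15.0
    flexion_swing_center: float = 72.0
    # axial load (BW), two-peaked in stance
    axial_peak1_bw: float = 0.78
    axial_peak2_bw: float = 0.73
    axial_pedestal_bw: float = 0.35
    axial_peak1_center: float = 15.0
    axial_peak2_center: float = 50.0
    # external moments (N*m) and shear (BW)
    flexion_moment_peak_nm: float = 26.0
    extension_moment_peak_nm: float = 16.0
    swing_flexor_moment_nm: float = 5.0
    adduction_moment_peak_nm: float = 6.0
    rotation_moment_peak_nm: float = 1.5
    ap_shear_bw: float = 0.12
    # bounded noise amplitudes
    noise_flexion_deg: float = 0.25
    noise_load_bw: float = 0.01
    noise_harmonics: int = 3


@dataclass
class GaitCycle:
    """Time-normalised primary kinematics + external loads for one cycle.

    ``loads`` are the intersegmental force (N) and moment (N*mm, about the
    knee centre) applied to the femur, expressed in the tibial frame, per
    frame.  Axial compression appears as a negative Y force.
    """

    percent_gc: np.ndarray
    flexion_deg: np.ndarray
    force_n: np.ndarray        # (n, 3)
    moment_nmm: np.ndarray     # (n, 3)
    bw_n: float
    height_m: float
    seed: int
    params: GaitParams = field(default_factory=GaitParams)

    @property
    def n_frames(self) -> int:
        return len(self.percent_gc)

    @property
    def axial_load_bw(self) -> np.ndarray:
        return -self.force_n[:, 1] / self.bw_n

    @property
    def stance_mask(self) -> np.ndarray:
        return self.percent_gc < TOE_OFF_PERCENT

    def toe_off_frame(self) -> int:
        return int(np.argmin(np.abs(self.percent_gc - TOE_OFF_PERCENT)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent_gc": self.percent_gc,
                "flexion_deg": self.flexion_deg,
                "force_x_n": self.force_n[:, 0],
                "force_y_n": self.force_n[:, 1],
                "force_z_n": self.force_n[:, 2],
                "moment_x_nmm": self.moment_nmm[:, 0],
                "moment_y_nmm": self.moment_nmm[:, 1],
                "moment_z_nmm": self.moment_nmm[:, 2],
            }
        )

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.10g")
        sidecar = {
            "bw_n": self.bw_n,
            "height_m": self.height_m,
            "seed": self.seed,
            "params": asdict(self.params),
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "GaitCycle":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(
            percent_gc=df["percent_gc"].to_numpy(float),
            flexion_deg=df["flexion_deg"].to_numpy(float),
            force_n=df[["force_x_n", "force_y_n", "force_z_n"]].to_numpy(float),
            moment_nmm=df[["moment_x_nmm", "moment_y_nmm", "moment_z_nmm"]].to_numpy(float),
            bw_n=float(meta["bw_n"]),
            height_m=float(meta["height_m"]),
            seed=int(meta["seed"]),
            params=GaitParams(**meta["params"]),
        )


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _bounded_noise(rng: np.random.Generator, t: np.ndarray, amplitude: float, harmonics: int) -> np.ndarray:
    """Smooth periodic perturbation with |noise| <= harmonics * amplitude."""
    out = np.zeros_like(t)
    for k in range(1, harmonics + 1):
        a, b = rng.uniform(-amplitude, amplitude, size=2)
        out += a * np.cos(2 * np.pi * k * t / 100.0) + b * np.sin(2 * np.pi * k * t / 100.0)
    return out


def _taper(t: np.ndarray) -> np.ndarray:
    """Stance window: rises 0->1 over 0-6 %GC, falls to 0 over 56-63 %GC."""
    w = np.ones_like(t)
    rise = t < 6.0
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / 6.0))
    fall = (t >= 56.0) & (t <= TOE_OFF_PERCENT)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - 56.0) / (TOE_OFF_PERCENT - 56.0)))
    w[t > TOE_OFF_PERCENT] = 0.0
    return w


def generate_gait(params: GaitParams | None = None, seed: int = 0) -> GaitCycle:
    """Generate one synthetic level-walking cycle (deterministic per seed)."""
    p = params or GaitParams()
    bw, height = subject_scalars(p.mass_kg, p.height_cm)
    rng = np.random.default_rng(seed)
    t = np.arange(N_FRAMES, dtype=float)  # integer %GC grid 0..99

    flex = (
        p.flexion_base_deg
        + p.flexion_stance_peak_deg * _gauss(t, p.flexion_stance_center, 7.0)
        + p.flexion_swing_peak_deg * _gauss(t, p.flexion_swing_center, 9.0)
        + _bounded_noise(rng, t, p.noise_flexion_deg / p.noise_harmonics, p.noise_harmonics)
    )
    flex = np.maximum(flex, 0.0)

    w = _taper(t)
    axial_bw = w * (
        p.axial_peak1_bw * _gauss(t, p.axial_peak1_center, 9.0)
        + p.axial_peak2_bw * _gauss(t, p.axial_peak2_center, 9.0)
        + p.axial_pedestal_bw * _gauss(t, 32.0, 26.0)
        + _bounded_noise(rng, t, p.noise_load_bw / p.noise_harmonics, p.noise_harmonics)
    )
    if np.any(axial_bw[w > 0.5] < 0.0):
        raise GaitError("parameters produce a negative stance axial load")
    axial_bw = np.maximum(axial_bw, 0.0)

    ap_bw = w * p.ap_shear_bw * (_gauss(t, 10.0, 7.0) - _gauss(t, 50.0, 9.0))
    ml_bw = w * 0.02 * _gauss(t, 30.0, 20.0)

    # moments (about knee centre, on the femur).  +Z flexes the knee
    # (quadriceps demand), -Z extends it (flexor demand); adduction moment
    # loads the medial compartment.
    m_flex_nm = (
        p.flexion_moment_peak_nm * w * _gauss(t, 12.0, 7.0)
        - p.extension_moment_peak_nm * w * _gauss(t, 48.0, 8.0)
        - p.swing_flexor_moment_nm * _gauss(t, 78.0, 10.0)
    )
    m_add_nm = p.adduction_moment_peak_nm * w * (
        _gauss(t, p.axial_peak1_center, 9.0)
        + 0.9 * _gauss(t, p.axial_peak2_center, 9.0)
        + 0.4 * _gauss(t, 32.0, 26.0)
    )
    m_rot_nm = p.rotation_moment_peak_nm * w * _gauss(t, 40.0, 20.0)

    force = np.stack(
        [ap_bw * bw, -axial_bw * bw, ml_bw * bw], axis=1
    )
    # adduction = rotation about -X in this frame
    moment = np.stack(
        [-m_add_nm * 1000.0, m_rot_nm * 1000.0, m_flex_nm * 1000.0], axis=1
    )
    return GaitCycle(
        percent_gc=t,
        flexion_deg=flex,
        force_n=force,
        moment_nmm=moment,
        bw_n=bw,
        height_m=height,
        seed=int(seed),
        params=p,
    )


@dataclass
class ReferenceForces:
    """Synthetic stand-in for instrumented-implant contact forces/moments."""

    percent_gc: np.ndarray
    medial_bw: np.ndarray
    lateral_bw: np.ndarray
    moment_nm: np.ndarray  # (n, 3)

    @property
    def total_bw(self) -> np.ndarray:
        return self.medial_bw + self.lateral_bw

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percent_gc": self.percent_gc,
                "medial_bw": self.medial_bw,
                "lateral_bw": self.lateral_bw,
                "total_bw": self.total_bw,
                "moment_x_nm": self.moment_nm[:, 0],
                "moment_y_nm": self.moment_nm[:, 1],
                "moment_z_nm": self.moment_nm[:, 2],
            }
        )


def generate_reference_forces(
    gait: GaitCycle,
    medial_share: float | np.ndarray = 0.6,
    noise_bw: float = 0.02,
    seed: int = 0,
) -> ReferenceForces:
    """Reference force curves derived from the gait's axial load.

    ``medial_share`` is the stance-phase medial fraction (scalar or per
    frame); medial + lateral equals the total exactly, by construction.
    """
    rng = np.random.default_rng(seed)
    total = gait.axial_load_bw + 0.25 * _gauss(gait.percent_gc, 40.0, 30.0)
    if noise_bw > 0.0:
        total = total + _bounded_noise(rng, gait.percent_gc, noise_bw / 3.0, 3)
    total = np.maximum(total, 0.0)
    share = np.broadcast_to(np.asarray(medial_share, dtype=float), total.shape)
    medial = share * total
    lateral = total - medial
    moment = np.stack(
        [
            -gait.moment_nmm[:, 0] / 1000.0 * 0.5,
            gait.moment_nmm[:, 1] / 1000.0 * 0.5,
            gait.moment_nmm[:, 2] / 1000.0 * 0.3,
        ],
        axis=1,
    )
    return ReferenceForces(gait.percent_gc.copy(), medial, lateral, moment)
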