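"""Result containers for fitted gait cycles.

:class:`GaitResults` is returned by :meth:`KneeModel.fit`; it stores the
per-frame secondary kinematics, activations, contact resultants (knee
contact force KCF and moment KCM, raw and normalised), centres of pressure
and ligament/muscle forces, plus solver diagnostics, and offers a
``summary()`` in the spirit of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import COORD_NAMES


def normalize_kcf(force_n, bw_n: float):
    """Knee contact force in body-weight (BW) units."""
    if bw_n <= 0:
        raise ValueError("body weight must be positive")
    return np.asarray(force_n, dtype=float) / bw_n


def normalize_kcm(moment_nm, bw_n: float, height_m: float):
    """Knee contact moment in BW*H units."""
    if bw_n <= 0 or height_m <= 0:
        raise ValueError("body weight and height must be positive")
    return np.asarray(moment_nm, dtype=float) / (bw_n * height_m)


def rmse_bw(simulated, reference):
    """Root-mean-square error between two equal-grid curves."""
    a = np.asarray(simulated, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the same grid")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class GaitResults:
    """Per-frame outputs of one gait-cycle equilibrium solution."""

    model: object
    gait: object
    scenario: object
    poses: np.ndarray                 # (n, 12)
    activations: np.ndarray           # (n, M)
    tf_contacts: list
    pf_contacts: list
    ligament_forces: dict             # bundle name -> (n,)
    diagnostics: list

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.poses)

    @property
    def percent_gc(self) -> np.ndarray:
        return self.gait.percent_gc

    @property
    def converged(self) -> np.ndarray:
        return np.array([d.converged for d in self.diagnostics])

    @property
    def kcf_total_n(self) -> np.ndarray:
        return np.array([c.total_force for c in self.tf_contacts])

    @property
    def kcf_medial_n(self) -> np.ndarray:
        return np.array([c.force_medial for c in self.tf_contacts])

    @property
    def kcf_lateral_n(self) -> np.ndarray:
        return np.array([c.force_lateral for c in self.tf_contacts])

    @property
    def kcf_total_bw(self) -> np.ndarray:
        return normalize_kcf(self.kcf_total_n, self.gait.bw_n)

    @property
    def kcf_medial_bw(self) -> np.ndarray:
        return normalize_kcf(self.kcf_medial_n, self.gait.bw_n)

    @property
    def kcf_lateral_bw(self) -> np.ndarray:
        return normalize_kcf(self.kcf_lateral_n, self.gait.bw_n)

    @property
    def kcm_nm(self) -> np.ndarray:
        """Contact moment on the tibial tray (N*m), per frame."""
        return np.array([c.moment for c in self.tf_contacts]) / 1000.0

    @property
    def kcm_bwh(self) -> np.ndarray:
        return normalize_kcm(self.kcm_nm, self.gait.bw_n, self.gait.height_m)

    @property
    def pf_force_n(self) -> np.ndarray:
        return np.array([c.total_force for c in self.pf_contacts])

    def cop(self, compartment: str, min_force_n: float = 0.0) -> np.ndarray:
        """(n, 3) CoP track for one compartment; NaN rows when unloaded.

        ``min_force_n`` suppresses frames whose compartment carries less
        compressive force (the pressure centroid of a nearly unloaded
        compartment is not a meaningful contact location; instrumented
        implant studies apply the same cutoff when reporting CoP tracks).
        """
        out = np.full((self.n_frames, 3), np.nan)
        for i, c in enumerate(self.tf_contacts):
            p = c.cop.get(compartment)
            if p is not None and c.compartment_compression(compartment) >= min_force_n:
                out[i] = p
        return out

    @property
    def muscle_forces_n(self) -> np.ndarray:
        fmax = np.array([m.max_isometric_force for m in self.model.muscles])
        return self.activations * fmax

    @property
    def muscle_names(self) -> list:
        return [m.name for m in self.model.muscles]

    @property
    def pcl_force_n(self) -> np.ndarray:
        return self.ligament_forces["aPCL"] + self.ligament_forces["pPCL"]

    def secondary(self, name: str) -> np.ndarray:
        return self.poses[:, COORD_NAMES.index(name)]

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data = {"percent_gc": self.percent_gc}
        for i, name in enumerate(COORD_NAMES):
            data[name] = self.poses[:, i]
        data["kcf_total_bw"] = self.kcf_total_bw
        data["kcf_medial_bw"] = self.kcf_medial_bw
        data["kcf_lateral_bw"] = self.kcf_lateral_bw
        kcm = self.kcm_nm
        for j, ax in enumerate(("x", "y", "z")):
            data[f"kcm_{ax}_nm"] = kcm[:, j]
        for comp in ("medial", "lateral"):
            track = self.cop(comp)
            for j, ax in enumerate(("x", "y", "z")):
                data[f"cop_{comp}_{ax}_mm"] = track[:, j]
        data["pf_force_n"] = self.pf_force_n
        for name, f in self.ligament_forces.items():
            data[f"lig_{name}_n"] = f
        for j, name in enumerate(self.muscle_names):
            data[f"mus_{name}_n"] = self.muscle_forces_n[:, j]
        data["converged"] = self.converged.astype(int)
        data["iterations"] = [d.iterations for d in self.diagnostics]
        return pd.DataFrame(data)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False, float_format="%.10g")

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = []
        label = self.scenario.label if self.scenario is not None else "baseline"
        lines.append("Gait-cycle equilibrium results")
        lines.append("=" * 46)
        lines.append(f"scenario:            {label}")
        lines.append(f"frames:              {self.n_frames}")
        lines.append(f"converged frames:    {int(self.converged.sum())}/{self.n_frames}")
        pk = int(np.argmax(self.kcf_total_bw))
        lines.append(
            f"peak total KCF:      {self.kcf_total_bw[pk]:.2f} BW at {self.percent_gc[pk]:.0f} %GC"
        )
        lines.append(
            f"  medial/lateral:    {self.kcf_medial_bw[pk]:.2f} / {self.kcf_lateral_bw[pk]:.2f} BW"
        )
        lines.append(
            f"peak flexion:        {self.poses[:, 0].max():.1f} deg at "
            f"{self.percent_gc[int(np.argmax(self.poses[:, 0]))]:.0f} %GC"
        )
        lines.append(f"peak PCL force:      {self.pcl_force_n.max():.0f} N")
        ap = self.secondary("tf_ap")
        lines.append(
            f"AP femoral range:    [{ap.min():+.1f}, {ap.max():+.1f}] mm"
        )
        lines.append(
            f"max |residual|:      "
            f"{max(np.max(np.abs(d.residuals)) for d in self.diagnostics):.2f} (N or N*mm)"
        )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_contact_forces(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.percent_gc, self.kcf_total_bw, label="total")
        ax.plot(self.percent_gc, self.kcf_medial_bw, label="medial")
        ax.plot(self.percent_gc, self.kcf_lateral_bw, label="lateral")
        ax.set_xlabel("% gait cycle")
        ax.set_ylabel("KCF (BW)")
        ax.legend()
        return ax

    def plot_kinematics(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.percent_gc, self.poses[:, 0], label="flexion (deg)")
        ax.plot(self.percent_gc, self.secondary("tf_ap"), label="AP (mm)")
        ax.plot(self.percent_gc, self.secondary("tf_adduction"), label="adduction (deg)")
        ax.plot(self.percent_gc, self.secondary("tf_rotation"), label="int. rotation (deg)")
        ax.set_xlabel("% gait cycle")
        ax.legend()
        return ax
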