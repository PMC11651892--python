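"""The PCL-tensioning experiment: pre-strain sweep x implant conformity.

Eleven PCL reference-strain perturbations (-10 to +10 percentage points in
2-point steps around the 2% baseline) are each run through the same gait
cycle on the standard- and low-conformity inlay, giving 22 scenarios.  The
summary metrics mirror the study's outcome set: peak medial/lateral knee
contact force, the anteroposterior femoral shift at toe-off (63 %GC)
relative to the matching-conformity baseline, the CoP shift at the
peak-force frame, peak PCL force, and the tight/loose asymmetry index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gait import GaitCycle, TOE_OFF_PERCENT
from .ligaments import CONFORMITIES, PRESTRAIN_DELTAS, PrestrainScenario
from .model import KneeModel
from .results import GaitResults, normalize_kcf, normalize_kcm, rmse_bw

#: minimum compartment load for a centre of pressure to count as a contact
#: location in the outcome metrics (the convention instrumented-implant
#: reports use)
COP_MIN_FORCE_N = 30.0

__all__ = [
    "run_sweep",
    "summarize_sweep",
    "asymmetry_index",
    "SweepResults",
    "normalize_kcf",
    "normalize_kcm",
    "rmse_bw",
]


class ExperimentError(RuntimeError):
    pass


def run_sweep(
    base_models: dict,
    gait: GaitCycle,
    deltas=PRESTRAIN_DELTAS,
    conformities=CONFORMITIES,
    max_unconverged_fraction: float = 0.05,
    progress: bool = False,
) -> "SweepResults":
    """Run every (delta, conformity) scenario on the shared gait input.

    ``base_models`` maps conformity name to a reference-assembled
    :class:`KneeModel`.  Scenarios are independent (stateless), so the
    result does not depend on execution order.  A scenario with more than
    ``max_unconverged_fraction`` unconverged frames aborts the sweep; below
    that, unconverged frames are carried in the diagnostics.
    """
    results = []
    for conf in conformities:
        if conf not in base_models:
            raise ExperimentError(f"no base model for conformity {conf!r}")
        base = base_models[conf]
        for delta in deltas:
            sc = PrestrainScenario(int(delta), conf)
            model = base.apply_prestrain(sc)
            res = model.fit(gait, scenario=sc)
            bad = int((~res.converged).sum())
            if bad > max_unconverged_fraction * res.n_frames:
                raise ExperimentError(
                    f"scenario {sc.label}: {bad}/{res.n_frames} frames failed to "
                    f"converge (limit {max_unconverged_fraction:.0%})"
                )
            if progress:
                print(f"  {sc.label}: {res.n_frames - bad}/{res.n_frames} converged")
            results.append(res)
    return SweepResults(results=results, gait=gait)


@dataclass
class SweepSummary:
    """Per-scenario outcome metrics, shifts relative to the delta=0 scenario
    of the matching conformity."""

    table: pd.DataFrame

    def row(self, delta: int, conformity: str) -> pd.Series:
        t = self.table
        sel = (t["delta"] == delta) & (t["conformity"] == conformity)
        if not sel.any():
            raise KeyError((delta, conformity))
        return t[sel].iloc[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.table.to_json(orient="records", indent=2))


def _toe_off_index(gait: GaitCycle) -> int:
    return gait.toe_off_frame()


def summarize_sweep(sweep: "SweepResults") -> SweepSummary:
    """Outcome metrics per scenario.

    Unconverged frames are excluded from peak metrics; shift metrics are
    relative to the same-conformity baseline (delta = 0), which therefore
    reports exact zeros.
    """
    rows = []
    gait = sweep.gait
    i_to = _toe_off_index(gait)
    base = {c: sweep.get(0, c) for c in sweep.conformities}
    for res in sweep.results:
        sc = res.scenario
        b = base[sc.conformity]
        ok = res.converged
        kcf = np.where(ok, res.kcf_total_bw, -np.inf)
        pk = int(np.argmax(kcf))
        pk_b = int(np.argmax(np.where(b.converged, b.kcf_total_bw, -np.inf)))
        cop_m = res.cop("medial", min_force_n=COP_MIN_FORCE_N)
        cop_m_b = b.cop("medial", min_force_n=COP_MIN_FORCE_N)
        cop_l = res.cop("lateral", min_force_n=COP_MIN_FORCE_N)
        ap = res.secondary("tf_ap")
        rows.append(
            {
                "delta": sc.delta,
                "conformity": sc.conformity,
                "peak_kcf_bw": res.kcf_total_bw[pk],
                "peak_kcf_frame": float(gait.percent_gc[pk]),
                "peak_medial_kcf_bw": float(np.max(np.where(ok, res.kcf_medial_bw, -np.inf))),
                "peak_lateral_kcf_bw": float(np.max(np.where(ok, res.kcf_lateral_bw, -np.inf))),
                "toe_off_ap_shift_mm": float(ap[i_to] - b.secondary("tf_ap")[i_to]),
                "cop_medial_ap_shift_at_peak_mm": float(cop_m[pk_b, 0] - cop_m_b[pk_b, 0]),
                "cop_medial_ap_excursion_mm": float(np.nanmax(cop_m[:, 0]) - np.nanmin(cop_m[:, 0])),
                "cop_lateral_ap_excursion_mm": float(np.nanmax(cop_l[:, 0]) - np.nanmin(cop_l[:, 0])),
                "peak_pcl_force_n": float(np.max(np.where(ok, res.pcl_force_n, -np.inf))),
                "adduction_rom_deg": float(np.ptp(res.secondary("tf_adduction")[ok])),
                "rotation_rom_deg": float(np.ptp(res.secondary("tf_rotation")[ok])),
                "n_unconverged": int((~ok).sum()),
            }
        )
    table = pd.DataFrame(rows).sort_values(["conformity", "delta"]).reset_index(drop=True)
    return SweepSummary(table)


def asymmetry_index(summary: SweepSummary, conformity: str = "standard") -> pd.DataFrame:
    """|shift(-d)| / |shift(+d)| for the AP-translation and CoP metrics.

    Values below one express that loosening the PCL perturbs the joint less
    than tightening it by the same amount.  An undefined ratio (zero tight
    shift) is reported as NaN, never an error.
    """
    rows = []
    for d in (2, 4, 6, 8, 10):
        row = {"delta_magnitude": d}
        for metric in ("toe_off_ap_shift_mm", "cop_medial_ap_shift_at_peak_mm"):
            loose = abs(float(summary.row(-d, conformity)[metric]))
            tight = abs(float(summary.row(+d, conformity)[metric]))
            row[metric + "_ratio"] = loose / tight if tight > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SweepResults:
    """All scenario results of one pre-strain x conformity sweep."""

    results: list
    gait: GaitCycle
    _summary: SweepSummary | None = field(default=None, repr=False)

    @property
    def conformities(self) -> list:
        return sorted({r.scenario.conformity for r in self.results})

    @property
    def deltas(self) -> list:
        return sorted({r.scenario.delta for r in self.results})

    def get(self, delta: int, conformity: str) -> GaitResults:
        for r in self.results:
            if r.scenario.delta == delta and r.scenario.conformity == conformity:
                return r
        raise KeyError((delta, conformity))

    def summary(self) -> SweepSummary:
        if self._summary is None:
            self._summary = summarize_sweep(self)
        return self._summary

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r in self.results:
            r.save_csv(out / f"scenario_{r.scenario.label}.csv")
        self.summary().to_json(out / "sweep_summary.json")

    def plot_ap_shifts(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.summary().table
        for conf in self.conformities:
            sub = t[t["conformity"] == conf]
            ax.plot(sub["delta"], sub["toe_off_ap_shift_mm"], "o-", label=conf)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("PCL pre-strain delta (percentage points)")
        ax.set_ylabel("AP femoral shift at toe-off (mm)")
        ax.legend(title="conformity")
        return ax
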