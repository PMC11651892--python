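import numpy as np
import pytest

from kneemech.gait import GaitCycle, GaitParams, generate_gait
from kneemech.model import KneeModel


@pytest.fixture(scope="session")
def default_model() -> KneeModel:
    """Reference-assembled standard-conformity knee (shared, treated read-only)."""
    return KneeModel.default()


@pytest.fixture(scope="session")
def low_model() -> KneeModel:
    return KneeModel.default(conformity="low")


@pytest.fixture(scope="session")
def gait_cycle() -> GaitCycle:
    return generate_gait(GaitParams(), seed=1)


def make_constant_gait(n=8, flexion=12.0, axial_bw=0.8, flexor_nm=-8.0) -> GaitCycle:
    """Constant-load, constant-flexion pseudo-cycle for determinism checks."""
    bw, h = 70.0 * 9.81, 1.72
    force = np.tile([0.0, -axial_bw * bw, 0.0], (n, 1))
    moment = np.tile([0.0, 0.0, flexor_nm * 1000.0], (n, 1))
    return GaitCycle(
        percent_gc=np.arange(n, dtype=float),
        flexion_deg=np.full(n, float(flexion)),
        force_n=force,
        moment_nmm=moment,
        bw_n=bw,
        height_m=h,
        seed=0,
    )


@pytest.fixture(scope="session")
def sweep_results(gait_cycle):
    """The full 11-delta x 2-conformity sweep on the default synthetic gait.

    Session-scoped: this is the expensive end-to-end computation the
    acceptance checks interrogate.
    """
    from kneemech.experiments import run_sweep
    from kneemech.model import KneeModel

    base = {c: KneeModel.default(conformity=c) for c in ("standard", "low")}
    return run_sweep(base, gait_cycle, max_unconverged_fraction=1.0)
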