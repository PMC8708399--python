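import numpy as np
import pytest

from phagedyn.curves import (
    CombinationKey,
    GrowthCurve,
    NONE_TOKEN,
    PlateExperiment,
    TimeGrid,
)


@pytest.fixture(scope="session")
def grid():
    return TimeGrid.default()


def make_curve(od, grid=None, phage="P1", bact="B1", moi=1.0, rep=1,
               role="treatment", adjusted=True):
    grid = grid or TimeGrid.default()
    od = np.asarray(od, dtype=float)
    if od.size == 1:
        od = np.full(len(grid), od.item())
    return GrowthCurve(
        key=CombinationKey(phage, bact, moi, rep, role),
        grid=grid, od=od, adjusted=adjusted,
    )


def logistic_od(grid, k_od=0.7, r=0.85, n0_frac=0.05):
    """Closed-form logistic OD trace: OD(t) = K / (1 + (K/N0 - 1) e^{-rt})."""
    t = grid.times
    return k_od / (1.0 + (1.0 / n0_frac - 1.0) * np.exp(-r * t))


@pytest.fixture()
def toy_plate(grid):
    """Blank + control + 2 treatments, raw (with media background)."""
    bg = 0.05
    blank = make_curve(np.full(len(grid), bg), grid,
                       phage=NONE_TOKEN, bact=NONE_TOKEN, moi=0.0,
                       role="blank", adjusted=False)
    control = make_curve(bg + logistic_od(grid), grid,
                         phage=NONE_TOKEN, bact="B1", moi=0.0,
                         role="bacteria_control", adjusted=False)
    t1 = make_curve(bg + 0.5 * logistic_od(grid), grid,
                    phage="P1", bact="B1", moi=10.0, adjusted=False)
    t2 = make_curve(np.full(len(grid), bg + 0.01), grid,
                    phage="P2", bact="B1", moi=1.0, adjusted=False)
    return PlateExperiment(curves=[blank, control, t1, t2], grid=grid,
                           provenance="toy").validate()


@pytest.fixture(scope="session")
def small_study():
    """Tiny synthetic study shared across tests (2 phages, 2 strains)."""
    from phagedyn.simulate import NoiseModel, StudyConfig, generate_study

    cfg = StudyConfig(
        phages=("P1", "P2"), bacteria=("B1", "B2"),
        replicates=3, noise=NoiseModel(seed=11),
    )
    return generate_study(cfg, seed=11)
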