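import numpy as np
import pytest

from palpkit.synth import GeneratorParams
from palpkit.trajectory import HapticCondition, TargetPoint, Trial


@pytest.fixture
def default_params() -> GeneratorParams:
    return GeneratorParams.defaults()


@pytest.fixture
def condition() -> HapticCondition:
    return HapticCondition("thrill", "strong", 4, 1)


def make_random_trial(
    rng: np.random.Generator,
    n_frames: int | None = None,
    uniform_dt: bool = False,
    trial_id: str = "T001",
    participant_id: str = "P01",
) -> Trial:
    """A valid random trial: positions in a 160 mm box, z in [0, 30]."""
    n = n_frames or int(rng.integers(5, 40))
    if uniform_dt:
        t = np.arange(n) * 0.02
    else:
        t = np.cumsum(rng.uniform(0.005, 0.05, size=n))
        t -= t[0]
    index = np.column_stack([
        rng.uniform(-80, 80, n), rng.uniform(-80, 80, n), rng.uniform(0, 30, n)
    ])
    middle = index + np.array([20.0, 0.0, 0.0])
    condition = HapticCondition(
        vibration_type=rng.choice(["pulse", "thrill"]),
        vibration_intensity=rng.choice(["strong", "weak"]),
        skin_thickness_mm=int(rng.choice([4, 6])),
        location_index=int(rng.integers(1, 9)),
    )
    tx, ty = rng.uniform(-50, 50, 2)
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        condition=condition,
        target=TargetPoint(float(tx), float(ty)),
        t_s=t,
        index_tip=index,
        middle_tip=middle,
    )


def make_line_trial(
    start_xy: tuple[float, float],
    end_xy: tuple[float, float],
    target: TargetPoint,
    n: int = 50,
    dt: float = 0.02,
    z: float = 5.0,
) -> Trial:
    """Constant-velocity straight-line trial in the skin plane."""
    t = np.arange(n) * dt
    frac = np.linspace(0.0, 1.0, n)
    x = start_xy[0] + frac * (end_xy[0] - start_xy[0])
    y = start_xy[1] + frac * (end_xy[1] - start_xy[1])
    index = np.column_stack([x, y, np.full(n, z)])
    return Trial(
        trial_id="LINE",
        participant_id="P01",
        condition=HapticCondition("pulse", "strong", 4, 1),
        target=target,
        t_s=t,
        index_tip=index,
        middle_tip=index + np.array([20.0, 0.0, 0.0]),
    )
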