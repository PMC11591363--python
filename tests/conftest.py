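import numpy as np
import pytest

from gaitdf.normalize import NormalizedStepCurve


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_curve(
    x,
    y,
    *,
    animal="a0",
    group="control",
    day=3,
    side="left",
    joint="metatarsus",
    step=0,
):
    """NormalizedStepCurve with given bin vectors and default keys."""
    return NormalizedStepCurve(
        animal_id=animal,
        group=group,
        day=day,
        side=side,
        joint=joint,
        step_id=step,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
    )


@pytest.fixture
def curve_factory():
    return make_curve


def random_curves(rng, n, animal_prefix="a", group="control", n_bins=100, scale=1.0):
    """A list of random smooth-ish curves, one animal per curve."""
    out = []
    for i in range(n):
        out.append(
            make_curve(
                rng.normal(0, scale, n_bins),
                rng.normal(0, scale, n_bins),
                animal=f"{animal_prefix}{i}",
                group=group,
                step=i,
            )
        )
    return out
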