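import numpy as np
import pytest

from sbtkin import BreathCurve, ModelParams


@pytest.fixture
def ref_params() -> ModelParams:
    """A mid-range parameter set used by most worked examples."""
    return ModelParams(rho=1.2, pi_ratio=0.5, kappa=0.6)


@pytest.fixture
def schedule_15min() -> np.ndarray:
    """Every 15 min from 0 to 4 h, in hours."""
    return np.arange(0, 241, 15) / 60.0


@pytest.fixture
def make_curve():
    def _make(times, values, excluded=None, pid="P01", condition="0"):
        return BreathCurve(
            participant_id=pid,
            condition=condition,
            times=np.asarray(times, dtype=float),
            values=np.asarray(values, dtype=float),
            excluded=None if excluded is None else np.asarray(excluded, dtype=bool),
        )

    return _make
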