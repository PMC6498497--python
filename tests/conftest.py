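import numpy as np
import pandas as pd
import pytest

from adwarn import biomodel, synthetic


@pytest.fixture(scope="session")
def schedules():
    return synthetic.build_schedules()


@pytest.fixture(scope="session")
def r1_params():
    return biomodel.KineticParams.default(ki_vfa=315.0)


@pytest.fixture(scope="session")
def r1_fullload_result(schedules, r1_params):
    """R1 simulated through the full-load plateau (days 0-100)."""
    return biomodel.simulate(schedules["R1"], r1_params, t_end=101.0)


@pytest.fixture(scope="session")
def r1_gradual_frame():
    return synthetic.make_overload_fixture(synthetic.preset_r1_gradual())


@pytest.fixture(scope="session")
def r1_sudden_frame():
    return synthetic.make_overload_fixture(synthetic.preset_r1_sudden())


@pytest.fixture()
def flat_frame():
    """A perfectly constant indicator frame over the R1 span."""
    days = np.arange(0, 166)
    frame = pd.DataFrame(index=pd.Index(days, name="day"))
    for name, level in [
        ("acetate", 0.2), ("propionate", 0.06), ("butyrate", 0.1),
        ("vfa_total", 0.36), ("IA", 0.5), ("BA", 1.3), ("ia_ba", 0.38),
        ("ba_ta", 0.7), ("vfa_ba", 0.28), ("ch4_co2", 1.6),
        ("ch4_yield", 0.2), ("biogas_L", 8.5), ("ph", 6.8),
    ]:
        frame[name] = level
    return frame
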