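import numpy as np
import pytest

from wtdcc import BrdParams
from wtdcc.datagen import Scenario

# the study's base setting: one-year window, median IAD 1.5 months,
# sigma = exp(-0.35), OR 3, pv 25%, px 80%, 1:1 matching, n = 39,600
BASE_MU = float(np.log(1.5 / 12))
BASE_SIGMA = float(np.exp(-0.35))


@pytest.fixture(scope="session")
def base_brd() -> BrdParams:
    return BrdParams("lognormal", mu=BASE_MU, sigma=BASE_SIGMA)


@pytest.fixture(scope="session")
def base_scenario(base_brd) -> Scenario:
    return Scenario(
        n_total=39_600, controls_per_case=1, or_true=3.0, pv=0.25, px=0.8, brd=base_brd
    )


def scenario_grid(n_total=39_600, pv=0.25, px=0.8):
    """The eight lognormal study settings: mu x sigma x matching ratio."""
    out = []
    for mu in (np.log(1.5 / 12), np.log(2 / 12)):
        for sigma in (np.exp(-0.35), np.exp(-0.25)):
            for cpc in (1, 10):
                n = n_total - n_total % (1 + cpc)
                out.append(
                    Scenario(
                        n_total=n,
                        controls_per_case=cpc,
                        or_true=3.0,
                        pv=pv,
                        px=px,
                        brd=BrdParams("lognormal", mu=float(mu), sigma=float(sigma)),
                    )
                )
    return out
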