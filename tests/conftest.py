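import numpy as np
import pandas as pd
import pytest

from plasmidrbe.mcmahon import McMahonParams
from plasmidrbe.synthetic import generate_dose_response, wet_reference_design


@pytest.fixture
def params():
    """Reference parameter set used across model tests."""
    return McMahonParams(mu=0.01, phi=0.001, s0=0.9, c0=0.07, rho=10 / 4361)


@pytest.fixture
def noise_free_dataset():
    design = wet_reference_design(seed=0, noise_scale=0.0, true_mu=0.08, true_phi=0.0015)
    return design, generate_dose_response(design)


@pytest.fixture
def lane_frame():
    return pd.DataFrame(
        {
            "sample_id": ["a", "a", "a"],
            "dose": [0.0, 10.0, 20.0],
            "repeat_id": [1, 1, 1],
            "intensity_sc": [8.0, 5.0, 3.0],
            "intensity_oc": [1.0, 3.0, 4.0],
            "intensity_l": [0.5, 1.0, 2.0],
        }
    )


def brute_force_max_pairing(ssb_positions, separation_bp, n_bp):
    """Independent oracle: exhaustive maximum pairing of opposite-strand SSBs.

    Recursive enumeration over strand-1 breaks; exact for small fixtures.
    """
    s1 = sorted(bp for bp, st in ssb_positions if st == 1)
    s2 = sorted(bp for bp, st in ssb_positions if st == 2)

    def circ(i, j):
        d = abs(i - j)
        return min(d, n_bp - d)

    def best(i, used):
        if i == len(s1):
            return 0
        score = best(i + 1, used)  # leave s1[i] unpaired
        for j, b in enumerate(s2):
            if j not in used and circ(s1[i], b) <= separation_bp:
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())
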