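import logging

import numpy as np
import pandas as pd
import pytest

from swpergeo import swper, synth

logging.getLogger("swpergeo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def codebook():
    return swper.default_codebook()


@pytest.fixture(scope="session")
def small_survey():
    """A modest four-level survey with outcomes and items, no exclusions."""
    spec = synth.PopulationSpec(
        n_states=8,
        districts_per_state=3,
        communities_per_district=4,
        women_per_community=12,
        sigma2_state=0.5,
        sigma2_district=0.2,
        sigma2_community=0.8,
        exclusion_rates=(0.0, 0.0, 0.0),
        seed=42,
    )
    return synth.generate_survey(spec)


def toy_records(n=10, not_in_union=3, not_selected=2, missing=1):
    """Hand-built cascade fixture: exclusions planted in known positions."""
    rec = pd.DataFrame(
        {
            "state_id": "S1",
            "district_id": "D1",
            "community_id": "C1",
            "woman_id": [f"W{i}" for i in range(n)],
            "in_union": 1,
            "module_selected": 1,
            **{f"item_{i}": 1.0 for i in range(1, 15)},
        }
    )
    rec.loc[: not_in_union - 1, "in_union"] = 0
    rec.loc[not_in_union : not_in_union + not_selected - 1, "module_selected"] = 0
    start = not_in_union + not_selected
    rec.loc[start : start + missing - 1, "item_7"] = np.nan
    return rec
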