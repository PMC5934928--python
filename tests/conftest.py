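from datetime import date

import numpy as np
import pytest

from rand36val.scoring import RECODE_TABLE, Rand36Record


def make_record(responses=None, fill="best", patient_id="P1", group="test",
                occasion="baseline", when=date(2017, 3, 1)):
    """A full 36-item record; `fill` picks best/worst defaults, `responses`
    overrides individual items (None = missing)."""
    items = {}
    for item, table in RECODE_TABLE.items():
        best_raw = max(table, key=table.get)
        worst_raw = min(table, key=table.get)
        items[item] = best_raw if fill == "best" else worst_raw
    if responses:
        items.update(responses)
    return Rand36Record(
        patient_id=patient_id, group=group, occasion=occasion, date=when, items=items
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)
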