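import numpy as np
import pandas as pd
import pytest

from sevmir import io, simulate


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment, shared across read-only tests."""
    return simulate.simulate_experiment(simulate.GeneratorConfig(seed=1))


@pytest.fixture()
def small_sheet():
    rows = []
    for donor in ("HDF1", "HDF2", "HDF3"):
        for cond in ("Q", "SIPS"):
            for day in ("D7", "D21"):
                rows.append(
                    {
                        "sample_id": f"{donor}_{cond}_{day}",
                        "donor": donor,
                        "condition": cond,
                        "day": day,
                        "cells_for_secretion": 1.5e7 if cond == "Q" else 1.65e6,
                        "platform": "qpcr",
                    }
                )
    return io.SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


def make_ct(values: dict, detection_limit: float = 38.0, spikeins=()) -> io.CtMatrix:
    """Build a CtMatrix from {mirna: {sample: ct}} (NaN = ND)."""
    frame = pd.DataFrame(values).T.astype(float)
    return io.CtMatrix(frame, detection_limit=detection_limit, spikein_ids=tuple(spikeins))


def make_sheet(samples: list[tuple]) -> io.SampleSheet:
    """Build a SampleSheet from (sample_id, donor, condition, day, cells, platform)."""
    frame = pd.DataFrame(
        samples,
        columns=["sample_id", "donor", "condition", "day", "cells_for_secretion", "platform"],
    ).set_index("sample_id")
    return io.SampleSheet(frame)
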