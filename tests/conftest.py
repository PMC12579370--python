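import numpy as np
import pandas as pd
import pytest

from tegma.simulate import CSV_COLUMNS, PairedDataset


def make_dataset(crt_r, **channels) -> PairedDataset:
    """Build a small PairedDataset from explicit channel vectors.

    Unspecified channels are filled with a benign constant so the frame is
    schema-complete; pass np.nan entries to mark missing values.
    """
    n = len(crt_r)
    data = {"record_id": np.arange(n), "crt_r_min": np.asarray(crt_r, float)}
    for col in CSV_COLUMNS[2:]:
        data[col] = np.asarray(channels.get(col, np.full(n, 50.0)), float)
    return PairedDataset(pd.DataFrame(data, columns=list(CSV_COLUMNS)))


@pytest.fixture
def toy_dataset() -> PairedDataset:
    """10 records: 2 with a missing field, 1 with CRT-R above 5.5 min."""
    crt_r = [0.5, 0.7, 0.9, 1.2, 6.0, 0.6, 0.8, 1.0, 5.5, 0.4]
    cff = [20.0, 15.0, np.nan, 10.0, 1.0, 18.0, 14.0, 12.0, 2.0, 22.0]
    ckh_r = [9.0, 10.0, 10.5, 11.0, 11.7, np.nan, 10.2, 10.8, 11.6, 8.5]
    return make_dataset(crt_r, cff_ma_mm=cff, ckh_r_min=ckh_r)
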