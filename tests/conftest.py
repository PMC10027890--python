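import numpy as np
import pandas as pd
import pytest

from mircascade.io import CtMatrix


def make_ct(values: dict, samples, card=None, controls=()):
    """Build a CtMatrix from {mir: [ct per sample]}; None -> MISSING."""
    mirs = list(values)
    ct = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in row] for row in values.values()],
        index=pd.Index(mirs, name="mir_id"),
        columns=list(samples),
    )
    card = pd.Series(card if card is not None else "A", index=mirs)
    is_control = pd.Series([m in controls for m in mirs], index=mirs)
    return CtMatrix(ct=ct, card=card, is_control=is_control)


def make_meta(groups: dict, model="electrical_post_SE"):
    """{sample: group} -> metadata frame."""
    return pd.DataFrame(
        {"group": list(groups.values()), "model": model},
        index=pd.Index(list(groups.keys()), name="sample_id"),
    )


def make_burden(counts: dict, durations: dict | None = None):
    idx = pd.Index(list(counts.keys()), name="sample_id")
    dur = durations or {s: 30.0 * c for s, c in counts.items()}
    return pd.DataFrame(
        {"seizure_count": list(counts.values()),
         "seizure_duration": [dur[s] for s in counts]},
        index=idx,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_screen():
    """5 sham + 6 experimental samples, 6 assays + 1 control, one card."""
    samples = [f"sh{i}" for i in range(5)] + [f"ex{i}" for i in range(6)]
    base = {
        "m-flat": [25.0] * 11,
        "m-up": [25, 25.2, 24.8, 25.1, 24.9, 23.0, 23.2, 22.8, 23.1, 22.9, 23.0],
        "m-weak": [32, 31.5, 32.5, 31.8, 32.2, 31.9, 32.1, 31.7, 32.3, 32.0, 31.6],
        "m-missing": [None, None, None, None, 25.0, 25.0, None, None, None, None, None],
        "m-none": [None] * 11,
        "m-var": [24, 26, 25, 27, 23, 25, 24, 26, 27, 23, 25],
        "ctrl": [20.0] * 11,
    }
    ctm = make_ct(base, samples, controls=("ctrl",))
    meta = make_meta({s: ("sham" if s.startswith("sh") else "experimental") for s in samples})
    burden = make_burden({f"ex{i}": 5 * (i + 1) for i in range(6)})
    return ctm, meta, burden
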