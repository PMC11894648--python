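import numpy as np
import pandas as pd
import pytest

from plexquant import ExperimentalDesign, LabelSet, PSMTable, load_label_set


@pytest.fixture
def duo() -> LabelSet:
    return load_label_set(["A", "B"])


@pytest.fixture
def quad() -> LabelSet:
    return load_label_set(["126", "127N", "127C", "128N"])


def make_table(label_set, rows, **meta_overrides):
    """Tiny PSM table from a list of (protein_group, plex, reporter_values)."""
    n = len(rows)
    meta = pd.DataFrame(
        {
            "psm_id": [f"p{i}" for i in range(n)],
            "protein_group": [r[0] for r in rows],
            "plex": [r[1] for r in rows],
            "experiment": [r[1] for r in rows],
            "precursor_intensity": np.ones(n),
            "fill_time": np.ones(n),
            "pif": np.ones(n),
            "base_peak_ratio": np.full(n, np.nan),
        }
    )
    for key, vals in meta_overrides.items():
        meta[key] = vals
    raw = np.array([r[2] for r in rows], dtype=float)
    return PSMTable(label_set=label_set, meta=meta, raw=raw)


def make_design(label_set, roles, samples=None, groups=None, plex="plex1"):
    """Single-plex design from a role list in label-set channel order."""
    samples = samples or [
        f"s{i}" for i, r in enumerate(roles) if r == "sample"
    ]
    groups = groups or ["g"] * len(samples)
    rows, si = [], 0
    for ch, role in zip(label_set.channels, roles):
        sample = group = None
        if role == "sample":
            sample, group = samples[si], groups[si]
            si += 1
        rows.append({"plex": plex, "channel": ch, "role": role, "sample": sample, "group": group})
    return ExperimentalDesign(label_set=label_set, table=pd.DataFrame(rows))
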