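"""Shared helpers: seeded sub-streams and fixed CSV/JSON dialects."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

# Fixed offsets so every stage draws from its own reproducible stream.
_STREAM_OFFSETS = {
    "cohort": 0,
    "membership": 1,
    "trajectory": 2,
    "missingness": 3,
    "brain_reference": 4,
    "balance": 5,
    "synthesis": 6,
    "split": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Child generator for a named stage, derived from one master seed."""
    if name not in _STREAM_OFFSETS:
        raise KeyError(f"unknown random stream {name!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_OFFSETS[name]]))


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    # UTF-8, comma separated, dot decimal: bit-exact round-trips in tests.
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
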