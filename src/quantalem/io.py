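"""Dataset and result files: long-format CSV plus JSON sidecars.

A response dataset is stored as a CSV with columns ``trial_id,
spike_index, spike_time_ms, amplitude_mV`` and a JSON sidecar (same stem,
``.json``) carrying the protocol, generating parameters (if synthetic),
seed and baseline noise.  Results serialize to JSON with a schema version;
floats survive a round trip bit-exactly (shortest-repr serialization).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
import numpy as np
import pandas as pd

from .core import SpikeTrain, SynapticParameters
from .simulate import ResponseDataset

__all__ = ["read_dataset", "write_dataset", "write_result", "read_result"]

SCHEMA_VERSION = 1


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_dataset(dataset: ResponseDataset, path) -> Path:
    path = Path(path)
    rows = []
    for trial_id, (spikes, resp) in enumerate(dataset.trials):
        for k in range(spikes.M):
            rows.append((trial_id, k, spikes.times[k], resp[k]))
    pd.DataFrame(
        rows, columns=["trial_id", "spike_index", "spike_time_ms", "amplitude_mV"]
    ).to_csv(path, index=False)
    meta = {"schema_version": SCHEMA_VERSION, **dataset.metadata}
    _sidecar(path).write_text(json.dumps(_jsonable(meta), indent=2))
    return path


def read_dataset(path) -> ResponseDataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trial_id", "spike_index", "spike_time_ms", "amplitude_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    trials = []
    for trial_id, sub in df.groupby("trial_id", sort=True):
        sub = sub.sort_values("spike_index")
        times = sub["spike_time_ms"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            row = int(sub.index[bad[0] + 1])
            raise ValueError(
                f"non-monotone spike times in trial {trial_id} (CSV row {row + 2})"
            )
        if not np.array_equal(sub["spike_index"].to_numpy(), np.arange(len(sub))):
            raise ValueError(f"trial {trial_id}: spike_index must be 0..M-1")
        trials.append((SpikeTrain(times), sub["amplitude_mV"].to_numpy(dtype=float)))
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        meta.pop("schema_version", None)
    else:
        warnings.warn(f"no sidecar {sc.name}; metadata defaults to empty", stacklevel=2)
    return ResponseDataset(trials, meta)


def _jsonable(obj):
    if isinstance(obj, SynapticParameters):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_result(result, path, seed=None) -> Path:
    """Serialize any result object (dataclass or dict) to versioned JSON."""
    path = Path(path)
    payload = {"schema_version": SCHEMA_VERSION}
    if seed is not None:
        payload["seed"] = seed
    body = _jsonable(result)
    if not isinstance(body, dict):
        body = {"value": body}
    payload.update(body)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_result(path) -> dict:
    return json.loads(Path(path).read_text())
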