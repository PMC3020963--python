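"""CSV + JSON sidecar import/export for sweep sets.

Dialect: a CSV whose first column is the time base in ms and whose
remaining columns are the per-sweep currents in uA (one column per sweep
level), plus a sidecar JSON carrying the protocol descriptor, construct
label, oocyte id and seed.  The sidecar lives next to the CSV with the
extension ``.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Epoch, SweepSet, VoltageProtocol

__all__ = ["save_sweepset", "load_sweepset", "sidecar_path"]


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def _protocol_to_dict(proto: VoltageProtocol) -> dict:
    return {
        "name": proto.name,
        "holding": proto.holding,
        "epochs": [[e.level, e.duration] for e in proto.epochs],
        "sweep_variable": proto.sweep_variable,
        "sweep_levels": list(proto.sweep_levels),
        "sample_interval": proto.sample_interval,
        "leak_check_level": proto.leak_check_level,
    }


def _protocol_from_dict(d: dict) -> VoltageProtocol:
    return VoltageProtocol(
        name=d["name"],
        holding=d["holding"],
        epochs=tuple(Epoch(lvl, dur) for lvl, dur in d["epochs"]),
        sweep_variable=d["sweep_variable"],
        sweep_levels=tuple(d["sweep_levels"]),
        sample_interval=d["sample_interval"],
        leak_check_level=d.get("leak_check_level"),
    )


def save_sweepset(sweep: SweepSet, csv_path) -> Path:
    """Write traces to CSV and the protocol descriptor to a JSON sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"time_ms": sweep.time}
    for s, level in enumerate(sweep.protocol.sweep_levels):
        cols[f"sweep_{s:02d}_{level:g}mV_uA"] = sweep.currents[s]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "protocol": _protocol_to_dict(sweep.protocol),
        "construct": sweep.construct_label,
        "oocyte_id": sweep.oocyte_id,
        "seed": sweep.rng_seed,
        "is_leak_subtracted": sweep.is_leak_subtracted,
    }
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return csv_path


def load_sweepset(csv_path) -> SweepSet:
    """Read a sweep set written by :func:`save_sweepset`."""
    csv_path = Path(csv_path)
    meta = json.loads(sidecar_path(csv_path).read_text())
    df = pd.read_csv(csv_path)
    time = df.iloc[:, 0].to_numpy(dtype=float)
    currents = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SweepSet(
        protocol=_protocol_from_dict(meta["protocol"]),
        time=time,
        currents=currents,
        construct_label=meta["construct"],
        oocyte_id=int(meta["oocyte_id"]),
        rng_seed=int(meta["seed"]),
        is_leak_subtracted=bool(meta["is_leak_subtracted"]),
    )
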