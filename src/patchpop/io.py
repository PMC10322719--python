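"""Delimited/JSON readers and writers for the package's data bundles.

Sweep sets are written as one single-column TSV per sweep plus a JSON
manifest (sampling rate, per-sweep amplitude/kind/step times); spike
datasets as four TSV tables (spikes, trials, events, units) plus a JSON
manifest; feature tables as TSV with a units header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_UNITS
from .simulate import SpikeDataset, Sweep, SweepSet

__all__ = [
    "write_sweep_set", "read_sweep_set",
    "write_spike_dataset", "read_spike_dataset",
    "write_feature_table", "read_feature_table",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_sweep_set(sweep_set: SweepSet, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"sampling_rate_hz": sweep_set.sampling_rate_hz,
                "meta": _jsonable(sweep_set.meta), "sweeps": []}
    for i, s in enumerate(sweep_set.sweeps):
        fname = f"sweep_{i:04d}.tsv"
        np.savetxt(out / fname, s.v_mv, fmt="%.6f")
        manifest["sweeps"].append({"file": fname, "amp_pa": s.amp_pa,
                                   "t_on_s": s.t_on_s, "t_off_s": s.t_off_s,
                                   "kind": s.kind,
                                   "spike_idx": s.spike_idx.tolist()})
    if sweep_set.spontaneous_mv is not None:
        np.savetxt(out / "spontaneous.tsv", sweep_set.spontaneous_mv, fmt="%.6f")
        manifest["spontaneous"] = "spontaneous.tsv"
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    return out


def read_sweep_set(in_dir) -> SweepSet:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    sweeps = []
    for rec in manifest["sweeps"]:
        v = np.loadtxt(src / rec["file"])
        sweeps.append(Sweep(v_mv=np.atleast_1d(v), amp_pa=rec["amp_pa"],
                            t_on_s=rec["t_on_s"], t_off_s=rec["t_off_s"],
                            kind=rec["kind"],
                            spike_idx=np.asarray(rec.get("spike_idx", []),
                                                 dtype=np.int64)))
    spont = None
    if "spontaneous" in manifest:
        spont = np.atleast_1d(np.loadtxt(src / manifest["spontaneous"]))
    return SweepSet(sampling_rate_hz=manifest["sampling_rate_hz"], sweeps=sweeps,
                    spontaneous_mv=spont, meta=manifest.get("meta", {}))


def write_spike_dataset(dataset: SpikeDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [(uid, t) for uid in dataset.unit_ids for t in dataset.spikes[uid]]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        out / "spikes.tsv", sep="\t", index=False, float_format="%.6f")
    dataset.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    dataset.events.to_csv(out / "events.tsv", sep="\t", index=False)
    dataset.units.to_csv(out / "units.tsv", sep="\t", index=False)
    manifest = {"duration_s": dataset.duration_s,
                "event_names": dataset.event_names,
                "meta": _jsonable(dataset.meta)}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    return out


def read_spike_dataset(in_dir) -> SpikeDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    spikes_df = pd.read_csv(src / "spikes.tsv", sep="\t")
    units = pd.read_csv(src / "units.tsv", sep="\t")
    spikes = {uid: np.sort(grp["time_s"].to_numpy())
              for uid, grp in spikes_df.groupby("unit_id")}
    for uid in units["unit_id"]:
        spikes.setdefault(uid, np.empty(0))
    return SpikeDataset(spikes=spikes,
                        trials=pd.read_csv(src / "trials.tsv", sep="\t"),
                        events=pd.read_csv(src / "events.tsv", sep="\t"),
                        units=units,
                        duration_s=manifest["duration_s"],
                        event_names=manifest["event_names"],
                        meta=manifest.get("meta", {}))


def write_feature_table(df: pd.DataFrame, path) -> Path:
    """TSV with a second header row carrying the per-column units."""
    path = Path(path)
    units = [FEATURE_UNITS.get(c, "-") for c in df.columns]
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        fh.write("\t".join(units) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False)
    return path


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", skiprows=[1])
    return df
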