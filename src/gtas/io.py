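"""Plain-text serialization: spike-train TSV, model JSON, run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .analytic import CumulantDensity
from .model import GTaSModel, ModelValidationError, validate_model
from .shifts import shift_from_spec
from .simulate import SpikeTrainSet

_MODEL_KEYS = {"n_trains", "mother_rate", "markings"}
_MARKING_KEYS = {"subset", "probability", "shift"}


def save_model(model: GTaSModel, path) -> None:
    doc = {
        "n_trains": model.n_trains,
        "mother_rate": model.mother_rate,
        "markings": [
            {
                "subset": list(subset),
                "probability": prob,
                "shift": model.shifts[subset].to_spec(),
            }
            for subset, prob in model.markings.items()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path) -> GTaSModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: model document must be a JSON object")
    unknown = set(doc) - _MODEL_KEYS
    if unknown:
        raise ModelValidationError(f"{path}: unknown keys {sorted(unknown)}")
    for key in _MODEL_KEYS:
        if key not in doc:
            raise ModelValidationError(f"{path}: missing field {key!r}")
    if not isinstance(doc["markings"], list):
        raise ModelValidationError(f"{path}: 'markings' must be a list")
    n = doc["n_trains"]
    if not isinstance(n, int):
        raise ModelValidationError(f"{path}: 'n_trains' must be an integer")
    if not isinstance(doc["mother_rate"], (int, float)) or isinstance(doc["mother_rate"], bool):
        raise ModelValidationError(f"{path}: 'mother_rate' must be a number")
    markings, shifts = {}, {}
    for entry in doc["markings"]:
        if not isinstance(entry, dict) or set(entry) - _MARKING_KEYS:
            raise ModelValidationError(f"{path}: malformed marking entry {entry!r}")
        for key in _MARKING_KEYS:
            if key not in entry:
                raise ModelValidationError(f"{path}: marking entry missing {key!r}")
        if not isinstance(entry["probability"], (int, float)) or isinstance(
            entry["probability"], bool
        ):
            raise ModelValidationError(
                f"{path}: marking probability must be a number, got {entry['probability']!r}"
            )
        subset = tuple(entry["subset"])
        if any(not isinstance(i, int) for i in subset):
            raise ModelValidationError(f"{path}: subset indices must be integers: {subset!r}")
        if subset in markings:
            raise ModelValidationError(f"{path}: duplicate marking {subset!r}")
        markings[subset] = entry["probability"]
        try:
            shifts[subset] = shift_from_spec(entry["shift"], n)
        except ValueError as exc:
            raise ModelValidationError(f"{path}: marking {subset!r}: {exc}") from exc
    return validate_model(n, doc["mother_rate"], markings, shifts)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def write_spikes(spikes: SpikeTrainSet, path, provenance: bool = False) -> None:
    """Two-column TSV (train_id, time) sorted by time, full float precision;
    an optional third ``marking`` bitmask column when provenance is kept."""
    if provenance and spikes.marking is None:
        raise ValueError("spike set carries no provenance")
    ids = np.concatenate(
        [np.full(t.size, i + 1, dtype=np.int64) for i, t in enumerate(spikes.trains)]
    )
    times = np.concatenate(spikes.trains) if spikes.trains else np.empty(0)
    rows = np.argsort(times, kind="stable")
    lines = [
        f"# n_trains\t{spikes.n_trains}",
        f"# window\t{spikes.t_start!r}\t{spikes.t_stop!r}",
    ]
    if provenance:
        marks = np.concatenate(spikes.marking)
        for r in rows:
            lines.append(f"{ids[r]}\t{float(times[r])!r}\t{int(marks[r])}")
    else:
        for r in rows:
            lines.append(f"{ids[r]}\t{float(times[r])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spikes(path) -> SpikeTrainSet:
    n_trains = None
    window = None
    ids, times = [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "n_trains":
                n_trains = int(parts[1])
            elif parts[0] == "window":
                window = (float(parts[1]), float(parts[2]))
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{ln}: malformed row {raw!r}")
        try:
            tid = int(parts[0])
            t = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row {raw!r}") from exc
        if tid < 1:
            raise ValueError(f"{path}:{ln}: train id must be >= 1")
        ids.append(tid)
        times.append(t)
    if n_trains is None or window is None:
        raise ValueError(f"{path}: missing '# n_trains' or '# window' header")
    if ids and max(ids) > n_trains:
        raise ValueError(f"{path}: train id {max(ids)} exceeds declared n_trains")
    ids_a = np.asarray(ids, dtype=np.int64)
    times_a = np.asarray(times, dtype=float)
    if times_a.size and (times_a.min() < window[0] or times_a.max() >= window[1]):
        raise ValueError(f"{path}: event time outside the declared window")
    trains = [np.sort(times_a[ids_a == i + 1]) for i in range(n_trains)]
    return SpikeTrainSet(n_trains, window[0], window[1], trains)


# ---------------------------------------------------------------------------
# Cumulant-density CSV
# ---------------------------------------------------------------------------

def write_density(cd: CumulantDensity, path) -> None:
    """CSV with columns ``tau_1..tau_{k-1}, value[, se]``; singular atoms in
    ``# atom`` header lines (kept symbolic, never binned)."""
    km1 = len(cd.axes)
    lines = [f"# indices\t{','.join(map(str, cd.indices))}"]
    for vec, mass in cd.atoms:
        coords = ",".join(repr(float(v)) for v in np.atleast_1d(vec))
        lines.append(f"# atom\t{coords}\t{mass!r}")
    header = [f"tau_{m + 1}" for m in range(km1)] + ["value"]
    if cd.se is not None:
        header.append("se")
    lines.append(",".join(header))
    mesh = np.meshgrid(*cd.axes, indexing="ij")
    flat = [g.ravel() for g in mesh]
    vals = cd.values.ravel()
    ses = cd.se.ravel() if cd.se is not None else None
    for i in range(vals.size):
        row = [repr(float(f[i])) for f in flat] + [repr(float(vals[i]))]
        if ses is not None:
            row.append(repr(float(ses[i])))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(out_path, seed: Optional[int] = None,
                   config_paths=(), extra: Optional[dict] = None) -> Path:
    """Emit ``<out>.manifest.json`` describing a CLI run (config hashes,
    seed, package version, argv, timestamp)."""
    hashes = {}
    for p in config_paths:
        hashes[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    doc = {
        "package": "gtas",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashes,
        "argv": sys.argv,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        doc.update(extra)
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(doc, indent=1) + "\n")
    return mpath
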