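"""File formats: keypoint tensors, labeled datasets, model checkpoints.

Keypoint payloads are (samples × 17 × 3) tensors in the package's joint
order.  Three interchangeable on-disk formats are supported:

* ``.npz``  — arrays ``poses`` and optionally ``labels``;
* ``.csv``  — long form with header ``sample_id,joint_index,x,y,z[,label]``,
  joint_index 0–16 complete for every sample;
* ``.json`` — object with ``poses`` (nested lists) and optional ``labels``.

Datasets are written as npz + long-form CSV + a JSON manifest carrying the
generator config, seed and a config hash for provenance.  Checkpoints are
single ``.npz`` files bundling model kind, config, weights and (for the GCN)
the adjacency matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .models import FFNNClassifier, FFNNConfig, GCNClassifier, GCNConfig
from .skeleton import N_JOINTS
from .synthetic import PoseDataset

CHECKPOINT_VERSION = 1


def _validate_payload(poses, source: str) -> np.ndarray:
    arr = np.asarray(poses, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (N_JOINTS, 3):
        raise FormatError(
            f"{source}: expected a (samples, 17, 3) payload, got shape {arr.shape}"
        )
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        s, j, c = bad[0]
        raise FormatError(
            f"{source}: non-finite value at sample {s}, joint {j}, coordinate {c}"
        )
    return arr


# ---------------------------------------------------------------------------
# Keypoint files
# ---------------------------------------------------------------------------

def write_keypoints(path, poses, labels=None) -> None:
    """Write a keypoint payload; format chosen from the file suffix."""
    path = Path(path)
    arr = _validate_payload(poses, str(path))
    suffix = path.suffix.lower()
    if suffix == ".npz":
        if labels is None:
            np.savez(path, poses=arr)
        else:
            np.savez(path, poses=arr, labels=np.asarray(labels, dtype=int))
    elif suffix == ".csv":
        n = arr.shape[0]
        rows = {
            "sample_id": np.repeat(np.arange(n), N_JOINTS),
            "joint_index": np.tile(np.arange(N_JOINTS), n),
            "x": arr[:, :, 0].ravel(),
            "y": arr[:, :, 1].ravel(),
            "z": arr[:, :, 2].ravel(),
        }
        if labels is not None:
            rows["label"] = np.repeat(np.asarray(labels, dtype=int), N_JOINTS)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif suffix == ".json":
        payload = {"poses": arr.tolist()}
        if labels is not None:
            payload["labels"] = [int(v) for v in labels]
        path.write_text(json.dumps(payload))
    else:
        raise ValidationError(f"unsupported keypoint format: {suffix!r}")


def read_keypoints(path):
    """Read a keypoint file; returns ``(poses, labels_or_None)``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: file is empty")
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path) as data:
            if "poses" not in data:
                raise FormatError(f"{path}: missing 'poses' array")
            poses = _validate_payload(data["poses"], str(path))
            labels = data["labels"].astype(int) if "labels" in data else None
        return poses, labels
    if suffix == ".csv":
        return _read_keypoints_csv(path)
    if suffix == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        if "poses" not in payload:
            raise FormatError(f"{path}: missing 'poses' key")
        poses = _validate_payload(payload["poses"], str(path))
        labels = (np.asarray(payload["labels"], dtype=int)
                  if "labels" in payload else None)
        return poses, labels
    raise ValidationError(f"unsupported keypoint format: {suffix!r}")


def _read_keypoints_csv(path):
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    required = {"sample_id", "joint_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sample_ids = df["sample_id"].unique()
    poses = np.empty((len(sample_ids), N_JOINTS, 3))
    labels = [] if "label" in df.columns else None
    for k, sid in enumerate(sample_ids):
        block = df[df["sample_id"] == sid]
        joints = np.sort(block["joint_index"].to_numpy())
        if not np.array_equal(joints, np.arange(N_JOINTS)):
            raise FormatError(
                f"{path}: sample {sid} does not have joints 0–16 exactly once"
            )
        block = block.set_index("joint_index").sort_index()
        poses[k] = block[["x", "y", "z"]].to_numpy()
        if labels is not None:
            lab = block["label"].unique()
            if len(lab) != 1:
                raise FormatError(f"{path}: sample {sid} has inconsistent labels")
            labels.append(int(lab[0]))
    poses = _validate_payload(poses, str(path))
    return poses, (np.asarray(labels, dtype=int) if labels is not None else None)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def config_hash(config) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_dataset(dataset: PoseDataset, basepath) -> dict:
    """Write npz + long CSV + JSON manifest; returns the file paths."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    npz = base.with_suffix(".npz")
    csv = base.with_suffix(".csv")
    manifest = base.with_suffix(".manifest.json")
    write_keypoints(npz, dataset.poses, dataset.labels)
    write_keypoints(csv, dataset.poses, dataset.labels)
    meta = {
        "n_samples": int(len(dataset)),
        "class_counts": {str(c): int(np.sum(dataset.labels == c))
                         for c in np.unique(dataset.labels)},
    }
    if dataset.config is not None:
        meta["generator_config"] = asdict(dataset.config)
        meta["seed"] = dataset.config.seed
        meta["config_hash"] = config_hash(dataset.config)
    manifest.write_text(json.dumps(meta, indent=2, default=str))
    return {"npz": npz, "csv": csv, "manifest": manifest}


def load_dataset(path) -> PoseDataset:
    """Load a labeled dataset from any supported keypoint file."""
    poses, labels = read_keypoints(path)
    if labels is None:
        raise FormatError(f"{path}: dataset file has no labels")
    return PoseDataset(poses, labels)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, extra: dict | None = None) -> None:
    """Serialize a model (kind + config + weights [+ adjacency]) to one npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": model.kind,
        "config": model.config_dict(),
        "extra": extra or {},
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    if model.kind == "gcn":
        arrays["adjacency"] = model.adjacency
    np.savez(path, meta=np.frombuffer(json.dumps(meta, default=str).encode(),
                                      dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Reconstruct a model from a checkpoint; returns ``(model, meta)``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such checkpoint")
    with np.load(path) as data:
        if "meta" not in data:
            raise FormatError(f"{path}: not a checkpoint file")
        meta = json.loads(bytes(data["meta"]).decode())
        params = {k[len("param_"):]: data[k] for k in data.files
                  if k.startswith("param_")}
        if meta["kind"] == "gcn":
            cfg = meta["config"]
            config = GCNConfig(conv_channels=tuple(cfg["conv_channels"]),
                               dense_units=cfg["dense_units"],
                               n_classes=cfg["n_classes"],
                               dropout_rate=cfg["dropout_rate"],
                               activation=cfg["activation"])
            model = GCNClassifier(data["adjacency"], config)
        elif meta["kind"] == "ffnn":
            cfg = meta["config"]
            config = FFNNConfig(hidden_units=tuple(cfg["hidden_units"]),
                                dropout_rate=cfg["dropout_rate"],
                                n_classes=cfg["n_classes"],
                                input_dim=cfg["input_dim"])
            model = FFNNClassifier(config)
        else:
            raise FormatError(f"{path}: unknown model kind {meta['kind']!r}")
    model.set_params(params)
    return model, meta
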