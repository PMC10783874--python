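"""Versioned single-archive checkpoints.

A checkpoint is one ``.npz`` holding every parameter array under
``param/<name>`` (plus optional ``head/<name>`` arrays for fine-tuned
prediction heads) and a JSON metadata record: format version, model config,
both feature schemas, the originating seed, and a SHA-256 checksum of the
weight payload.  Loading rebuilds the model from the stored config and
refuses payloads whose checksum does not match or whose schema disagrees
with the requesting caller.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .chem import FeatureSchema
from .errors import ChecksumError, SchemaError
from .model import BatmanNet, ModelConfig

__all__ = ["save_checkpoint", "load_checkpoint", "weight_payload_bytes"]

FORMAT_VERSION = 1


def _payload_digest(arrays: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name], dtype=np.float64).tobytes())
    return h.hexdigest()


def save_checkpoint(path, model: BatmanNet, heads: dict | None = None,
                    meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": v for k, v in model.state_arrays().items()}
    if heads:
        arrays.update({f"head/{k}": np.asarray(v, dtype=np.float64)
                       for k, v in heads.items()})
    record = {
        "format_version": FORMAT_VERSION,
        "config": model.config.to_dict(),
        "atom_schema": model.atom_schema.to_json(),
        "bond_schema": model.bond_schema.to_json(),
        "seed": model.seed,
        "checksum": _payload_digest(arrays),
        "extra": meta or {},
    }
    meta_bytes = np.frombuffer(json.dumps(record).encode(), dtype=np.uint8)
    np.savez(path, __meta__=meta_bytes, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path, expect_atom_schema: FeatureSchema | None = None):
    """Load a checkpoint; returns ``(model, heads, meta)``."""
    with np.load(Path(path), allow_pickle=False) as z:
        record = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    if record.get("format_version") != FORMAT_VERSION:
        raise ChecksumError(f"unsupported checkpoint version: "
                            f"{record.get('format_version')}")
    if _payload_digest(arrays) != record["checksum"]:
        raise ChecksumError("checkpoint payload does not match its checksum")
    atom_schema = FeatureSchema.from_json(record["atom_schema"])
    bond_schema = FeatureSchema.from_json(record["bond_schema"])
    if expect_atom_schema is not None and expect_atom_schema != atom_schema:
        raise SchemaError("checkpoint atom schema is incompatible")
    model = BatmanNet(ModelConfig.from_dict(record["config"]),
                      atom_schema, bond_schema, seed=record["seed"])
    model.load_state({k[len("param/"):]: v for k, v in arrays.items()
                      if k.startswith("param/")})
    heads = {k[len("head/"):]: v for k, v in arrays.items()
             if k.startswith("head/")}
    return model, heads, record


def weight_payload_bytes(path) -> bytes:
    """Canonical byte serialisation of a checkpoint's weight payload (sorted
    name order); save -> load -> save must reproduce it bit-for-bit."""
    with np.load(Path(path), allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return b"".join(np.ascontiguousarray(arrays[k], dtype=np.float64).tobytes()
                    for k in sorted(arrays))
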