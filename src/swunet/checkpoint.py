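"""Single-file weight archives with the embedded model configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import ModelConfig, SWUNet


def save_checkpoint(path, model: SWUNet, extra: dict | None = None) -> None:
    """Write weights + JSON-encoded ModelConfig (and optional metadata)."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    payload["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path, seed: int = 0):
    """Rebuild the model from an archive; returns ``(model, extra)``."""
    path = Path(path)
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        state = {
            k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")
        }
    cfg = ModelConfig.from_dict(meta["config"])
    model = SWUNet(cfg, seed=seed)
    model.load_state_dict(state)
    return model, meta.get("extra", {})
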