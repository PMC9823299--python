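"""Model checkpoint serialisation (.npz: weights + JSON config)."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .codec import GraphContext
from .graph_ae import GraphAE, NaiveAE, TrainConfig, featurize

__all__ = ["save_model", "load_model"]


def save_model(model, ctx: GraphContext, path):
    meta = {
        "variant": model.variant,
        "cfg": asdict(model.cfg),
        "fingerprint": ctx.fingerprint,
        "in_dim": model.encoder.layers[0].w.shape[0],
    }
    arrays = {f"p{k}": p.data for k, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_model(path, ctx: GraphContext):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"p{k}"] for k in range(len(z.files) - 1)]
    if meta["fingerprint"] != ctx.fingerprint:
        raise ValueError("checkpoint was trained on a different molecule")
    cfg = TrainConfig(**meta["cfg"])
    if meta["variant"] == "graph_ae":
        model = GraphAE(featurize(ctx.g, ctx), in_dim=meta["in_dim"], cfg=cfg)
    else:
        model = NaiveAE(in_dim=meta["in_dim"], cfg=cfg)
    for p, d in zip(model.params, arrays):
        p.data = d
    return model
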