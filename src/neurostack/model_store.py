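"""Save/load a fitted stacked ensemble as a plain-text model directory.

Layout::

    model_dir/
      manifest.json             meta algorithm, encoder list, threshold
      base_<encoder>.json       CNNConfig + weights + channel standardizer
      embedding.tsv             token, v1..vd
      gnb.json                  GNB priors/means/variances/smoothing
      meta_background.tsv       meta-feature training matrix (for SHAP)

Only the Gaussian naive Bayes meta-learner round-trips (it is the
deliverable model); the delegated comparison meta-learners are transient.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .cnn_base import CNNConfig, TrainedBaseModel, build_cnn
from .encoders import ALPHABET21, EmbeddingTable, GGapConfig
from .stacking import (
    GNBModel,
    GNBParams,
    META_FEATURE_ORDER,
    StackedModel,
)

_INPUT_SHAPES = {"onehot": (100, 20), "aaindex": (100, 14), "ggap": (440, 10)}


def save_stacked(model: StackedModel, model_dir: str | Path) -> None:
    if model.meta_algorithm != "gnb" or not isinstance(model.meta, GNBModel):
        raise NotImplementedError(
            "only the GNB-stacked ensemble serializes; comparison meta-learners are transient"
        )
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)

    for encoder_id, base in model.base_models.items():
        payload = {
            "config": asdict(base.config),
            "weights": [w.tolist() for w in base.net.get_weights()],
            "channel_mean": base.channel_mean.tolist(),
            "channel_std": base.channel_std.tolist(),
            "input_shape": [base.net.in_len, base.net.in_ch],
        }
        (model_dir / f"base_{encoder_id}.json").write_text(json.dumps(payload))

    emb = model.embedding_table
    lines = ["token\t" + "\t".join(f"v{i+1}" for i in range(emb.d))]
    for tok in ALPHABET21:
        vec = np.asarray(emb.token_vectors[tok])
        lines.append(tok + "\t" + "\t".join(f"{v:.10g}" for v in vec))
    (model_dir / "embedding.tsv").write_text("\n".join(lines) + "\n")

    params = model.meta.params
    (model_dir / "gnb.json").write_text(json.dumps({
        "class_priors": params.class_priors.tolist(),
        "means": params.means.tolist(),
        "variances": params.variances.tolist(),
        "var_smoothing": params.var_smoothing,
    }))

    if model.meta_train_X is not None:
        rows = ["\t".join(f"{v:.10g}" for v in row) for row in model.meta_train_X]
        (model_dir / "meta_background.tsv").write_text("\n".join(rows) + "\n")

    (model_dir / "manifest.json").write_text(json.dumps({
        "meta_algorithm": model.meta_algorithm,
        "encoders": list(META_FEATURE_ORDER),
        "decision_threshold": model.decision_threshold,
        "ggap_g": model.ggap_config.g,
        "ggap_count_cap": model.ggap_config.count_cap,
        "embedding_dim": emb.d,
        "embedding_params": list(emb.training_params),
    }, indent=2))


def load_stacked(model_dir: str | Path) -> StackedModel:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())

    base_models = {}
    for encoder_id in META_FEATURE_ORDER:
        payload = json.loads((model_dir / f"base_{encoder_id}.json").read_text())
        cfg_dict = payload["config"]
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        config = CNNConfig(**cfg_dict)
        net = build_cnn(config, tuple(payload["input_shape"]))
        net.set_weights([np.asarray(w) for w in payload["weights"]])
        base_models[encoder_id] = TrainedBaseModel(
            config=config,
            net=net,
            channel_mean=np.asarray(payload["channel_mean"]),
            channel_std=np.asarray(payload["channel_std"]),
        )

    emb_lines = (model_dir / "embedding.tsv").read_text().splitlines()
    d = len(emb_lines[0].split("\t")) - 1
    vectors = {}
    for line in emb_lines[1:]:
        parts = line.split("\t")
        vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
    table = EmbeddingTable(
        token_vectors=vectors, d=d,
        training_params=tuple(tuple(p) for p in manifest.get("embedding_params", [])),
    )

    gnb_raw = json.loads((model_dir / "gnb.json").read_text())
    meta = GNBModel(var_smoothing=gnb_raw["var_smoothing"])
    meta.params = GNBParams(
        class_priors=np.asarray(gnb_raw["class_priors"]),
        means=np.asarray(gnb_raw["means"]),
        variances=np.asarray(gnb_raw["variances"]),
        var_smoothing=gnb_raw["var_smoothing"],
    )

    meta_X = None
    bg = model_dir / "meta_background.tsv"
    if bg.exists():
        meta_X = np.array([
            [float(v) for v in line.split("\t")]
            for line in bg.read_text().splitlines() if line.strip()
        ])

    return StackedModel(
        base_models=base_models,
        embedding_table=table,
        meta=meta,
        meta_algorithm=manifest["meta_algorithm"],
        ggap_config=GGapConfig(g=manifest["ggap_g"], count_cap=manifest["ggap_count_cap"]),
        decision_threshold=manifest["decision_threshold"],
        meta_train_X=meta_X,
    )
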