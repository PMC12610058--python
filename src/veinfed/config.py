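"""Run configuration: one YAML file describes a full reproducible run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .federation import FederationConfig
from .head import MarginParams
from .preprocess import QualityIndicatorParams
from .synthetic import ClientSpec, SyntheticFederationSpec

__all__ = ["RunConfig", "load_config", "save_config", "default_desk_config"]


@dataclass
class RunConfig:
    """Everything needed to regenerate data, train and evaluate a run."""

    data_root: str = "data"
    output_dir: str = "out"
    federation_spec: SyntheticFederationSpec | None = None
    training: FederationConfig = field(default_factory=FederationConfig)
    split_ratio: float = 0.8
    split_seed: int = 0
    far_target: float = 0.01
    seed: int = 0


def default_desk_config(seed: int = 0) -> RunConfig:
    """The package's desk-scale reference study: 4 heterogeneous clients.

    Class counts 12/10/8/6 with 6 samples per class, 64x128 images, one
    vertically-oriented low-contrast noisy client — a miniature of the
    multi-organization heterogeneity the method targets.
    """
    spec = SyntheticFederationSpec(
        clients=(
            ClientSpec(n_classes=12, samples_per_class=6),
            ClientSpec(n_classes=10, samples_per_class=6, contrast_level=0.8,
                       noise_sd=6.0),
            ClientSpec(n_classes=8, samples_per_class=6, image_height=128,
                       image_width=64, orientation="vertical",
                       illumination_offset=-15.0),
            ClientSpec(n_classes=6, samples_per_class=6, contrast_level=0.6,
                       noise_sd=8.0, illumination_offset=10.0),
        ),
        master_seed=seed,
    )
    training = FederationConfig(
        n_rounds=15,
        local_epochs=3,
        batch_size=32,
        learning_rate=0.05,
        momentum=0.9,
        margin=MarginParams(margin=0.4, scale=16.0),
        embedding_dim=64,
        seed=seed,
    )
    return RunConfig(
        federation_spec=spec, training=training, split_seed=seed, seed=seed
    )


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    spec = None
    if raw.get("federation_spec"):
        fs = raw["federation_spec"]
        spec = SyntheticFederationSpec(
            clients=tuple(ClientSpec(**c) for c in fs["clients"]),
            master_seed=fs.get("master_seed", 0),
            shared_class_fraction=fs.get("shared_class_fraction", 0.0),
        )
    tr_raw = dict(raw.get("training", {}))
    margin = MarginParams(**tr_raw.pop("margin", {}))
    quality = QualityIndicatorParams(**tr_raw.pop("quality", {}))
    training = FederationConfig(margin=margin, quality=quality, **tr_raw)
    return RunConfig(
        data_root=raw.get("data_root", "data"),
        output_dir=raw.get("output_dir", "out"),
        federation_spec=spec,
        training=training,
        split_ratio=raw.get("split_ratio", 0.8),
        split_seed=raw.get("split_seed", 0),
        far_target=raw.get("far_target", 0.01),
        seed=raw.get("seed", 0),
    )
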