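"""Federated orchestration: client updates, server aggregation, rounds.

Each communication round, every client (i) loads the global encoder,
(ii) widens its head with the prototype columns received from the server,
(iii) runs local mini-batch SGD on the prototype-margin loss, and
(iv) uploads its new encoder parameters and freshly computed prototypes.
The server averages encoder parameters with sample-count-proportional
weights and aggregates prototypes per class; personal heads W_k never
cross the wire.

The first round bootstraps with no prototype columns (none exist yet);
prototypes first circulate in round 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoder import (
    EncoderContract,
    Prototype,
    PrototypeSet,
    SmallConvEncoder,
    compute_prototypes,
)
from .head import (
    ExpandedWeightMatrix,
    MarginParams,
    expand_weight_matrix,
    init_weight_matrix,
    loss_and_grads,
)
from .preprocess import (
    QualityIndicatorParams,
    SobelConfig,
    batch_quality_indicator,
    compute_quality_records,
    enhance_image,
)
from .synthetic import ClientDataset, VeinImage

__all__ = [
    "FederationConfig",
    "ClientState",
    "ServerState",
    "FederationHistory",
    "prepare_client",
    "client_update",
    "aggregate_models",
    "aggregate_prototypes",
    "run_federation",
    "run_local_baseline",
    "communication_cost",
]


@dataclass
class FederationConfig:
    """Knobs of a federated (or local-baseline) training run."""

    n_rounds: int = 15
    local_epochs: int = 1
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    margin: MarginParams = field(default_factory=MarginParams)
    quality: QualityIndicatorParams = field(default_factory=QualityIndicatorParams)
    gradient_threshold: float = 100.0
    embedding_dim: int = 64
    seed: int = 0
    prototype_distribution: str = "all"  # or "exclude_own"
    # ablation switches
    prototype_sharing: bool = True
    quality_margin: bool = True  # enhancement + adaptive margin
    # printed-form variants
    literal_class_count_weights: bool = False
    normalized_prototype_aggregation: bool = False

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.prototype_distribution not in ("all", "exclude_own"):
            raise ValueError("prototype_distribution must be 'all' or 'exclude_own'")


@dataclass
class ClientState:
    """Everything a client holds between rounds (never shared)."""

    client_id: int
    images: list[VeinImage]  # training split, enhanced if quality_margin
    labels: np.ndarray
    pixels: np.ndarray  # (n, H, W) float stack actually fed to the encoder
    sample_quality: np.ndarray  # per-sample class quality score Q
    w_local: np.ndarray  # trainable head block
    local_labels: list[int]
    quality_records: dict
    n_samples: int
    velocity: dict | None = None  # momentum state, persists across rounds

    def images_enhanced(self) -> list[VeinImage]:
        """Training samples as VeinImages over the preprocessed pixel stack."""
        return [
            VeinImage(
                pixels=self.pixels[i],
                client_id=self.client_id,
                class_label=int(self.labels[i]),
                orientation=self.images[i].orientation,
            )
            for i in range(self.n_samples)
        ]


@dataclass
class ServerState:
    encoder_params: np.ndarray
    prototypes: PrototypeSet
    d: int


@dataclass
class FederationHistory:
    """Per-round per-client mean training losses plus final state."""

    records: list[dict]
    server: ServerState
    clients: list[ClientState]
    round_prototypes: list[PrototypeSet]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def loss(self, round_idx: int, client_id: int) -> float:
        for r in self.records:
            if r["round"] == round_idx and r["client"] == client_id:
                return r["mean_loss"]
        raise KeyError((round_idx, client_id))


def prepare_client(
    dataset: ClientDataset,
    config: FederationConfig,
    rng: np.random.Generator,
) -> ClientState:
    """One-off preprocessing pass: enhancement, quality records, head init.

    With ``quality_margin`` disabled (the fixed-margin ablation) raw
    images are used and every class gets the neutral quality score.
    """
    if not dataset.images:
        raise ValueError(f"client {dataset.client_id} has an empty training split")
    sobel = SobelConfig(
        orientation=dataset.spec.orientation,
        gradient_threshold=config.gradient_threshold,
    )
    if config.quality_margin:
        records = compute_quality_records(dataset, sobel, config.quality)
        pixels = np.stack(
            [enhance_image(im, sobel)[0] for im in dataset.images]
        )
        quality = np.array(
            [records[im.class_label].quality for im in dataset.images]
        )
    else:
        records = {}
        pixels = np.stack([im.pixels.astype(float) for im in dataset.images])
        quality = np.full(len(dataset.images), 50.0)

    local_labels = dataset.classes()
    w_local = init_weight_matrix(rng, config.embedding_dim, len(local_labels))
    return ClientState(
        client_id=dataset.client_id,
        images=dataset.images,
        labels=dataset.labels,
        pixels=pixels,
        sample_quality=quality,
        w_local=w_local,
        local_labels=local_labels,
        quality_records=records,
        n_samples=len(dataset.images),
    )


def _sgd_step(params, grads, velocity, lr, momentum):
    for k, g in grads.items():
        v = velocity.get(k)
        v = momentum * v - lr * g if v is not None else -lr * g
        velocity[k] = v
        params[k] = params[k] + v
    return params


def client_update(
    state: ClientState,
    global_params: np.ndarray,
    prototype_blocks: list[tuple[int, np.ndarray, list[int]]],
    config: FederationConfig,
    rng: np.random.Generator,
    encoder: SmallConvEncoder | None = None,
) -> tuple[np.ndarray, PrototypeSet, list[float]]:
    """One round of local training; returns (new params, prototypes, epoch losses).

    The encoder starts from the global parameters; the expanded head is
    rebuilt from this round's prototype blocks.  Frozen prototype columns
    are bitwise untouched by the optimizer.
    """
    if encoder is None:
        encoder = SmallConvEncoder(seed=0, d=config.embedding_dim)
    encoder.set_flat_params(global_params)

    blocks = prototype_blocks if config.prototype_sharing else []
    expanded = expand_weight_matrix(
        state.w_local, state.local_labels, state.client_id, blocks
    )
    n = state.n_samples
    if state.velocity is None:
        state.velocity = {}
    velocity = state.velocity
    epoch_losses: list[float] = []
    for _ in range(config.local_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            z, cache = encoder.forward(state.pixels[idx])
            znorm = np.linalg.norm(z, axis=1, keepdims=True)
            emb = z / znorm
            if config.quality_margin:
                q_hat = batch_quality_indicator(
                    state.sample_quality[idx], config.quality
                )
            else:
                q_hat = np.zeros(idx.size)
            targets = expanded.label_to_column(state.labels[idx])
            loss, d_emb, d_w = loss_and_grads(
                emb, expanded, targets, q_hat, config.margin
            )
            # back through embedding normalization
            dz = (d_emb - emb * np.sum(d_emb * emb, axis=1, keepdims=True)) / znorm
            grads = encoder.backward(cache, dz)
            grads["__w_local__"] = d_w
            params = dict(encoder.params)
            params["__w_local__"] = expanded.w_local
            _sgd_step(
                params, grads, velocity, config.learning_rate, config.momentum
            )
            expanded.w_local = params.pop("__w_local__")
            encoder.params.update(params)
            batch_losses.append(loss)
        epoch_losses.append(float(np.mean(batch_losses)))

    state.w_local = expanded.w_local
    protos = compute_prototypes(encoder, state.images_enhanced(), state.client_id)
    return encoder.get_flat_params(), protos, epoch_losses


def aggregate_models(
    params_list: list[np.ndarray],
    sample_counts: list[int],
    literal_class_count_weights: bool = False,
    total_classes: int | None = None,
) -> np.ndarray:
    """Sample-count-weighted average of encoder parameter vectors.

    Default weights are |D_k| / sum_j |D_j| (they sum to 1).  The literal
    variant divides by the federation's total class count instead, for
    study; its weights do not sum to 1.
    """
    if not params_list:
        raise ValueError("nothing to aggregate")
    shapes = {p.shape for p in params_list}
    if len(shapes) != 1:
        raise ValueError("parameter vectors disagree in shape")
    counts = np.asarray(sample_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("sample counts must be positive")
    if literal_class_count_weights:
        if not total_classes:
            raise ValueError("literal weighting needs the total class count")
        weights = counts / float(total_classes)
    else:
        weights = counts / counts.sum()
    out = np.zeros_like(params_list[0])
    for w, p in zip(weights, params_list):
        out += w * p
    return out


def aggregate_prototypes(
    prototype_sets: list[PrototypeSet],
    normalized: bool = False,
    class_totals: dict[int, int] | None = None,
) -> PrototypeSet:
    """Per-class aggregation; every owner's entry is replaced by the mean.

    For class j owned by the client set CS_j with per-owner counts
    |D_k^j| and N_j = sum |D_k^j|:

        S-bar_j = (1/|CS_j|) * sum_{k in CS_j} (|D_k^j| / N_j) S_k^j

    The leading 1/|CS_j| is kept as printed (multi-owner prototypes
    shrink in norm); ``normalized=True`` drops it so the weights sum
    to 1.  Prototype count is conserved: one entry per (client, class)
    pair, single-owner prototypes pass through bit-identically.
    """
    by_class: dict[int, list[Prototype]] = {}
    for ps in prototype_sets:
        for p in ps.prototypes:
            by_class.setdefault(p.class_label, []).append(p)

    out: list[Prototype] = []
    for label, owners in by_class.items():
        n_j = sum(p.n_samples for p in owners)
        if class_totals is not None and class_totals.get(label) != n_j:
            raise ValueError(
                f"class {label}: uploaded counts sum to {n_j}, expected "
                f"{class_totals.get(label)}"
            )
        if len(owners) == 1:
            agg = owners[0].vector  # exact single-owner identity
        else:
            agg = sum((p.n_samples / n_j) * p.vector for p in owners)
            if not normalized:
                agg = agg / len(owners)
        for p in owners:
            out.append(
                Prototype(
                    class_label=label,
                    client_id=p.client_id,
                    vector=np.array(agg, dtype=float),
                    n_samples=p.n_samples,
                )
            )
    before = sum(len(ps) for ps in prototype_sets)
    assert len(out) == before, "prototype count must be conserved"
    return PrototypeSet(out)


def _blocks_for_client(
    global_protos: PrototypeSet, client_id: int, distribution: str
) -> list[tuple[int, np.ndarray, list[int]]]:
    """Group the global prototype set into per-owner (d x N_a) blocks."""
    by_owner: dict[int, list[Prototype]] = {}
    for p in global_protos.prototypes:
        if distribution == "exclude_own" and p.client_id == client_id:
            continue
        by_owner.setdefault(p.client_id, []).append(p)
    blocks = []
    for owner in sorted(by_owner):
        protos = sorted(by_owner[owner], key=lambda p: p.class_label)
        mat = np.stack([p.vector for p in protos], axis=1)
        blocks.append((owner, mat, [p.class_label for p in protos]))
    return blocks


def run_federation(
    config: FederationConfig, datasets: list[ClientDataset]
) -> FederationHistory:
    """Multi-round synchronous federated training over all clients.

    Fully deterministic for a given config: all randomness (head init,
    batch shuffling) derives from ``config.seed``.
    """
    if not datasets:
        raise ValueError("need at least one client dataset")
    ss = np.random.SeedSequence(config.seed)
    init_ss, *client_ss = ss.spawn(1 + len(datasets))
    clients = [
        prepare_client(ds, config, np.random.default_rng(child))
        for ds, child in zip(datasets, ss.spawn(len(datasets) + 1)[1:])
    ]
    shuffle_rngs = [np.random.default_rng(c) for c in client_ss]

    encoder = SmallConvEncoder(seed=int(init_ss.generate_state(1)[0] % 2**31), d=config.embedding_dim)
    global_params = encoder.get_flat_params()
    global_protos = PrototypeSet([])

    records: list[dict] = []
    round_protos: list[PrototypeSet] = []
    for rnd in range(1, config.n_rounds + 1):
        new_params, new_protos = [], []
        for state, rng in zip(clients, shuffle_rngs):
            blocks = _blocks_for_client(
                global_protos, state.client_id, config.prototype_distribution
            )
            params_k, protos_k, losses = client_update(
                state, global_params, blocks, config, rng, encoder
            )
            new_params.append(params_k)
            new_protos.append(protos_k)
            records.append(
                {
                    "round": rnd,
                    "client": state.client_id,
                    "mean_loss": float(np.mean(losses)),
                }
            )
        total_classes = sum(len(c.local_labels) for c in clients)
        global_params = aggregate_models(
            new_params,
            [c.n_samples for c in clients],
            config.literal_class_count_weights,
            total_classes,
        )
        global_protos = aggregate_prototypes(
            new_protos, config.normalized_prototype_aggregation
        )
        round_protos.append(global_protos)

    server = ServerState(
        encoder_params=global_params, prototypes=global_protos, d=config.embedding_dim
    )
    return FederationHistory(records, server, clients, round_protos)


def run_local_baseline(
    config: FederationConfig, datasets: list[ClientDataset]
) -> tuple[list[np.ndarray], FederationHistory]:
    """Independent per-client training with the same total budget.

    Each client trains alone with the plain (no prototype columns)
    margin loss for ``n_rounds * local_epochs`` epochs; nothing is
    shared.  Returns per-client final encoder parameters.
    """
    local_cfg = replace(
        config, prototype_sharing=False, n_rounds=1,
        local_epochs=config.n_rounds * config.local_epochs,
    )
    ss = np.random.SeedSequence(config.seed)
    init_ss, *client_ss = ss.spawn(1 + len(datasets))
    records: list[dict] = []
    param_list: list[np.ndarray] = []
    clients: list[ClientState] = []
    for ds, child, prep in zip(
        datasets, client_ss, ss.spawn(len(datasets) + 1)[1:]
    ):
        state = prepare_client(ds, config, np.random.default_rng(prep))
        encoder = SmallConvEncoder(
            seed=int(init_ss.generate_state(1)[0] % 2**31), d=config.embedding_dim
        )
        params, _, losses = client_update(
            state,
            encoder.get_flat_params(),
            [],
            local_cfg,
            np.random.default_rng(child),
            encoder,
        )
        for ep, lo in enumerate(losses, start=1):
            records.append({"round": ep, "client": ds.client_id, "mean_loss": lo})
        param_list.append(params)
        clients.append(state)
    server = ServerState(
        encoder_params=param_list[0], prototypes=PrototypeSet([]), d=config.embedding_dim
    )
    return param_list, FederationHistory(records, server, clients, [])


def communication_cost(
    train_class_counts: list[int],
    d: int = 512,
    distribution: str = "all",
    unit: float = 2**20,
) -> pd.DataFrame:
    """Per-round prototype traffic per client, in ``unit`` parameters.

    Upload: each client sends one d-vector per training class.  Download:
    under ``all`` every client receives the full global prototype set;
    under ``exclude_own`` its own classes are omitted.  The encoder's
    parameter payload is identical for every method and reported by the
    caller alongside.
    """
    total = sum(train_class_counts)
    rows = []
    for k, n_k in enumerate(train_class_counts):
        upload = n_k * d / unit
        down_classes = total if distribution == "all" else total - n_k
        rows.append(
            {
                "client": k,
                "train_classes": n_k,
                "upload": upload,
                "download": down_classes * d / unit,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_upload"] = float(df["upload"].mean())
    df.attrs["mean_download"] = float(df["download"].mean())
    return df
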