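"""Prototype-expanded margin classification head.

Each client owns a trainable weight matrix W_k whose unit columns act as
centers for its own classes.  Before local training, W_k is widened with
the *prototype* columns of every other client's classes, received from
the server: the sample must now be pulled toward its own column while
being pushed away not only from the client's other classes but also from
every class anywhere in the federation.  Prototype columns are frozen —
they are other clients' property — and only W_k receives updates.

The target logit carries a quality-adaptive margin.  With per-sample
batch-standardized quality Q-hat in [-1, 1] and base margin m:

    g_angle = -m * Q-hat          (angular-space margin)
    g_add   =  m * Q-hat + m      (cosine-space additive margin)
    f(theta_y) = s * (cos(theta_y + g_angle) - g_add)

so low-quality samples (Q-hat -> -1) are penalized in angle and
high-quality ones (Q-hat -> +1) in cosine, interpolating between the two
classic margin constructions; Q-hat = 0 gives the plain fixed additive
margin.  Non-target logits are s * cos(theta_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "MarginParams",
    "ExpandedWeightMatrix",
    "init_weight_matrix",
    "expand_weight_matrix",
    "similarity",
    "margins_from_quality",
    "target_logit",
    "prototype_margin_loss",
    "loss_and_grads",
]

_COS_EPS = 1e-7


@dataclass
class MarginParams:
    """Base margin m, logit scale s, and the margin-placement switch.

    ``literal_form=True`` applies the margin as the affine expression
    s*(cos(theta) + g_angle - g_add) instead of placing the angular term
    inside the cosine; shipped for comparison studies.
    """

    margin: float = 0.4
    scale: float = 64.0
    literal_form: bool = False

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def init_weight_matrix(rng: np.random.Generator, d: int, n_classes: int) -> np.ndarray:
    """Random d x N_k matrix with unit columns."""
    w = rng.normal(size=(d, n_classes))
    return w / np.linalg.norm(w, axis=0, keepdims=True)


@dataclass
class ExpandedWeightMatrix:
    """W'_k = (P_1 ... P_{k-1}  W_k  P_{k+1} ... P_m) with a column map.

    ``w_local`` is the live trainable block (raw, normalized on use);
    prototype columns are stored unit-norm and never modified.
    """

    w_local: np.ndarray  # (d, N_k), trainable
    local_labels: list[int]
    client_id: int
    proto_cols: np.ndarray  # (d, N - N_k), frozen, unit columns
    col_client: np.ndarray  # (N,) owning client per column
    col_label: np.ndarray  # (N,) class label per column
    is_local: np.ndarray  # (N,) bool
    local_start: int  # column offset of the local block

    @property
    def d(self) -> int:
        return self.w_local.shape[0]

    @property
    def n_columns(self) -> int:
        return self.col_label.size

    @property
    def n_local(self) -> int:
        return self.w_local.shape[1]

    def label_to_column(self, labels: np.ndarray) -> np.ndarray:
        """Map local class labels to global column indices."""
        lut = {lab: self.local_start + j for j, lab in enumerate(self.local_labels)}
        try:
            return np.array([lut[int(l)] for l in labels])
        except KeyError as exc:
            raise KeyError(f"label {exc} is not a local class") from exc

    def matrix(self) -> np.ndarray:
        """Full d x N matrix with every column unit-normalized."""
        wn = self.w_local / np.linalg.norm(self.w_local, axis=0, keepdims=True)
        if self.proto_cols.shape[1] == 0:
            return wn
        left = self.proto_cols[:, : self.local_start]
        right = self.proto_cols[:, self.local_start :]
        return np.concatenate([left, wn, right], axis=1)


def expand_weight_matrix(
    w_local: np.ndarray,
    local_labels: list[int],
    client_id: int,
    prototype_blocks: list[tuple[int, np.ndarray, list[int]]],
) -> ExpandedWeightMatrix:
    """Assemble W'_k from W_k and other clients' prototype blocks.

    ``prototype_blocks`` holds (owner client id, d x N_a matrix, labels);
    blocks are laid out in ascending client id with the local block at
    its own position.  Duplicate (client, class) keys and row-dimension
    mismatches are rejected.
    """
    d = w_local.shape[0]
    if w_local.shape[1] != len(local_labels):
        raise ValueError("w_local column count must match local_labels")
    entries: list[tuple[int, np.ndarray | None, list[int]]] = [
        (client_id, None, list(local_labels))
    ]
    for owner, mat, labels in prototype_blocks:
        if owner == client_id:
            continue  # own prototypes never displace the trainable block
        mat = np.asarray(mat, dtype=float)
        if mat.shape[0] != d:
            raise ValueError(
                f"prototype block of client {owner} has row dim {mat.shape[0]}, "
                f"expected {d}"
            )
        if mat.shape[1] != len(labels):
            raise ValueError("prototype block width must match its label list")
        entries.append((owner, mat, list(labels)))
    entries.sort(key=lambda e: e[0])

    seen: set[tuple[int, int]] = set()
    col_client, col_label, is_local = [], [], []
    proto_parts = []
    local_start = -1
    offset = 0
    for owner, mat, labels in entries:
        for lab in labels:
            key = (owner, lab)
            if key in seen:
                raise ValueError(f"duplicate (client, class) key {key}")
            seen.add(key)
        n_cols = len(labels)
        col_client.extend([owner] * n_cols)
        col_label.extend(labels)
        if mat is None:
            local_start = offset
            is_local.extend([True] * n_cols)
        else:
            is_local.extend([False] * n_cols)
            proto_parts.append(mat)
        offset += n_cols

    proto_cols = (
        np.concatenate(proto_parts, axis=1) if proto_parts else np.zeros((d, 0))
    )
    return ExpandedWeightMatrix(
        w_local=w_local,
        local_labels=list(local_labels),
        client_id=client_id,
        proto_cols=proto_cols,
        col_client=np.array(col_client),
        col_label=np.array(col_label),
        is_local=np.array(is_local, dtype=bool),
        local_start=local_start,
    )


def similarity(embeddings: np.ndarray, expanded: ExpandedWeightMatrix) -> np.ndarray:
    """Cosine similarity matrix: rows = batch samples, cols = global classes."""
    s = np.asarray(embeddings, dtype=float) @ expanded.matrix()
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite similarity entries")
    return s


def margins_from_quality(q_hat, margin: float):
    """(g_angle, g_add) = (-m*Q-hat, m*Q-hat + m)."""
    q_hat = np.asarray(q_hat, dtype=float)
    return -margin * q_hat, margin * q_hat + margin


def target_logit(cos_theta, q_hat, params: MarginParams):
    """Margin-penalized logit for the true-class column."""
    cos_theta = np.asarray(cos_theta, dtype=float)
    g_angle, g_add = margins_from_quality(q_hat, params.margin)
    if params.literal_form:
        return params.scale * (cos_theta + g_angle - g_add)
    theta = np.arccos(np.clip(cos_theta, -1.0 + _COS_EPS, 1.0 - _COS_EPS))
    ang = np.clip(theta + g_angle, 0.0, np.pi)
    return params.scale * (np.cos(ang) - g_add)


def _target_logit_and_dcos(cos_theta, q_hat, params: MarginParams):
    """Target logit plus its derivative w.r.t. cos(theta)."""
    cos_theta = np.asarray(cos_theta, dtype=float)
    g_angle, g_add = margins_from_quality(q_hat, params.margin)
    if params.literal_form:
        f = params.scale * (cos_theta + g_angle - g_add)
        return f, np.full_like(cos_theta, params.scale)
    cc = np.clip(cos_theta, -1.0 + _COS_EPS, 1.0 - _COS_EPS)
    theta = np.arccos(cc)
    raw = theta + g_angle
    ang = np.clip(raw, 0.0, np.pi)
    f = params.scale * (np.cos(ang) - g_add)
    # d cos(ang)/d cos(theta) = sin(ang)/sin(theta); zero where the clamp binds
    sin_theta = np.sqrt(1.0 - cc * cc)
    inside = (raw > 0.0) & (raw < np.pi)
    dcos = np.where(inside, params.scale * np.sin(ang) / sin_theta, 0.0)
    return f, dcos


def prototype_margin_loss(
    sim: np.ndarray,
    target_cols: np.ndarray,
    q_hat: np.ndarray,
    params: MarginParams,
    expanded: ExpandedWeightMatrix,
    return_grad: bool = True,
):
    """Mean margin cross-entropy over the batch, and d(loss)/d(similarity).

    Per sample i with target column y:

        L_i = -log  e^{f(theta_y)} / ( e^{f(theta_y)}
               + sum_{local j != y} e^{s cos theta_j}
               + sum_{prototype J} e^{s cos phi_J} )

    Prototype columns can never be targets.  When classes are shared
    across clients, prototype columns carrying the sample's own label are
    excluded from the denominator.  The gradient w.r.t. the similarity
    matrix is returned so the caller can chain into embeddings and the
    local weight block (prototype columns stay frozen by construction).
    """
    sim = np.asarray(sim, dtype=float)
    n, n_cols = sim.shape
    target_cols = np.asarray(target_cols)
    q_hat = np.asarray(q_hat, dtype=float)
    if np.any(q_hat < -1.0 - 1e-12) or np.any(q_hat > 1.0 + 1e-12):
        raise ValueError("q_hat must lie in [-1, 1]")
    if not np.all(expanded.is_local[target_cols]):
        raise ValueError("a target label points at a frozen prototype column")

    rows = np.arange(n)
    logits = params.scale * sim
    f_y, df_y = _target_logit_and_dcos(sim[rows, target_cols], q_hat, params)
    logits[rows, target_cols] = f_y

    # exclude prototype columns that duplicate the sample's own class
    target_labels = expanded.col_label[target_cols]
    excluded = (~expanded.is_local[None, :]) & (
        expanded.col_label[None, :] == target_labels[:, None]
    )
    logits = np.where(excluded, -np.inf, logits)

    lse = logsumexp(logits, axis=1)
    losses = lse - logits[rows, target_cols]
    loss = float(losses.mean())
    if not np.isfinite(loss):
        raise ValueError("non-finite loss")
    if not return_grad:
        return loss, None

    p = softmax(logits, axis=1)
    dlogits = p.copy()
    dlogits[rows, target_cols] -= 1.0
    dlogits /= n
    dsim = dlogits * params.scale
    dsim[rows, target_cols] = dlogits[rows, target_cols] * df_y
    dsim[excluded] = 0.0
    return loss, dsim


def loss_and_grads(
    embeddings: np.ndarray,
    expanded: ExpandedWeightMatrix,
    target_cols: np.ndarray,
    q_hat: np.ndarray,
    params: MarginParams,
):
    """Loss plus gradients w.r.t. the (unit) embeddings and raw W_k.

    The embedding gradient flows through every column (including frozen
    prototypes — repulsion from them still shapes the encoder); the
    weight gradient exists only for the local block and is chained
    through its column normalization.
    """
    emb = np.asarray(embeddings, dtype=float)
    sim = similarity(emb, expanded)
    loss, dsim = prototype_margin_loss(sim, target_cols, q_hat, params, expanded)

    w_full = expanded.matrix()
    d_emb = dsim @ w_full.T

    sl = slice(expanded.local_start, expanded.local_start + expanded.n_local)
    d_wn = emb.T @ dsim[:, sl]  # gradient w.r.t. normalized local columns
    w = expanded.w_local
    norms = np.linalg.norm(w, axis=0, keepdims=True)
    wn = w / norms
    # chain through column normalization: (I - n n^T)/||w||
    d_w = (d_wn - wn * np.sum(d_wn * wn, axis=0, keepdims=True)) / norms
    return loss, d_emb, d_w
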