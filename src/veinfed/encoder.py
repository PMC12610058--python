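"""Trainable embedding encoders and per-class prototypes.

The federation shares only the *encoder* — the map from an image to a
d-dimensional unit embedding — while every client keeps its own
classification head.  Any object satisfying :class:`EncoderContract` can
play that role; the shipped :class:`SmallConvEncoder` is a deliberately
tiny convolutional network (three conv blocks, global pooling, one linear
projection) with hand-written gradients, sized so that full federated
runs complete in minutes on one CPU core.  Heavier backbones plug in
through the same contract.

A class *prototype* is the re-normalized mean of the unit embeddings of
that class's samples — a compact class representative that clients can
exchange instead of raw images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .synthetic import VeinImage

__all__ = [
    "EncoderContract",
    "SmallConvEncoder",
    "Prototype",
    "PrototypeSet",
    "embed_batch",
    "compute_prototypes",
    "reference_encoder",
]

_CHECKPOINT_VERSION = 1


@runtime_checkable
class EncoderContract(Protocol):
    """Minimal interface the federation needs from an encoder."""

    d: int

    def embed(self, images: np.ndarray) -> np.ndarray: ...

    def get_flat_params(self) -> np.ndarray: ...

    def set_flat_params(self, flat: np.ndarray) -> None: ...


def _as_batch(images) -> np.ndarray:
    """Stack VeinImages / 2-D arrays into an (n, H, W) float batch."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        return images.astype(float)
    arrs = [
        im.pixels.astype(float) if isinstance(im, VeinImage) else np.asarray(im, float)
        for im in images
    ]
    return np.stack(arrs)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-size convolution via im2col.

    x: (n, c_in, h, w); w: (c_out, c_in, 3, 3); b: (c_out,).
    Returns (out, col) with out (n, c_out, h, w).
    """
    n, c, h, ww = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # sliding windows -> (n, h, w, c, 3, 3)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * ww, c * 9)
    wmat = w.reshape(c_out, c * 9).T  # (c*9, c_out)
    out = col @ wmat + b  # (n, h*w, c_out)
    out = out.transpose(0, 2, 1).reshape(n, c_out, h, ww)
    return out, col


def _conv_backward(dout: np.ndarray, col: np.ndarray, x_shape, w: np.ndarray):
    """Gradients of the same-size 3x3 convolution."""
    n, c, h, ww = x_shape
    c_out = w.shape[0]
    dmat = dout.reshape(n, c_out, h * ww).transpose(0, 2, 1)  # (n, hw, c_out)
    dw = np.einsum("npk,npo->ko", col, dmat).T.reshape(w.shape)
    db = dmat.sum(axis=(0, 1))
    dcol = dmat @ w.reshape(c_out, c * 9)  # (n, hw, c*9)
    # scatter back (col2im) over the zero-padded input
    dxp = np.zeros((n, c, h + 2, ww + 2))
    dcol = dcol.reshape(n, h, ww, c, 3, 3)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + ww] += dcol[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _pool2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling (crops odd trailing row/col)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, :, : h2 * 2, : w2 * 2]
    return x.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))


def _pool2_backward(dout: np.ndarray, x_shape) -> np.ndarray:
    n, c, h, w = x_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros((n, c, h, w))
    up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    dx[:, :, : h2 * 2, : w2 * 2] = up
    return dx


def _fit_to_shape(batch: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rotate transposed-orientation images and zoom to the encoder's input.

    Vein identity lives in the curve layout, which survives a 90-degree
    rotation and mild rescaling; this lets one encoder serve clients with
    different sensor geometries.
    """
    from scipy.ndimage import zoom

    h, w = shape
    if batch.shape[1:] == (h, w):
        return batch
    if batch.shape[1:] == (w, h):  # finger axis runs the other way
        return np.rot90(batch, k=1, axes=(1, 2)).copy() if h > w else np.rot90(
            batch, k=-1, axes=(1, 2)
        ).copy()
    bh, bw = batch.shape[1:]
    if (bh > bw) != (h > w):
        batch = np.rot90(batch, k=-1, axes=(1, 2))
        bh, bw = bw, bh
    return zoom(batch, (1, h / bh, w / bw), order=1)


class SmallConvEncoder:
    """Tiny CNN over a fixed 64x128 input grid.

    Pipeline: per-image standardization, a fixed 2x2 average pool (cheap
    anti-aliased downsample), then [conv3x3 + ReLU + avgpool2] x 2, one
    more conv3x3 + ReLU, and a linear projection of the *flattened*
    feature map to d dimensions — the spatial layout of the vein curves
    is the identity signal, so no global pooling.  Inputs whose geometry
    does not match are rotated/rescaled first.  ``embed`` returns
    L2-normalized rows; all gradients are hand-derived.
    """

    CHANNELS = (8, 16, 32)
    INPUT_SHAPE = (64, 128)

    def __init__(self, seed: int = 0, d: int = 64):
        if d < 8:
            raise ValueError("embedding dimension must be >= 8")
        self.d = d
        rng = np.random.default_rng(seed)
        c_prev = 1
        self.params: dict[str, np.ndarray] = {}
        for i, c in enumerate(self.CHANNELS):
            fan_in = c_prev * 9
            self.params[f"w{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (c, c_prev, 3, 3))
            self.params[f"b{i}"] = np.zeros(c)
            c_prev = c
        h, w = self.INPUT_SHAPE
        # /2 stem pool, /2 after blocks 0 and 1; block 2 keeps resolution
        fh, fw = h // 8, w // 8
        n_feat = self.CHANNELS[-1] * fh * fw
        self._feat_shape = (self.CHANNELS[-1], fh, fw)
        self.params["w_fc"] = rng.normal(0, np.sqrt(1.0 / n_feat), (n_feat, d))
        self.params["b_fc"] = np.zeros(d)
        self._param_keys = list(self.params)

    # --- forward / backward -------------------------------------------------

    def forward(self, images) -> tuple[np.ndarray, dict]:
        """Raw (unnormalized) embeddings z plus the backprop cache."""
        x = _fit_to_shape(_as_batch(images), self.INPUT_SHAPE)
        x = x - x.mean(axis=(1, 2), keepdims=True)
        x = x / (x.std(axis=(1, 2), keepdims=True) + 1e-6)
        x = _pool2(x[:, None, :, :])  # fixed stem downsample
        cache: dict = {"inputs": []}
        for i in range(len(self.CHANNELS)):
            out, col = _conv_forward(x, self.params[f"w{i}"], self.params[f"b{i}"])
            mask = out > 0
            act = out * mask
            pooled = _pool2(act) if i < len(self.CHANNELS) - 1 else act
            cache["inputs"].append((x.shape, col, mask, act.shape))
            x = pooled
        n = x.shape[0]
        feat = x.reshape(n, -1)
        cache["feat"] = feat
        z = feat @ self.params["w_fc"] + self.params["b_fc"]
        return z, cache

    def backward(self, cache: dict, dz: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        grads["w_fc"] = cache["feat"].T @ dz
        grads["b_fc"] = dz.sum(axis=0)
        dfeat = dz @ self.params["w_fc"].T
        dx = dfeat.reshape(dz.shape[0], *self._feat_shape)
        for i in reversed(range(len(self.CHANNELS))):
            x_shape, col, mask, act_shape = cache["inputs"][i]
            dact = _pool2_backward(dx, act_shape) if i < len(self.CHANNELS) - 1 else dx
            dout = dact * mask
            dx, dw, db = _conv_backward(dout, col, x_shape, self.params[f"w{i}"])
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    def embed(self, images) -> np.ndarray:
        """Unit-norm embeddings, one row per image."""
        z, _ = self.forward(images)
        return z / np.linalg.norm(z, axis=1, keepdims=True)

    # --- parameter plumbing -------------------------------------------------

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in self._param_keys])

    def set_flat_params(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_params:
            raise ValueError("flat parameter vector has the wrong length")
        off = 0
        for k in self._param_keys:
            p = self.params[k]
            self.params[k] = flat[off : off + p.size].reshape(p.shape).copy()
            off += p.size

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def save(self, path) -> None:
        np.savez(
            path,
            __version__=_CHECKPOINT_VERSION,
            d=self.d,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "SmallConvEncoder":
        with np.load(path) as data:
            if int(data["__version__"]) != _CHECKPOINT_VERSION:
                raise ValueError("unsupported checkpoint version")
            enc = cls(seed=0, d=int(data["d"]))
            for k in enc._param_keys:
                enc.params[k] = data[k].copy()
        return enc


def reference_encoder(seed: int = 0, d: int = 64) -> SmallConvEncoder:
    """A freshly initialized small convolutional encoder (seeded)."""
    return SmallConvEncoder(seed=seed, d=d)


def embed_batch(encoder: EncoderContract, images) -> np.ndarray:
    """Unit embeddings for a batch; one row of length d per image."""
    emb = encoder.embed(_as_batch(images))
    if emb.shape[1] != encoder.d:
        raise ValueError("encoder returned embeddings of the wrong width")
    return emb


@dataclass
class Prototype:
    """Unit-norm class representative owned by one client."""

    class_label: int
    client_id: int
    vector: np.ndarray
    n_samples: int


@dataclass
class PrototypeSet:
    prototypes: list[Prototype]

    def __len__(self) -> int:
        return len(self.prototypes)

    def keys(self) -> list[tuple[int, int]]:
        return [(p.client_id, p.class_label) for p in self.prototypes]

    def block(self) -> tuple[np.ndarray, list[int]]:
        """(d x n) column matrix plus the matching class labels."""
        mat = np.stack([p.vector for p in self.prototypes], axis=1)
        return mat, [p.class_label for p in self.prototypes]


def compute_prototypes(
    encoder: EncoderContract, images: list[VeinImage], client_id: int | None = None
) -> PrototypeSet:
    """Mean of each class's unit embeddings, re-normalized to unit length.

    Prototypes live on the unit sphere so they can stand directly as
    classifier weight columns.  A class whose embeddings cancel to the
    zero vector has no direction and is rejected.
    """
    by_class: dict[int, list[VeinImage]] = {}
    for im in images:
        by_class.setdefault(im.class_label, []).append(im)
    if not by_class:
        raise ValueError("no images to build prototypes from")
    protos = []
    for label, ims in sorted(by_class.items()):
        emb = embed_batch(encoder, ims)
        mean = emb.mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-9:
            raise ValueError(
                f"degenerate prototype for class {label}: embeddings cancel"
            )
        cid = client_id if client_id is not None else ims[0].client_id
        protos.append(
            Prototype(
                class_label=label,
                client_id=cid,
                vector=mean / norm,
                n_samples=len(ims),
            )
        )
    return PrototypeSet(protos)
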