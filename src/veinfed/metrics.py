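"""Open-set verification protocol and metrics.

Verification is open-set: the classes used for testing are never seen in
training.  Each client reserves 20% of its classes (all their samples);
at test time every sample is embedded, every unordered sample pair is
scored by cosine similarity, and pairs are genuine (same class) or
impostor (different classes).  Sweeping an acceptance threshold over the
scores yields the false acceptance rate FAR (impostor pairs accepted),
false rejection rate FRR (genuine pairs rejected), true acceptance rate
TAR = 100 - FRR, the equal error rate EER (where FAR = FRR) and
TAR at a fixed FAR operating point.  The acceptance rule is
score >= threshold; ties count as accept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import EncoderContract, embed_batch
from .synthetic import ClientDataset, VeinImage

__all__ = [
    "OpenSetSplit",
    "VerificationScores",
    "VerificationMetrics",
    "train_test_class_counts",
    "split_open_set",
    "score_pairs",
    "far_frr_at",
    "roc_points",
    "eer",
    "tar_at_far",
    "evaluate_encoder",
    "rel_reduction",
    "rel_gain",
    "summarize",
]


@dataclass
class OpenSetSplit:
    """Class-disjoint train/test partition of one client's dataset."""

    train: ClientDataset
    test: ClientDataset
    train_classes: list[int]
    test_classes: list[int]
    seed: int


@dataclass
class VerificationScores:
    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, dtype=float)
        self.impostor = np.asarray(self.impostor, dtype=float)


@dataclass
class VerificationMetrics:
    eer: float  # percent
    tar_at_far: float  # percent, at FAR = 1%
    n_genuine: int
    n_impostor: int


def train_test_class_counts(n_classes: int, ratio: float = 0.8) -> tuple[int, int]:
    """floor(ratio * n) training classes, the rest held out."""
    n_train = math.floor(ratio * n_classes)
    return n_train, n_classes - n_train


def split_open_set(
    dataset: ClientDataset, ratio: float = 0.8, seed: int = 0
) -> OpenSetSplit:
    """Split by *classes* (not samples): held-out identities keep all samples."""
    classes = dataset.classes()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to split")
    n_train, n_test = train_test_class_counts(len(classes), ratio)
    if n_test < 2:
        raise ValueError(
            f"client {dataset.client_id}: only {n_test} test class(es); "
            "impostor pairs need at least 2"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(classes))
    train_classes = sorted(classes[i] for i in order[:n_train])
    test_classes = sorted(classes[i] for i in order[n_train:])
    tr = [im for im in dataset.images if im.class_label in set(train_classes)]
    te = [im for im in dataset.images if im.class_label in set(test_classes)]
    return OpenSetSplit(
        train=ClientDataset(dataset.client_id, dataset.spec, tr),
        test=ClientDataset(dataset.client_id, dataset.spec, te),
        train_classes=train_classes,
        test_classes=test_classes,
        seed=seed,
    )


def score_pairs(
    encoder: EncoderContract, test_images: list[VeinImage]
) -> VerificationScores:
    """Cosine similarity of every unordered sample pair, split by label."""
    labels = np.array([im.class_label for im in test_images])
    if len(set(labels.tolist())) < 2:
        raise ValueError("need >= 2 classes for impostor pairs")
    counts = pd.Series(labels).value_counts()
    if not (counts >= 2).any():
        raise ValueError("need at least one class with >= 2 samples")
    emb = embed_batch(encoder, test_images)
    sim = emb @ emb.T
    iu = np.triu_indices(len(labels), k=1)
    scores = sim[iu]
    same = labels[iu[0]] == labels[iu[1]]
    return VerificationScores(genuine=scores[same], impostor=scores[~same])


def far_frr_at(scores: VerificationScores, threshold: float) -> tuple[float, float]:
    """(FAR, FRR) in percent at one threshold; accept iff score >= threshold."""
    if scores.genuine.size == 0 or scores.impostor.size == 0:
        raise ValueError("both score sets must be non-empty")
    far = float(np.mean(scores.impostor >= threshold) * 100.0)
    frr = float(np.mean(scores.genuine < threshold) * 100.0)
    return far, frr


def roc_points(scores: VerificationScores) -> pd.DataFrame:
    """FAR/FRR at every candidate threshold (sorted score union plus ±inf)."""
    thr = np.concatenate(
        [[-np.inf], np.unique(np.concatenate([scores.genuine, scores.impostor])), [np.inf]]
    )
    far = np.array([np.mean(scores.impostor >= t) * 100.0 for t in thr])
    frr = np.array([np.mean(scores.genuine < t) * 100.0 for t in thr])
    return pd.DataFrame({"threshold": thr, "far": far, "frr": frr})


def eer(scores: VerificationScores) -> float:
    """Equal error rate in percent: where FAR = FRR along the sweep.

    FAR - FRR decreases monotonically with the threshold; the crossing is
    located between adjacent candidate thresholds and resolved by linear
    interpolation of both rates.
    """
    pts = roc_points(scores)
    diff = (pts["far"] - pts["frr"]).to_numpy()
    far = pts["far"].to_numpy()
    frr = pts["frr"].to_numpy()
    idx = np.nonzero(diff <= 0)[0][0]  # first threshold where FRR catches FAR
    if diff[idx] == 0:
        return float(far[idx])
    i, j = idx - 1, idx
    alpha = diff[i] / (diff[i] - diff[j])
    return float(far[i] + alpha * (far[j] - far[i]))


def tar_at_far(scores: VerificationScores, far_target: float = 0.01) -> float:
    """TAR (percent) at the operating point FAR = far_target (a proportion).

    Interpolates TAR linearly in FAR between the two candidate thresholds
    bracketing the target.
    """
    if scores.impostor.size == 0:
        raise ValueError("impostor score set is empty")
    if scores.impostor.size < 1.0 / far_target:
        warnings.warn(
            f"only {scores.impostor.size} impostor pairs; FAR = {far_target} "
            "operating point is coarsely resolved",
            stacklevel=2,
        )
    target = far_target * 100.0
    pts = roc_points(scores)
    thr = pts["threshold"].to_numpy()
    far = pts["far"].to_numpy()
    tar = 100.0 - pts["frr"].to_numpy()
    # far is non-increasing along the sweep
    idx = np.nonzero(far <= target)[0][0]
    if idx == 0 or far[idx] == target:
        return float(tar[idx])
    i, j = idx - 1, idx
    # never interpolate across an infinite endpoint (degenerate tie mass)
    if far[i] == far[j] or not (np.isfinite(thr[i]) and np.isfinite(thr[j])):
        return float(tar[j])
    alpha = (far[i] - target) / (far[i] - far[j])
    return float(tar[i] + alpha * (tar[j] - tar[i]))


def evaluate_encoder(
    encoder: EncoderContract,
    test_images: list[VeinImage],
    far_target: float = 0.01,
) -> VerificationMetrics:
    scores = score_pairs(encoder, test_images)
    return VerificationMetrics(
        eer=eer(scores),
        tar_at_far=tar_at_far(scores, far_target),
        n_genuine=int(scores.genuine.size),
        n_impostor=int(scores.impostor.size),
    )


def rel_reduction(a: float, b: float) -> float:
    """Percent by which a is lower than b: (b - a) / b * 100."""
    return (b - a) / b * 100.0


def rel_gain(a: float, b: float) -> float:
    """Percent by which a is higher than b: (a - b) / b * 100."""
    return (a - b) / b * 100.0


def summarize(
    per_dataset: pd.DataFrame, baselines: pd.DataFrame | None = None
) -> dict:
    """Mean row plus pairwise relative changes against optional baselines.

    ``per_dataset``: one row per dataset with metric columns (e.g. "eer",
    "tar"). ``baselines``: same columns, one row per competing method.
    EER-like columns are compared by relative reduction, everything else
    by relative gain.
    """
    means = per_dataset.mean(numeric_only=True).round(2)
    out = {
        "per_dataset": per_dataset,
        "mean": {k: float(v) for k, v in means.items()},
    }
    if baselines is not None:
        # relative changes use the report's 2-dp means, as rendered
        rel = {}
        for method, row in baselines.iterrows():
            entry = {}
            for col in per_dataset.columns:
                if col not in row:
                    continue
                if "eer" in col.lower():
                    entry[col] = round(rel_reduction(means[col], row[col]), 2)
                else:
                    entry[col] = round(rel_gain(means[col], row[col]), 2)
            rel[method] = entry
        out["relative_to"] = rel
    return out
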