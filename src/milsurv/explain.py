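"""Integrated-gradients attribution and counterfactual modality contribution.

Attributions are computed on the model's input feature bag along the
straight line from a baseline bag (features of a blank white patch, or
zeros) to the actual bag. The attribution target is the mean of the K
pre-sigmoid hazard logits (sigmoid outputs saturate and flatten the path
gradient). Per-patch scores are the feature-dimension sums; patient-wise
normalization divides by the maximum absolute value so scores live in
[-1, 1] with sign and zeros preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bags import FeatureBag, toy_encode
from .model import Model


@dataclass
class AttributionMap:
    raw: np.ndarray          # (N,) per-patch integrated gradients
    normalized: np.ndarray   # (N,) in [-1, 1], sign-preserving
    slide_ig: float          # mean of normalized values
    baseline: str            # description of the baseline bag


def white_patch_baseline(bag: FeatureBag, out_dim: int, out_px: int = 256,
                         seed: int = 0) -> np.ndarray:
    """Baseline features: every patch replaced by an all-white patch pushed
    through the toy encoder (feature 'missingness' in image space)."""
    white = np.full((1, out_px, out_px, 3), 255, dtype=np.uint8)
    row = toy_encode(white, np.zeros((1, 2)), out_dim=out_dim, seed=seed).features
    return np.repeat(row.astype(np.float64), bag.n_patches, axis=0)


def integrated_gradients(
    model: Model,
    bag: FeatureBag,
    mol_idx: int | None = None,
    stage_idx: int | None = None,
    baseline: np.ndarray | str = "white",
    steps: int = 128,
) -> AttributionMap:
    """Midpoint-rule integrated gradients of the mean hazard logit.

    ``baseline`` is 'white', 'zeros', or an explicit array of the bag's
    shape. Per-feature attribution is (x - x0) times the mean path
    gradient; per-patch attribution sums over feature dimensions.
    """
    x = bag.features.astype(np.float64)
    if isinstance(baseline, str):
        if baseline == "white":
            x0 = white_patch_baseline(bag, out_dim=model.cfg.in_dim)
            desc = "white-patch features"
        elif baseline == "zeros":
            x0 = np.zeros_like(x)
            desc = "all-zero features"
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
    else:
        x0 = np.asarray(baseline, dtype=np.float64)
        desc = "custom baseline"
    if x0.shape != x.shape:
        raise ValueError("baseline shape must match the bag")

    grad_sum = np.zeros_like(x)
    for s in range(steps):
        alpha = (s + 0.5) / steps
        _, dx = model.logit_target_grad(x0 + alpha * (x - x0), mol_idx, stage_idx)
        grad_sum += dx
    per_feature = (x - x0) * grad_sum / steps
    raw = per_feature.sum(axis=1)
    normalized, slide_ig = normalize_ig(raw)
    return AttributionMap(raw=raw, normalized=normalized,
                         slide_ig=slide_ig, baseline=desc)


def normalize_ig(raw) -> tuple[np.ndarray, float]:
    """Patient-wise rescale to [-1, 1]: divide by max |value| (if nonzero),
    preserving sign and zeros; the slide-level score is the mean."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size < 1:
        raise ValueError("need at least one patch")
    peak = np.abs(raw).max()
    normalized = raw / peak if peak > 0 else raw.copy()
    return normalized, float(normalized.mean())


def top_fraction_regions(attributions, frac: float = 0.05) -> dict[str, np.ndarray]:
    """Indices of the ceil(frac * N) most risk-increasing and most
    risk-decreasing patches; ties broken by patch index."""
    a = np.asarray(attributions, dtype=np.float64)
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    k = int(np.ceil(frac * len(a)))
    idx = np.arange(len(a))
    # lexsort: primary key value, secondary patch index (stable ascending)
    order_desc = np.lexsort((idx, -a))
    order_asc = np.lexsort((idx, a))
    return {
        "increasing": np.sort(order_desc[:k]),
        "decreasing": np.sort(order_asc[:k]),
    }


def modality_contribution(
    model: Model,
    bag: FeatureBag,
    mol_idx: int,
    stage_idx: int,
    modality: str,
    reference_level: int,
) -> float:
    """Counterfactual risk contribution of one categorical input:
    risk(actual level) - risk(reference level), everything else fixed.
    Positive values mean the actual level raises the risk relative to the
    reference."""
    feats = bag.features.astype(np.float64)
    if modality == "mol_class":
        n_levels = model.cfg.n_mol_classes
    elif modality == "stage":
        n_levels = model.cfg.n_stages
    else:
        raise ValueError("modality must be 'mol_class' or 'stage'")
    if not 0 <= reference_level < n_levels:
        raise ValueError(f"reference level {reference_level} out of range")
    actual = model.forward(feats, mol_idx, stage_idx).risk
    if modality == "mol_class":
        ref = model.forward(feats, reference_level, stage_idx).risk
    else:
        ref = model.forward(feats, mol_idx, reference_level).risk
    return float(actual - ref)
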