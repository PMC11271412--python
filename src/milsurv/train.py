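"""Time discretization, discrete-time survival likelihood, and training.

The follow-up scale is cut into K = 4 intervals at the quartiles of the
uncensored event-time distribution. Each patient contributes the
discrete-time negative log likelihood

    event:    -log h_k - sum_{j<k} log(1 - h_j)
    censored: -sum_{j<=k} log(1 - h_j)

where k is the patient's interval. Censored patients contribute survival
through their own interval inclusive. Optimization follows the reference
schedule: Adam, batch size one, stepwise learning-rate decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bags import FeatureBag
from .model import Model, ModelConfig
from .synthetic import records_to_indices


@dataclass(frozen=True)
class TimeGrid:
    """K right-closed intervals (t_{k-1}, t_k]; the last is unbounded."""

    edges: tuple[float, ...]  # K-1 interior edges, strictly increasing

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if len(e) < 1 or (np.diff(e) <= 0).any():
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def bin_of(self, times) -> np.ndarray:
        """0-based interval index; a time equal to an edge falls in the
        interval the edge closes (right-closed rule)."""
        return np.searchsorted(np.asarray(self.edges), np.asarray(times),
                               side="left").astype(np.int64)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 24
    lr: float = 3e-5
    lr_decay_epochs: tuple[int, ...] = (2, 5, 15)
    decay_factor: float = 10.0
    weight_decay: float = 1e-5
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch size one is supported")


def discretize_times(records: pd.DataFrame, k: int = 4) -> TimeGrid:
    """Interval edges from event-time quartiles of uncensored patients."""
    times = np.asarray(records["time_years"], dtype=np.float64)
    events = np.asarray(records["event"], dtype=np.int64)
    unc = times[events == 1]
    if len(unc) < k:
        raise ValueError(f"need at least {k} uncensored events, got {len(unc)}")
    qs = [i / k for i in range(1, k)]
    edges = np.quantile(unc, qs, method="linear")
    return TimeGrid(edges=tuple(float(e) for e in edges))


def nll_loss(h: np.ndarray, bin_idx: int, event: int) -> float:
    """Negative log likelihood of one patient's discrete-time outcome.

    ``bin_idx`` is 0-based. Hazards at exactly 0/1 are clamped to 1e-7
    with a warning.
    """
    h = np.asarray(h, dtype=np.float64)
    if ((h < 0) | (h > 1)).any():
        raise ValueError("hazards must lie in [0, 1]")
    if not 0 <= bin_idx < len(h):
        raise ValueError("bin index out of range")
    if ((h == 0) | (h == 1)).any():
        warnings.warn("hazards at 0/1 clamped to 1e-7 for the log likelihood")
        h = np.clip(h, 1e-7, 1.0 - 1e-7)
    if event:
        return float(-np.log(h[bin_idx]) - np.log(1.0 - h[:bin_idx]).sum())
    return float(-np.log(1.0 - h[: bin_idx + 1]).sum())


def nll_grad_logits(h: np.ndarray, bin_idx: int, event: int) -> np.ndarray:
    """d(nll)/d(logit) for sigmoid hazards — closed form."""
    g = np.zeros_like(h)
    if event:
        g[:bin_idx] = h[:bin_idx]
        g[bin_idx] = -(1.0 - h[bin_idx])
    else:
        g[: bin_idx + 1] = h[: bin_idx + 1]
    return g


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    Updates run in place on preallocated buffers; with batch-one training
    the optimizer pass is a large share of the step cost.
    """

    def __init__(self, params, lr, weight_decay=0.0, b1=0.9, b2=0.999, eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self._buf = {k: np.empty_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        scale = self.lr / b1t
        for k, p in params.items():
            g, m, v, buf = grads[k], self.m[k], self.v[k], self._buf[k]
            if self.wd:
                np.multiply(p, self.wd, out=buf)
                g += buf
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=buf)
            m += buf
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.b2
            v += buf
            np.divide(v, b2t, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= scale
            p -= buf


@dataclass
class TrainResult:
    model: Model
    time_grid: TimeGrid
    loss_trace: list[float] = field(default_factory=list)


def train(
    bags: list[FeatureBag],
    records: pd.DataFrame,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    time_grid: TimeGrid | None = None,
) -> TrainResult:
    """Fit the multimodal model on one bag per patient.

    ``bags`` aligns row-wise with ``records``. All randomness (parameter
    init, epoch shuffling, dropout) derives from the two seeds, so a rerun
    reproduces the loss trace exactly.
    """
    if len(bags) != len(records):
        raise ValueError("bags and records must align")
    if time_grid is None:
        time_grid = discretize_times(records, model_cfg.n_bins)
    bins = time_grid.bin_of(records["time_years"])
    events = np.asarray(records["event"], dtype=np.int64)
    mol_idx, stage_idx = records_to_indices(records)

    model = Model(model_cfg)
    opt = Adam(model.params, train_cfg.lr, train_cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 7]))
    n = len(bags)
    feats = [b.features.astype(np.float64) for b in bags]

    trace = []
    for epoch in range(1, train_cfg.epochs + 1):
        n_decays = sum(1 for e in train_cfg.lr_decay_epochs if epoch >= e)
        opt.lr = train_cfg.lr / (train_cfg.decay_factor ** n_decays)
        order = rng.permutation(n)
        total = 0.0
        for i in order:
            out, cache = model.forward(
                feats[i], int(mol_idx[i]), int(stage_idx[i]),
                train=True, rng=rng, want_cache=True,
            )
            loss = nll_loss(out.hazards, int(bins[i]), int(events[i]))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, "
                    f"sample {records['patient_id'].iloc[i]}"
                )
            dlogits = nll_grad_logits(out.hazards, int(bins[i]), int(events[i]))
            grads, _ = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            total += loss
        trace.append(total / n)
    return TrainResult(model=model, time_grid=time_grid, loss_trace=trace)


def predict_risks(model: Model, bags, records: pd.DataFrame) -> np.ndarray:
    """Deterministic eval-mode risk score per patient."""
    mol_idx, stage_idx = records_to_indices(records)
    return np.array(
        [
            model.forward(b.features.astype(np.float64),
                          int(mol_idx[i]), int(stage_idx[i])).risk
            for i, b in enumerate(bags)
        ]
    )


def stratified_folds(bins, events, n_folds, seed):
    """Fold assignment stratified on (interval, event); within each stratum
    fold sizes differ by at most one. Strata smaller than the fold count
    are merged into the largest stratum with a warning."""
    bins = np.asarray(bins)
    events = np.asarray(events)
    n = len(bins)
    labels = bins * 2 + events
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < n_folds]
    if len(small):
        warnings.warn("strata smaller than the fold count merged")
        biggest = uniq[np.argmax(counts)]
        labels = np.where(np.isin(labels, small), biggest, labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    folds = np.empty(n, dtype=np.int64)
    start = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        folds[idx] = (start + np.arange(len(idx))) % n_folds
        start += len(idx)
    return folds


def crossvalidate(
    bags: list[FeatureBag],
    records: pd.DataFrame,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    tau: float = 10.0,
):
    """Out-of-fold risk scores and per-fold C-indices."""
    from .evaluate import concordance

    grid = discretize_times(records, model_cfg.n_bins)
    bins = grid.bin_of(records["time_years"])
    events = np.asarray(records["event"], dtype=np.int64)
    folds = stratified_folds(bins, events, n_folds, seed)

    risks = np.full(len(records), np.nan)
    cindices = []
    for f in range(n_folds):
        test = folds == f
        tr = ~test
        sub_records = records.loc[tr].reset_index(drop=True)
        sub_bags = [b for b, keep in zip(bags, tr) if keep]
        res = train(sub_bags, sub_records, model_cfg, train_cfg, time_grid=grid)
        te_records = records.loc[test].reset_index(drop=True)
        te_bags = [b for b, keep in zip(bags, test) if keep]
        r = predict_risks(res.model, te_bags, te_records)
        risks[test] = r
        cindices.append(
            concordance(r, te_records["time_years"], te_records["event"], tau=tau)
        )
    scores = pd.DataFrame(
        {"patient_id": records["patient_id"], "fold": folds, "risk": risks}
    )
    return scores, cindices
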