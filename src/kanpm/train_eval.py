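"""Dataset splitting, training with early stopping, and the metric suite.

Splits
------
Four protocols, all seeded and reproducible:

* ``warm`` -- random pair-level 8:1:1 split; a pair never recurs across
  splits but its drug/protein may.
* ``unseen_drug`` / ``unseen_protein`` -- the *identifiers* of the split-on
  entity are partitioned 8:1:1 and every pair follows its entity, so test
  entities are absent by id from train and validation.
* ``all_unseen`` -- drug ids and protein ids are partitioned independently;
  a pair is kept only when both ids landed in the same bucket (mixed-bucket
  pairs are discarded and counted).

Metrics
-------
MSE; concordance index CI = (1/Z) Σ_{y_i > y_j} h(p_i - p_j) with step
credits 1 / 0.5 / 0 and Z the number of ordered pairs with y_i > y_j; and
r_m² = r² (1 - sqrt(r² - r₀²)) where r² is the squared Pearson correlation
and r₀² the through-origin coefficient of determination of y on p (the
radicand is clamped at 0).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .core_data import InteractionRecord, ModelConfig
from .model import DatasetTensors, DTAModel
from .nn import Adam

__all__ = [
    "SplitSpec",
    "SplitResult",
    "split_dataset",
    "mse",
    "concordance_index",
    "rm_squared",
    "relative_change",
    "MetricReport",
    "repeat_experiment",
    "EarlyStopper",
    "TrainResult",
    "train_model",
    "evaluate_model",
    "compute_metrics",
]

_MODES = ("warm", "unseen_drug", "unseen_protein", "all_unseen")


@dataclass
class SplitSpec:
    mode: str = "warm"
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown split mode {self.mode!r}; use {_MODES}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class SplitResult:
    train: list
    val: list
    test: list
    n_discarded: int = 0

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def _partition_sizes(n: int, ratios) -> tuple[int, int, int]:
    # floor the val/test shares; the remainder goes to train
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    return n - n_val - n_test, n_val, n_test


def _bucket_ids(ids, ratios, rng) -> dict:
    ids = sorted(ids)
    order = rng.permutation(len(ids))
    n_train, n_val, _ = _partition_sizes(len(ids), ratios)
    bucket = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            b = "train"
        elif rank < n_train + n_val:
            b = "val"
        else:
            b = "test"
        bucket[ids[idx]] = b
    return bucket


def split_dataset(interactions: list[InteractionRecord],
                  spec: SplitSpec) -> SplitResult:
    """Partition interactions under one of the four evaluation protocols."""
    if len(interactions) < 10:
        raise ValueError("need at least 10 interactions to split")
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "warm":
        order = rng.permutation(len(interactions))
        n_train, n_val, _ = _partition_sizes(len(interactions), spec.ratios)
        train = [interactions[i] for i in order[:n_train]]
        val = [interactions[i] for i in order[n_train:n_train + n_val]]
        test = [interactions[i] for i in order[n_train + n_val:]]
        return SplitResult(train, val, test)

    drug_ids = {r.drug_id for r in interactions}
    protein_ids = {r.protein_id for r in interactions}
    if spec.mode in ("unseen_drug", "all_unseen") and len(drug_ids) < 10:
        raise ValueError(
            f"{spec.mode}: need >= 10 distinct drugs, got {len(drug_ids)}")
    if spec.mode in ("unseen_protein", "all_unseen") and len(protein_ids) < 10:
        raise ValueError(
            f"{spec.mode}: need >= 10 distinct proteins, got {len(protein_ids)}")

    buckets = {"train": [], "val": [], "test": []}
    discarded = 0
    if spec.mode == "unseen_drug":
        b = _bucket_ids(drug_ids, spec.ratios, rng)
        for r in interactions:
            buckets[b[r.drug_id]].append(r)
    elif spec.mode == "unseen_protein":
        b = _bucket_ids(protein_ids, spec.ratios, rng)
        for r in interactions:
            buckets[b[r.protein_id]].append(r)
    else:  # all_unseen
        bd = _bucket_ids(drug_ids, spec.ratios, rng)
        bp = _bucket_ids(protein_ids, spec.ratios, rng)
        for r in interactions:
            if bd[r.drug_id] == bp[r.protein_id]:
                buckets[bd[r.drug_id]].append(r)
            else:
                discarded += 1
    return SplitResult(buckets["train"], buckets["val"], buckets["test"],
                       n_discarded=discarded)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mse(y, p) -> float:
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("y and p must be equal-length non-empty vectors")
    return float(np.mean((y - p) ** 2))


def concordance_index(y, p) -> float:
    """Fraction of ordered label pairs ranked concordantly; prediction ties
    credit 0.5.  Label ties contribute nothing to the normalizer."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need >= 2 aligned samples")
    gt = y[:, None] > y[None, :]          # ordered pairs with y_i > y_j
    z = int(gt.sum())
    if z == 0:
        raise ValueError("all labels tied: concordance index undefined")
    diff = p[:, None] - p[None, :]
    credit = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float((credit * gt).sum() / z)


def rm_squared(y, p) -> float:
    """r_m² = r² (1 - sqrt(r² - r₀²)) with r₀² from the through-origin fit.

    r² is the squared Pearson correlation of predictions and labels; r₀² is
    1 - Σ(y - k·p)² / Σ(y - ȳ)² with slope k = Σ y·p / Σ p².  The radicand
    is clamped at 0 so numerical r² < r₀² cannot produce NaN.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape or y.size < 3:
        raise ValueError("need >= 3 aligned samples")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("zero variance: r_m^2 undefined")
    r2 = float(np.corrcoef(p, y)[0, 1] ** 2)
    k = float(np.sum(y * p) / np.sum(p * p))
    r02 = 1.0 - float(np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2))
    return float(r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0))))


def relative_change(reference: float, new: float,
                    direction: str = "decrease") -> float:
    """Percentage improvement of ``new`` over ``reference``.

    ``decrease`` phrasing (errors like MSE): 100 (ref - new)/ref;
    ``increase`` phrasing (scores like CI, r_m²): 100 (new - ref)/ref.
    Rounded to 2 decimals for reporting.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if direction == "decrease":
        pct = 100.0 * (reference - new) / reference
    else:
        pct = 100.0 * (new - reference) / reference
    return round(pct, 2)


def compute_metrics(y, p) -> dict:
    return {
        "mse": mse(y, p),
        "ci": concordance_index(y, p),
        "rm2": rm_squared(y, p),
        "n": int(np.asarray(y).size),
    }


@dataclass
class MetricReport:
    """Mean and sample standard deviation of metrics over repeats."""

    per_seed: list = field(default_factory=list)  # list of metric dicts
    n: int = 0

    @property
    def metric_names(self):
        return [k for k in self.per_seed[0] if k != "n"] if self.per_seed else []

    def mean(self, name: str) -> float:
        return float(np.mean([m[name] for m in self.per_seed]))

    def sd(self, name: str) -> float:
        vals = [m[name] for m in self.per_seed]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def cell(self, name: str, decimals: int = 3) -> str:
        """Format as the conventional 'mean (sd)' table cell."""
        return f"{self.mean(name):.{decimals}f} ({self.sd(name):.{decimals}f})"

    def as_dict(self) -> dict:
        out = {"n": self.n, "per_seed": self.per_seed}
        for name in self.metric_names:
            out[name] = {"mean": self.mean(name), "sd": self.sd(name)}
        return out


def repeat_experiment(run_fn, seed: int, n_repeats: int = 5) -> MetricReport:
    """Run ``run_fn(seed_i)`` for seeds seed..seed+n_repeats-1 and aggregate.

    ``run_fn`` must return a metric dict (e.g. from :func:`compute_metrics`).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    per_seed = [dict(run_fn(seed + i)) for i in range(n_repeats)]
    n = per_seed[0].get("n", 0)
    return MetricReport(per_seed=per_seed, n=n)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop when the validation loss has not strictly decreased for more
    than ``patience`` consecutive epochs."""

    def __init__(self, patience: int = 20):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best > self.patience


@dataclass
class TrainResult:
    model: DTAModel
    history: list          # rows of (epoch, train_mse, val_mse)
    best_epoch: int
    best_val_mse: float


def _pairs_to_indices(pairs, tensors: DatasetTensors):
    return [(tensors.p_index[r.protein_id], tensors.d_index[r.drug_id])
            for r in pairs]


def train_model(config: ModelConfig, tensors: DatasetTensors,
                train_pairs: list[InteractionRecord],
                val_pairs: list[InteractionRecord],
                seed: int | None = None, verbose: bool = False) -> TrainResult:
    """MSE training with Adam and patience-based early stopping.

    Runs at most ``config.epochs`` epochs, monitors validation MSE, and
    restores the best-validation weights before returning.  Fully
    deterministic for a fixed seed.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    seed = config.seed if seed is None else seed
    model = DTAModel(config, seed=seed)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed + 1)

    tr_idx = _pairs_to_indices(train_pairs, tensors)
    va_idx = _pairs_to_indices(val_pairs, tensors)
    y_tr = np.asarray([r.affinity for r in train_pairs], dtype=np.float64)
    y_va = np.asarray([r.affinity for r in val_pairs], dtype=np.float64)

    stopper = EarlyStopper(config.patience)
    best_state = None
    history = []
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(len(tr_idx))
        sq_err_sum = 0.0
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            batch = tensors.collate([tr_idx[i] for i in sel])
            pred = model(batch)
            target = Tensor(y_tr[sel].astype(pred.data.dtype))
            err = pred - target
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch of {len(sel)}); inspect lr/inputs")
            opt.zero_grad()
            loss.backward()
            opt.step()
            sq_err_sum += float(loss.data) * len(sel)
        train_mse = sq_err_sum / len(order)
        val_pred = model.predict(tensors, va_idx,
                                 batch_size=max(config.batch_size, 256))
        val_mse = mse(y_va, val_pred)
        history.append((epoch, train_mse, val_mse))
        if verbose:
            print(f"epoch {epoch:3d}  train {train_mse:.4f}  val {val_mse:.4f}")
        improved = val_mse < stopper.best
        stop = stopper.update(epoch, val_mse)
        if improved:
            best_state = copy.deepcopy(model.state_dict())
        if stop:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model, history, stopper.best_epoch, stopper.best)


def evaluate_model(model: DTAModel, tensors: DatasetTensors,
                   pairs: list[InteractionRecord]) -> dict:
    idx = _pairs_to_indices(pairs, tensors)
    y = np.asarray([r.affinity for r in pairs], dtype=np.float64)
    pred = model.predict(tensors, idx)
    return compute_metrics(y, pred)
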