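"""Loss assembly and gradient-based fitting of the fuzzy rule network.

The objective is a class-weighted cross-entropy plus two interpretability
regularizers::

    loss = CE_weighted + lambda1 * (||vec(A)||_1 + ||vec(M)||_1)
         + lambda2 * sum_{i<j} <vec(S[:,:,i]), vec(S[:,:,j])>

The L1 term drives attention/connection sparsity (few features and
concepts per rule); the pairwise inner-product term on the contribution
matrix ``S = A * M`` penalizes duplicated rules.  Parameters are updated
with Adam on their unconstrained representations while the shared
smoothness eps is annealed geometrically once per optimizer step.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .fuzzy_core import SmoothnessState, anneal_eps
from .network import (
    FeatureSchema,
    NetworkParams,
    _cutoffs_from_raw,
    encode,
    infer,
    rule_strengths,
)

__all__ = [
    "TrainConfig",
    "TrainLog",
    "sparsity_loss",
    "correlation_loss",
    "total_loss",
    "fit",
    "random_search",
]

LEAF_NAMES = ("attention_raw", "connection_raw", "inference_raw", "cutoff_raw")


@dataclass
class TrainConfig:
    """Hyperparameters of a single fit.

    ``class_weights=None`` means inverse class frequency, computed on the
    training labels (positives are upweighted under class imbalance).
    """

    lambda_sparse: float = 1e-3
    lambda_corr: float = 1e-3
    class_weights: list[float] | None = None
    learning_rate: float = 1e-2
    n_epochs: int = 200
    batch_size: int = 64
    gamma: float = 0.999
    eps_min: float = 0.01
    n_rules: int = 10
    seed: int = 0
    early_stopping_patience: int | None = None
    validation_fraction: float = 0.1  # only used when early stopping is on

    def __post_init__(self):
        if self.lambda_sparse < 0 or self.lambda_corr < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_rules < 1:
            raise ValueError("learning_rate, batch_size and n_rules must be positive")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "TrainConfig":
        if isinstance(source, str) and "\n" in source:
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(**doc)


@dataclass
class TrainLog:
    """Per-epoch loss decomposition; serializable as CSV."""

    epoch: list[int] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    cross_entropy: list[float] = field(default_factory=list)
    sparsity: list[float] = field(default_factory=list)
    correlation: list[float] = field(default_factory=list)
    eps: list[float] = field(default_factory=list)

    def append(self, epoch, total, ce, sp, corr, eps):
        self.epoch.append(int(epoch))
        self.total.append(float(total))
        self.cross_entropy.append(float(ce))
        self.sparsity.append(float(sp))
        self.correlation.append(float(corr))
        self.eps.append(float(eps))

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": self.epoch,
                "total_loss": self.total,
                "cross_entropy": self.cross_entropy,
                "sparsity": self.sparsity,
                "correlation": self.correlation,
                "eps": self.eps,
            }
        ).to_csv(path, index=False)


# -- loss terms -----------------------------------------------------------

def _projected(leaves: dict, schema: FeatureSchema):
    """Constrained parameter views from raw leaves (arrays or tensors)."""
    mask = schema.slot_mask()[:, :, None]
    A = ad.sigmoid(leaves["attention_raw"]) * mask
    M = ad.sigmoid(leaves["connection_raw"])
    W = ad.softplus(leaves["inference_raw"])
    cuts = _cutoffs_from_raw(leaves["cutoff_raw"])
    return A, M, W, cuts


def sparsity_loss(params, schema: FeatureSchema | None = None):
    """L1 norm of the projected attention and connection entries.

    Accepts a :class:`NetworkParams` or a ``(A, M)`` pair of projected
    arrays/tensors.  Entries are in [0, 1] so the L1 norm is a plain sum;
    structurally-unused concept slots are zeroed by the slot mask and do
    not contribute.
    """
    if isinstance(params, NetworkParams):
        A, M = params.attention, params.connection
    else:
        A, M = params
    return ad.asum(A) + ad.asum(M)


def correlation_loss(params, schema: FeatureSchema | None = None):
    """Sum over rule pairs of inner products of contribution columns.

    ``S[i,d,k] = A[i,d,k] * M[i,k]``; the loss is
    ``sum_{k<j} <vec(S[:,:,k]), vec(S[:,:,j])>`` — zero for a single rule,
    large when two rules attend to the same concepts.
    """
    if isinstance(params, NetworkParams):
        A, M = params.attention, params.connection
    else:
        A, M = params
    N = A.shape[0]
    K = A.shape[2]
    if K == 1:
        return ad.asum(A * 0.0)  # preserves graph type
    S = A * ad.reshape(M, (N, 1, K))
    G = ad.reshape(S, (-1, K))
    P = ad.einsum2("ak,aj->kj", G, G)
    upper = np.triu(np.ones((K, K)), k=1)
    return ad.asum(P * upper)


def _loss_graph(X, y, leaves, schema, eps, config, class_weights):
    """Differentiable total loss and its components on one batch."""
    A, M, W, cuts = _projected(leaves, schema)
    enc = encode(X, schema, cutoffs=cuts, eps1=eps)
    if not isinstance(enc, ad.Tensor) and np.asarray(enc).ndim == 2:
        enc = np.asarray(enc)[None]
    r = rule_strengths(enc, None, attention=A, connection=M, eps2=eps)
    O = infer(r, None, inference=W, eps3=eps)
    logp = O - ad.logsumexp(O, axis=1, keepdims=True)
    onehot = np.eye(O.shape[1])[np.asarray(y, dtype=int)]
    w = class_weights[np.asarray(y, dtype=int)]
    ce_each = -ad.asum(logp * onehot, axis=1)
    ce = ad.asum(ce_each * w) / float(np.sum(w))
    sp = sparsity_loss((A, M))
    corr = correlation_loss((A, M))
    total = ce + config.lambda_sparse * sp + config.lambda_corr * corr
    return total, ce, sp, corr


def total_loss(X, y, params: NetworkParams, config: TrainConfig,
               class_weights=None, *, components=False):
    """Total training loss of a batch under the current parameters."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("batch must be nonempty")
    cw = _resolve_class_weights(class_weights or config.class_weights, y,
                                params.n_classes)
    leaves = {k: getattr(params, k) for k in LEAF_NAMES}
    total, ce, sp, corr = _loss_graph(
        np.atleast_2d(X), y, leaves, params.schema, params.smoothness.eps, config, cw
    )
    vals = tuple(float(ad.asarray(t)) for t in (total, ce, sp, corr))
    return vals if components else vals[0]


def _resolve_class_weights(cw, y, n_classes):
    if cw is not None:
        w = np.asarray(cw, dtype=np.float64)
        if w.shape != (n_classes,) or np.any(w <= 0):
            raise ValueError("class_weights must be positive, one per class")
        return w
    counts = np.bincount(np.asarray(y, dtype=int), minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = len(y) / (n_classes * counts)  # inverse frequency
    return w


class Adam:
    """Plain Adam on a dict of named arrays."""

    def __init__(self, shapes: dict, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, values: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            values[k] = values[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return values


def fit(X, y, schema: FeatureSchema, config: TrainConfig,
        init: NetworkParams | None = None, n_classes: int | None = None):
    """Minibatch Adam on the total loss with per-step eps annealing.

    ``X`` is the model-ready matrix (standardized continuous + level
    codes), ``y`` integer class labels.  When ``init`` is None the
    network starts from the seeded random (empty-knowledge)
    initialization with membership cutoffs at the training-data
    quantiles.  Returns ``(NetworkParams, TrainLog)``.
    """
    from .rules import RuleSet, init_from_rules  # local import, avoids a cycle

    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    C = n_classes or max(2, int(y.max()) + 1)
    if init is None:
        params = init_from_rules(
            RuleSet([]), schema, config.n_rules, seed=config.seed,
            n_classes=C, data=X,
        )
    else:
        params = init.copy()
    params.smoothness = SmoothnessState(
        eps=0.99, eps_min=config.eps_min, gamma=config.gamma, step=0
    )
    cw = _resolve_class_weights(config.class_weights, y, C)
    rng = np.random.default_rng(config.seed)
    log = TrainLog()

    # optional validation split for early stopping
    X_tr, y_tr = X, y
    X_val = y_val = None
    if config.early_stopping_patience:
        n_val = max(1, int(round(config.validation_fraction * len(y))))
        perm = rng.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    values = {k: getattr(params, k).copy() for k in LEAF_NAMES}
    opt = Adam({k: v.shape for k, v in values.items()}, lr=config.learning_rate)
    best_val, patience_left, best_values = np.inf, config.early_stopping_patience, None

    n = len(y_tr)
    for epoch in range(config.n_epochs):
        perm = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            leaves = {k: ad.Tensor(v) for k, v in values.items()}
            total, ce, sp, corr = _loss_graph(
                X_tr[idx], y_tr[idx], leaves, schema,
                params.smoothness.eps, config, cw,
            )
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {opt.t}: "
                    f"ce={float(ad.asarray(ce))}, sparse={float(ad.asarray(sp))}, "
                    f"corr={float(ad.asarray(corr))}, eps={params.smoothness.eps}"
                )
            grads = ad.grad(total, leaves)
            values = opt.step(values, grads)
            params.smoothness = anneal_eps(params.smoothness)
            sums += [total.item(), ce.item(), float(ad.asarray(sp)), float(ad.asarray(corr))]
            n_batches += 1
        log.append(epoch, *(sums / max(n_batches, 1)), params.smoothness.eps)

        if config.early_stopping_patience:
            for k in LEAF_NAMES:
                setattr(params, k, values[k])
            vl = total_loss(X_val, y_val, params, config, class_weights=list(cw))
            if vl < best_val - 1e-9:
                best_val, patience_left = vl, config.early_stopping_patience
                best_values = {k: v.copy() for k, v in values.items()}
            else:
                patience_left -= 1
                if patience_left <= 0:
                    values = best_values or values
                    break

    for k in LEAF_NAMES:
        setattr(params, k, values[k])
    return params, log


# -- hyperparameter search ------------------------------------------------

#: parameters sampled log-uniformly when given as a (low, high) range
_LOG_SCALE = {"learning_rate", "lambda_sparse", "lambda_corr"}
_INT_PARAMS = {"n_epochs", "batch_size", "n_rules"}


def sample_config(search_space: dict, rng: np.random.Generator,
                  base: TrainConfig | None = None) -> TrainConfig:
    """Draw one configuration uniformly from the search space.

    Each entry is either a list of choices or a ``(low, high)`` range;
    rates and regularization weights are sampled log-uniformly.
    """
    kwargs = asdict(base) if base else {}
    for name, spec in search_space.items():
        # a 2-tuple is a (low, high) range; a list is an explicit choice set
        if isinstance(spec, tuple) and len(spec) == 2:
            lo, hi = float(spec[0]), float(spec[1])
            if name in _LOG_SCALE:
                val = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            else:
                val = rng.uniform(lo, hi)
            if name in _INT_PARAMS:
                val = int(round(val))
            kwargs[name] = val
        else:
            choice = spec[int(rng.integers(len(spec)))]
            kwargs[name] = choice
    kwargs.pop("seed", None)
    return TrainConfig(seed=int(rng.integers(2**31 - 1)), **kwargs)


def random_search(train_table, schema: FeatureSchema, search_space: dict,
                  n_trials: int, seed: int, scorer=None, **scorer_kwargs):
    """Random hyperparameter search scored by patient-wise CV mean AUC.

    ``train_table`` is a labeled pair-level cohort table.  Returns
    ``(best TrainConfig, trials)`` where ``trials`` is a list of
    ``(config, score)`` in sampled order; ties break toward the earlier
    trial.  Fully reproducible given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if scorer is None:
        from .evaluation import cv_auc_scorer

        scorer = cv_auc_scorer
    rng = np.random.default_rng(seed)
    trials = []
    best, best_score = None, -np.inf
    for _ in range(n_trials):
        cfg = sample_config(search_space, rng)
        score = float(scorer(train_table, schema, cfg, **scorer_kwargs))
        trials.append((cfg, float(score)))
        if score > best_score:
            best, best_score = cfg, float(score)
    return best, trials
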