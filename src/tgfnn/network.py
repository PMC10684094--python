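"""The three-layer fuzzy rule network.

Layer 1 (encoding) turns each continuous feature into "low" / "medium" /
"high" membership degrees and each categorical feature into its one-hot
level indicators.  Layer 2 (rules) combines concepts into K conjunctive
rules: an attention tensor ``A`` (N features x D concept slots x K
rules) selects which concept of which feature a rule attends to, and a
connection matrix ``M`` (N x K) weights each feature's contribution as
an exponent inside the parameterized T-norm, yielding firing strengths
``r_k``.  Layer 3 (inference) aggregates rules per class through the
parameterized T-conorm with a non-negative inference matrix ``W``
(K x C), and class scores are mapped to probabilities by a softmax.

Constrained quantities are stored unconstrained and mapped on access:
``A`` and ``M`` through a sigmoid into [0, 1], ``W`` through a softplus
into [0, inf), and membership cutoffs as a free ``a1`` plus three
softplus gaps (floored at 1e-3) so the ramp denominators never vanish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .fuzzy_core import (
    CONCEPTS,
    MembershipParams,
    SmoothnessState,
    membership,
    tconorm,
    tnorm,
)

__all__ = [
    "Feature",
    "FeatureSchema",
    "StandardizationStats",
    "NetworkParams",
    "encode",
    "rule_strengths",
    "infer",
    "forward",
    "project_params",
    "save_checkpoint",
    "load_checkpoint",
]

GAP_FLOOR = 1e-3


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str = "continuous"  # or "categorical"
    n_levels: int | None = None
    levels: tuple[str, ...] | None = None  # optional level names

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise ValueError(f"categorical feature {self.name!r} needs n_levels >= 2")

    @property
    def n_concepts(self) -> int:
        return 3 if self.kind == "continuous" else int(self.n_levels)

    def concept_names(self) -> tuple[str, ...]:
        if self.kind == "continuous":
            return CONCEPTS
        if self.levels is not None:
            return self.levels
        return tuple(f"level_{i}" for i in range(self.n_levels))


class FeatureSchema:
    """Ordered mixed continuous/categorical feature layout of the model."""

    def __init__(self, features: list[Feature]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.features = list(features)
        self._index = {f.name: i for i, f in enumerate(features)}

    def __len__(self):
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __eq__(self, other):
        return isinstance(other, FeatureSchema) and self.features == other.features

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def concept_dim(self) -> int:
        """Size of the concept axis: max(3, largest categorical level count)."""
        return max([3] + [f.n_concepts for f in self.features])

    @property
    def continuous_positions(self) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.kind == "continuous"]

    @property
    def categorical_positions(self) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.kind == "categorical"]

    @property
    def n_continuous(self) -> int:
        return len(self.continuous_positions)

    def index(self, name: str) -> int:
        return self._index[name]

    def concept_index(self, name: str, concept: str) -> int:
        """Slot of ``concept`` on the concept axis for feature ``name``."""
        f = self.features[self.index(name)]
        try:
            return f.concept_names().index(concept)
        except ValueError:
            raise KeyError(
                f"feature {name!r} has no concept {concept!r}; "
                f"known: {f.concept_names()}"
            ) from None

    def slot_mask(self) -> np.ndarray:
        """(N, D) 0/1 mask of structurally used concept slots."""
        mask = np.zeros((self.n_features, self.concept_dim))
        for i, f in enumerate(self.features):
            mask[i, : f.n_concepts] = 1.0
        return mask

    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "n_levels": f.n_levels,
                    "levels": list(f.levels) if f.levels else None,
                }
                for f in self.features
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            [
                Feature(
                    e["name"],
                    e["kind"],
                    e.get("n_levels"),
                    tuple(e["levels"]) if e.get("levels") else None,
                )
                for e in d["features"]
            ]
        )


@dataclass
class StandardizationStats:
    """Per-continuous-feature mean/SD and unit labels, for mapping model-space
    cutoffs back to clinical units."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)

    def unstandardize(self, name: str, x):
        i = self.names.index(name)
        return np.asarray(x) * self.sd[i] + self.mean[i]

    def standardize(self, name: str, x):
        i = self.names.index(name)
        return (np.asarray(x) - self.mean[i]) / self.sd[i]

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationStats":
        return cls(d["names"], d["mean"], d["sd"], d.get("units", {}))


@dataclass
class NetworkParams:
    """All trainable state, stored unconstrained (raw) plus the shared
    smoothness schedule and optional standardization statistics."""

    schema: FeatureSchema
    attention_raw: np.ndarray  # (N, D, K)
    connection_raw: np.ndarray  # (N, K)
    inference_raw: np.ndarray  # (K, C)
    cutoff_raw: np.ndarray  # (n_continuous, 4): a1, three gap pre-activations
    smoothness: SmoothnessState = field(default_factory=SmoothnessState)
    standardization: StandardizationStats | None = None

    def __post_init__(self):
        for name in ("attention_raw", "connection_raw", "inference_raw", "cutoff_raw"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        N, D, K = self.attention_raw.shape
        if (N, D) != (self.schema.n_features, self.schema.concept_dim):
            raise ValueError("attention shape inconsistent with schema")
        if self.connection_raw.shape != (N, K):
            raise ValueError("connection shape inconsistent with attention")
        if self.inference_raw.shape[0] != K:
            raise ValueError("inference shape inconsistent with attention")
        if self.cutoff_raw.shape != (self.schema.n_continuous, 4):
            raise ValueError("cutoff_raw must be (n_continuous, 4)")

    @property
    def n_rules(self) -> int:
        return self.attention_raw.shape[2]

    @property
    def n_classes(self) -> int:
        return self.inference_raw.shape[1]

    # -- constrained views ------------------------------------------------
    @property
    def attention(self) -> np.ndarray:
        """A in [0,1], structurally-unused concept slots zeroed."""
        return ad.sigmoid(self.attention_raw) * self.schema.slot_mask()[:, :, None]

    @property
    def connection(self) -> np.ndarray:
        return ad.sigmoid(self.connection_raw)

    @property
    def inference(self) -> np.ndarray:
        return ad.softplus(self.inference_raw)

    @property
    def cutoffs(self) -> np.ndarray:
        return _cutoffs_from_raw(self.cutoff_raw)

    @property
    def contribution(self) -> np.ndarray:
        """S[i,d,k] = A[i,d,k] * M[i,k]."""
        return self.attention * self.connection[:, None, :]

    @property
    def membership_params(self) -> MembershipParams:
        return MembershipParams(self.cutoffs, self.smoothness.eps)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.schema,
            self.attention_raw.copy(),
            self.connection_raw.copy(),
            self.inference_raw.copy(),
            self.cutoff_raw.copy(),
            SmoothnessState(**vars(self.smoothness)),
            self.standardization,
        )


def _cutoffs_from_raw(cutoff_raw):
    """a1 free; a2..a4 via cumulative softplus gaps floored at GAP_FLOOR."""
    is_t = isinstance(cutoff_raw, ad.Tensor)
    a1 = ad.take(cutoff_raw, [0], axis=-1) if is_t else ad.asarray(cutoff_raw)[..., :1]
    gaps_raw = ad.take(cutoff_raw, [1, 2, 3], axis=-1) if is_t else ad.asarray(cutoff_raw)[..., 1:]
    gaps = ad.softplus(gaps_raw) + GAP_FLOOR
    rest = a1 + ad.cumsum(gaps, axis=-1)
    return ad.concatenate([a1, rest], axis=-1)


def raw_from_cutoffs(cutoffs: np.ndarray) -> np.ndarray:
    """Inverse of the cutoff reparameterization (gaps floored if needed)."""
    cutoffs = np.atleast_2d(np.asarray(cutoffs, dtype=np.float64))
    gaps = np.maximum(np.diff(cutoffs, axis=-1) - GAP_FLOOR, 1e-9)
    # inverse softplus: log(exp(g) - 1), stable form
    inv = gaps + np.log1p(-np.exp(-gaps))
    return np.concatenate([cutoffs[..., :1], inv], axis=-1)


# -- layer operations -----------------------------------------------------

def encode(X, schema: FeatureSchema, params: MembershipParams | None = None, *,
           cutoffs=None, eps1=None):
    """Concept activations (B, N, D) for model-space rows.

    ``X`` is (B, N) (or a single row) in schema order: continuous columns
    hold standardized values, categorical columns hold integer level
    codes.  Continuous features fill their first three slots with
    (l, m, h); categorical features get one-hot level indicators; unused
    slots are zero.  Missing (NaN) values are rejected — imputation
    happens upstream in the cohort pipeline.

    ``cutoffs`` / ``eps1`` may override ``params`` (e.g. with an autodiff
    tensor for the differentiable training path).
    """
    if params is not None:
        cutoffs = cutoffs if cutoffs is not None else params.cutoffs
        eps1 = eps1 if eps1 is not None else params.eps1
    if eps1 is None:
        raise ValueError("encode needs MembershipParams or explicit cutoffs/eps1")
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != schema.n_features:
        raise ValueError(f"expected {schema.n_features} columns, got {X.shape[1]}")
    if np.isnan(X).any():
        raise ValueError("encode received missing values; impute before encoding")
    B, N, D = X.shape[0], schema.n_features, schema.concept_dim
    cont = schema.continuous_positions
    cat = schema.categorical_positions

    parts = []
    if cont:
        deg3 = membership(X[:, cont], cutoffs, eps1, validate=False)  # (B, Nc, 3)
        if D > 3:
            pad = np.zeros((B, len(cont), D - 3))
            deg3 = ad.concatenate([deg3, pad], axis=-1)
        parts.append(deg3)
    if cat:
        onehot = np.zeros((B, len(cat), D))
        for j, pos in enumerate(cat):
            codes = X[:, pos]
            levels = schema.features[pos].n_concepts
            if np.any((codes < 0) | (codes >= levels) | (codes != np.round(codes))):
                raise ValueError(
                    f"feature {schema.features[pos].name!r}: level codes must be "
                    f"integers in [0, {levels})"
                )
            onehot[np.arange(B), j, codes.astype(int)] = 1.0
        parts.append(onehot)

    combined = parts[0] if len(parts) == 1 else ad.concatenate(parts, axis=1)
    order = np.argsort(np.array(cont + cat))
    out = ad.take(combined, order, axis=1) if isinstance(combined, ad.Tensor) else (
        ad.asarray(combined)[:, order]
    )
    if single and not isinstance(out, ad.Tensor):
        return out[0]
    return out


def rule_strengths(encoded, params: NetworkParams, *, attention=None, connection=None,
                   eps2=None):
    """Firing strengths r (B, K) from concept activations (B, N, D).

    Per rule k, the attended degree of feature i is
    ``x~[i,k] = sum_d A[i,d,k] * deg[i,d]``; the rule fires at
    ``r_k = T_eps2(x~[., k]; exponents M[., k])``.
    """
    A = attention if attention is not None else params.attention
    M = connection if connection is not None else params.connection
    e2 = eps2 if eps2 is not None else params.smoothness.eps
    if isinstance(encoded, ad.Tensor):
        enc, single = encoded, False
    else:
        enc = np.asarray(encoded, dtype=np.float64)
        single = enc.ndim == 2
        if single:
            enc = enc[None]
    xt = ad.einsum2("bid,idk->bik", enc, A)
    r = tnorm(xt, M, e2, axis=1)
    if single and not isinstance(r, ad.Tensor):
        return r[0]
    return r


def infer(r, params: NetworkParams, *, inference=None, eps3=None):
    """Class scores O (B, C): T-conorm over rules of W[k,c] * r_k."""
    W = inference if inference is not None else params.inference
    e3 = eps3 if eps3 is not None else params.smoothness.eps
    single = not isinstance(r, ad.Tensor) and np.asarray(r).ndim == 1
    rv = r if isinstance(r, ad.Tensor) else np.atleast_2d(np.asarray(r, dtype=np.float64))
    K = W.shape[0]
    wr = ad.reshape(rv, (rv.shape[0], K, 1)) * W
    O = tconorm(wr, e3, axis=1)
    if single and not isinstance(O, ad.Tensor):
        return O[0]
    return O


def softmax(O, axis=-1):
    lse = ad.logsumexp(O, axis=axis, keepdims=True)
    return ad.exp(O - lse)


def forward(X, schema: FeatureSchema, params: NetworkParams):
    """Class probabilities softmax(O) for model-space rows."""
    enc = encode(X, schema, params.membership_params)
    single = np.asarray(X).ndim == 1
    if single:
        enc = enc[None]
    r = rule_strengths(enc, params)
    O = infer(r, params)
    p = softmax(O)
    return p[0] if single else p


def project_params(attention=None, connection=None, inference=None, cutoffs=None):
    """Idempotent repair of externally supplied constrained parameters.

    Clips attention/connection into [0, 1] and inference into [0, inf);
    sorts each cutoff row and enforces positive ramp gaps.  Already-valid
    inputs pass through unchanged.  Returns a dict of the supplied keys.
    """
    out = {}
    if attention is not None:
        out["attention"] = np.clip(np.asarray(attention, dtype=np.float64), 0.0, 1.0)
    if connection is not None:
        out["connection"] = np.clip(np.asarray(connection, dtype=np.float64), 0.0, 1.0)
    if inference is not None:
        out["inference"] = np.maximum(np.asarray(inference, dtype=np.float64), 0.0)
    if cutoffs is not None:
        c = np.sort(np.atleast_2d(np.asarray(cutoffs, dtype=np.float64)), axis=-1)
        # ramp gaps a2-a1 and a4-a3 must stay positive
        c[..., 1] = np.maximum(c[..., 1], c[..., 0] + GAP_FLOOR)
        c[..., 2] = np.maximum(c[..., 2], c[..., 1])
        c[..., 3] = np.maximum(c[..., 3], c[..., 2] + GAP_FLOOR)
        out["cutoffs"] = c
    return out


# -- checkpointing --------------------------------------------------------

def save_checkpoint(params: NetworkParams, path):
    """Serialize the full model to JSON; round-trips bit-identically."""
    doc = {
        "format": "tgfnn-checkpoint",
        "version": 1,
        "schema": params.schema.to_dict(),
        "attention_raw": params.attention_raw.tolist(),
        "connection_raw": params.connection_raw.tolist(),
        "inference_raw": params.inference_raw.tolist(),
        "cutoff_raw": params.cutoff_raw.tolist(),
        "smoothness": vars(params.smoothness).copy(),
        "standardization": (
            params.standardization.to_dict() if params.standardization else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_checkpoint(path) -> NetworkParams:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "tgfnn-checkpoint":
        raise ValueError(f"{path} is not a model checkpoint")
    return NetworkParams(
        FeatureSchema.from_dict(doc["schema"]),
        np.array(doc["attention_raw"], dtype=np.float64),
        np.array(doc["connection_raw"], dtype=np.float64),
        np.array(doc["inference_raw"], dtype=np.float64),
        np.array(doc["cutoff_raw"], dtype=np.float64),
        SmoothnessState(**doc["smoothness"]),
        StandardizationStats.from_dict(doc["standardization"])
        if doc.get("standardization")
        else None,
    )
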