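"""Jam-level mixture descriptors and network feature vectors.

A jam is treated as a five-component mixture (water, citric acid, glucose,
sucrose, anthocyanin); its mixture descriptor vector is the mass-fraction
weighted average of the component descriptor vectors:

    MD_jam = sum_c  w_c * MD_c,    sum_c w_c = 1.

Gelling agents (HM/LM pectin, xanthan gum), pH and acidity are separate
covariates, not part of the mixture rule.  The network input is a fixed,
ordered set of exactly ten named features drawn from the covariates, the
component percentages and the fifteen mixture descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import COMPONENT_ORDER
from .descriptors import DESCRIPTOR_NAMES, DescriptorVector

__all__ = [
    "MixtureComposition",
    "JamRecord",
    "FeatureConfig",
    "MinMaxScaler",
    "mixture_descriptor",
    "build_feature_vector",
    "feature_matrix",
    "scale_features",
    "default_feature_config",
    "N_FEATURES",
]

N_FEATURES = 10

_COVARIATES = ("time", "pct_HM_pectin", "pct_LM_pectin", "pct_xanthan", "pH", "acidity")
_COMPONENT_FEATURES = tuple(f"pct_{c}" for c in COMPONENT_ORDER)


@dataclass(frozen=True)
class MixtureComposition:
    """Mass fractions of the five descriptor-bearing components."""

    fractions: dict[str, float]

    def __post_init__(self):
        missing = set(COMPONENT_ORDER) - set(self.fractions)
        if missing:
            raise ValueError(f"missing component fractions: {sorted(missing)}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("mass fractions must be non-negative")
        total = sum(self.fractions[c] for c in COMPONENT_ORDER)
        if total <= 0:
            raise ValueError("composition sums to zero")
        object.__setattr__(
            self,
            "fractions",
            {c: self.fractions[c] / total for c in COMPONENT_ORDER},
        )

    def __getitem__(self, component: str) -> float:
        return self.fractions[component]

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[c] for c in COMPONENT_ORDER])


@dataclass(frozen=True)
class JamRecord:
    """One observation: covariates, composition and the three responses."""

    formulation: str
    time: float
    pct_HM_pectin: float
    pct_LM_pectin: float
    pct_xanthan: float
    pH: float
    acidity: float
    composition: MixtureComposition
    hardness: float | None = None
    water_activity: float | None = None
    adhesiveness: float | None = None

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("storage time must be non-negative")
        if self.water_activity is not None and not (0 < self.water_activity < 1):
            raise ValueError("water activity must lie in (0, 1)")


@dataclass(frozen=True)
class FeatureConfig:
    """Ordered list of exactly ten named input features."""

    features: tuple[str, ...]

    def __post_init__(self):
        if len(self.features) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.features)}")
        if len(set(self.features)) != N_FEATURES:
            raise ValueError("feature names must be unique")
        valid = set(_COVARIATES) | set(_COMPONENT_FEATURES) | set(DESCRIPTOR_NAMES)
        bad = [f for f in self.features if f not in valid]
        if bad:
            raise ValueError(f"unknown feature names: {bad}")


def mixture_descriptor(
    comp: MixtureComposition, component_vectors: dict[str, DescriptorVector]
) -> DescriptorVector:
    """Mass-fraction weighted average of the component descriptor vectors."""
    missing = set(COMPONENT_ORDER) - set(component_vectors)
    if missing:
        raise ValueError(f"missing component descriptor vectors: {sorted(missing)}")
    values = {
        name: sum(comp[c] * component_vectors[c][name] for c in COMPONENT_ORDER)
        for name in DESCRIPTOR_NAMES
    }
    return DescriptorVector(values=values)


def build_feature_vector(
    rec: JamRecord,
    cfg: FeatureConfig,
    component_vectors: dict[str, DescriptorVector],
) -> np.ndarray:
    """Extract the ordered ten-element input vector for one record.

    Mixture descriptors are computed on demand from the record's
    composition; response variables are never part of the input.
    """
    md = None
    out = np.empty(N_FEATURES)
    for k, name in enumerate(cfg.features):
        if name in _COVARIATES:
            out[k] = getattr(rec, name)
        elif name in _COMPONENT_FEATURES:
            out[k] = rec.composition[name.removeprefix("pct_")] * 100.0
        else:  # mixture descriptor
            if md is None:
                md = mixture_descriptor(rec.composition, component_vectors)
            out[k] = md[name]
    return out


def feature_matrix(records, cfg, component_vectors) -> np.ndarray:
    """Stacked feature vectors for a sequence of records."""
    return np.vstack([build_feature_vector(r, cfg, component_vectors) for r in records])


@dataclass
class MinMaxScaler:
    """Per-column min-max map onto [-1, 1]; constant columns map to 0.

    (scikit-learn's scaler sends constant columns to the range minimum,
    which would pin a constant feature at -1; here they go to 0.)
    """

    lo: np.ndarray = field(default=None)
    hi: np.ndarray = field(default=None)

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two rows")
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        span = self.hi - self.lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 2.0 * (X - self.lo) / span - 1.0
        return np.where(span == 0, 0.0, out)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, float)
        span = self.hi - self.lo
        return np.where(span == 0, self.lo, self.lo + (Xs + 1.0) * span / 2.0)


def scale_features(X: np.ndarray) -> tuple[np.ndarray, MinMaxScaler]:
    """Scale a feature matrix onto [-1, 1] column-wise."""
    scaler = MinMaxScaler()
    return scaler.fit_transform(X), scaler


def default_feature_config(
    records=None, component_vectors=None
) -> FeatureConfig:
    """Default ten-feature set.

    The six tabulated covariates (time, %HM, %LM, %xanthan, pH, acidity)
    plus the four mixture descriptors with the highest variance over the
    provided records.  Without records, a fixed descriptor quartet is used.
    """
    if records is None:
        extra = ("MW", "X1sol", "SAtot", "Pol")
    else:
        rows = [
            mixture_descriptor(r.composition, component_vectors).as_array()
            for r in records
        ]
        var = pd.DataFrame(rows, columns=list(DESCRIPTOR_NAMES)).var(axis=0)
        extra = tuple(var.sort_values(ascending=False).index[:4])
    return FeatureConfig(features=_COVARIATES + extra)
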