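"""MaxEnt feature expansions: linear, quadratic, product, hinge, threshold.

Environmental layers are normalised to [0,1] using background min/max
before expansion, so every feature column also lies in [0,1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import ParameterError

__all__ = ["FeatureSpec", "Normalizer", "build_features", "feature_names"]

FEATURE_CLASSES = frozenset("LQHPT")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand and how many hinge/threshold knots."""

    classes: str = "LQ"
    n_knots: int = 20

    def __post_init__(self):
        cls = self.classes.upper()
        bad = set(cls) - FEATURE_CLASSES
        if bad or not cls:
            raise ParameterError(
                f"feature classes must be a non-empty subset of LQHPT, got "
                f"{self.classes!r}"
            )
        object.__setattr__(self, "classes", cls)
        if self.n_knots < 2:
            raise ParameterError("n_knots must be >= 2")

    def has(self, c: str) -> bool:
        return c in self.classes


@dataclass(frozen=True)
class Normalizer:
    """Per-layer min/max from the background (plus presences) pool."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray) -> "Normalizer":
        return cls(np.nanmin(X, axis=0), np.nanmax(X, axis=0))

    def __call__(self, X: np.ndarray, clamp: bool = True) -> tuple[np.ndarray, int]:
        """Normalise to [0,1]; returns (values, count of clamped entries)."""
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        Z = (np.asarray(X, dtype=float) - self.mins) / span
        n_clamped = 0
        if clamp:
            n_clamped = int(((Z < 0) | (Z > 1)).sum())
            Z = np.clip(Z, 0.0, 1.0)
        return Z, n_clamped


def _knots(n: int) -> np.ndarray:
    """Evenly spaced interior knots on (0, 1)."""
    return np.linspace(0.0, 1.0, n + 2)[1:-1]


def feature_names(layer_names: list[str], spec: FeatureSpec,
                  constant_layers: frozenset[int] = frozenset()) -> list[str]:
    names: list[str] = []
    L = [n for i, n in enumerate(layer_names)]
    if spec.has("L"):
        names += [f"L({n})" for n in L]
    if spec.has("Q"):
        names += [f"Q({n})" for i, n in enumerate(L) if i not in constant_layers]
    if spec.has("H"):
        for i, n in enumerate(L):
            if i in constant_layers:
                continue
            for k in _knots(spec.n_knots):
                names.append(f"H+({n},{k:.3f})")
                names.append(f"H-({n},{k:.3f})")
    if spec.has("P"):
        for i in range(len(L)):
            for j in range(i + 1, len(L)):
                names.append(f"P({L[i]},{L[j]})")
    if spec.has("T"):
        for i, n in enumerate(L):
            if i in constant_layers:
                continue
            for k in _knots(spec.n_knots):
                names.append(f"T({n},{k:.3f})")
    return names


def build_features(
    Z: np.ndarray, spec: FeatureSpec,
    constant_layers: frozenset[int] | None = None,
) -> tuple[np.ndarray, frozenset[int]]:
    """Expand normalised layers (values in [0,1]) into the design matrix.

    L = identity; Q = squares; P = pairwise products; H = forward and
    reverse hinges at evenly spaced knots; T = step functions at the same
    knots. Hinge and step columns are scaled to [0,1]. Constant layers
    contribute only their (constant) linear column; their derived features
    are dropped with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if constant_layers is None:
        constant_layers = frozenset(
            int(i) for i in range(p) if np.nanstd(Z[:, i]) == 0.0
        )
        if constant_layers:
            warnings.warn(
                f"layers {sorted(constant_layers)} are constant; dropping "
                "their quadratic/hinge/threshold features"
            )
    cols: list[np.ndarray] = []
    variable = [i for i in range(p) if i not in constant_layers]
    if spec.has("L"):
        cols.append(Z)
    if spec.has("Q"):
        cols.append(Z[:, variable] ** 2)
    if spec.has("H"):
        ks = _knots(spec.n_knots)
        for i in variable:
            x = Z[:, i][:, None]
            fwd = np.clip((x - ks) / (1.0 - ks), 0.0, None)
            rev = np.clip((ks - x) / ks, 0.0, None)
            inter = np.empty((n, 2 * len(ks)))
            inter[:, 0::2] = fwd
            inter[:, 1::2] = rev
            cols.append(inter)
    if spec.has("P"):
        prods = [
            (Z[:, i] * Z[:, j])[:, None]
            for i in range(p)
            for j in range(i + 1, p)
        ]
        if prods:
            cols.append(np.hstack(prods))
    if spec.has("T"):
        ks = _knots(spec.n_knots)
        for i in variable:
            cols.append((Z[:, i][:, None] > ks).astype(float))
    return np.hstack(cols) if cols else np.empty((n, 0)), constant_layers
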