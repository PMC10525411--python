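"""Feature-class expansion for the maximum-entropy SDM.

Covariates are expanded into the classic MaxEnt feature classes:

* L (linear)    — min-max scaled covariate
* Q (quadratic) — min-max scaled square
* P (product)   — min-max scaled pairwise product
* T (threshold) — step indicators 1{x > k} at knots
* H (hinge)     — forward max(0, x-k)/(max-k) and reverse max(0, k-x)/(k-min)

Every feature lands in [0, 1].  Hinge and threshold knots are placed at
equally spaced quantiles of the background distribution so the expansion is
scale-free and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureSpec", "FeatureMeta", "FeatureExpander", "parse_classes"]

VALID_CLASSES = frozenset("LQPTH")


def parse_classes(classes: str | set[str] | frozenset[str]) -> frozenset[str]:
    """Normalize a feature-class declaration like ``"LQHPT"`` or a set."""
    if isinstance(classes, str):
        classes = set(classes.upper())
    classes = frozenset(classes)
    if not classes:
        raise ValueError("feature classes must be non-empty")
    bad = classes - VALID_CLASSES
    if bad:
        raise ValueError(f"unknown feature classes: {sorted(bad)}")
    return classes


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to build and how many knots to use."""

    classes: frozenset[str] = frozenset("LQHPT")
    n_hinge_knots: int = 50
    n_threshold_knots: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", parse_classes(self.classes))
        if self.n_hinge_knots < 2:
            raise ValueError("need at least 2 hinge knots")
        if self.n_threshold_knots < 1:
            raise ValueError("need at least 1 threshold knot")

    @property
    def label(self) -> str:
        return "".join(c for c in "LQHPT" if c in self.classes)


@dataclass(frozen=True)
class FeatureMeta:
    """Provenance of one design-matrix column."""

    cls: str                      # L, Q, P, T or H
    covariates: tuple[str, ...]   # one name, or two for products
    knot: float | None = None     # threshold/hinge knot (covariate units)
    direction: str | None = None  # "fwd"/"rev" for hinges
    lo: float = 0.0               # scaling bounds in raw units
    hi: float = 1.0


def _minmax(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


class FeatureExpander:
    """Builds and re-applies a feature expansion.

    The expansion is calibrated on training data (ranges and knot positions
    come from the training covariates, knots from the background rows) and
    can then be applied to any matrix with the same covariate columns, so
    projection onto new rasters uses the training normalization.
    """

    def __init__(
        self,
        spec: FeatureSpec,
        covariate_names: list[str],
        X_train: np.ndarray,
        background_rows: np.ndarray | None = None,
    ) -> None:
        X_train = np.asarray(X_train, dtype=float)
        if X_train.ndim != 2 or X_train.shape[1] != len(covariate_names):
            raise ValueError("training matrix does not match covariate names")
        if not np.all(np.isfinite(X_train)):
            raise ValueError("training covariates must be finite")
        self.spec = spec
        self.names = list(covariate_names)
        self.lo = X_train.min(axis=0)
        self.hi = X_train.max(axis=0)
        bg = X_train if background_rows is None else np.asarray(background_rows, float)
        self.meta: list[FeatureMeta] = []
        self._build_meta(bg)

    # -- calibration -------------------------------------------------------

    def _knots(self, x: np.ndarray, n: int, interior: bool) -> np.ndarray:
        """Equally spaced quantiles of the background values.

        Interior knots (thresholds, hinges) exclude the extremes so every
        feature varies on the training data.
        """
        qs = np.linspace(0, 1, n + 2)[1:-1] if interior else np.linspace(0, 1, n)
        return np.unique(np.quantile(x, qs))

    def _build_meta(self, bg: np.ndarray) -> None:
        spec, names = self.spec, self.names
        p = len(names)
        constant = [j for j in range(p) if self.hi[j] <= self.lo[j]]
        if constant and (spec.classes & {"Q", "H", "T"}):
            warnings.warn(
                f"constant covariates contribute only linear features: "
                f"{[names[j] for j in constant]}"
            )
        linear_cols = range(p) if "L" in spec.classes else constant
        for j in linear_cols:
            self.meta.append(
                FeatureMeta("L", (names[j],), lo=self.lo[j], hi=self.hi[j])
            )
        for j in range(p):
            if j in constant:
                continue
            if "Q" in spec.classes:
                qlo = 0.0 if self.lo[j] < 0 < self.hi[j] else float(
                    min(self.lo[j] ** 2, self.hi[j] ** 2)
                )
                qhi = float(max(self.lo[j] ** 2, self.hi[j] ** 2))
                self.meta.append(FeatureMeta("Q", (names[j],), lo=qlo, hi=qhi))
        if "P" in spec.classes:
            for j in range(p):
                for k in range(j + 1, p):
                    corners = np.array(
                        [
                            self.lo[j] * self.lo[k],
                            self.lo[j] * self.hi[k],
                            self.hi[j] * self.lo[k],
                            self.hi[j] * self.hi[k],
                        ]
                    )
                    self.meta.append(
                        FeatureMeta(
                            "P",
                            (names[j], names[k]),
                            lo=float(corners.min()),
                            hi=float(corners.max()),
                        )
                    )
        for j in range(p):
            if j in constant:
                continue
            if "T" in spec.classes:
                for k in self._knots(bg[:, j], spec.n_threshold_knots, interior=True):
                    self.meta.append(FeatureMeta("T", (names[j],), knot=float(k)))
            if "H" in spec.classes:
                for k in self._knots(bg[:, j], spec.n_hinge_knots, interior=True):
                    if self.hi[j] > k:
                        self.meta.append(
                            FeatureMeta(
                                "H", (names[j],), knot=float(k), direction="fwd",
                                lo=float(k), hi=float(self.hi[j]),
                            )
                        )
                    if k > self.lo[j]:
                        self.meta.append(
                            FeatureMeta(
                                "H", (names[j],), knot=float(k), direction="rev",
                                lo=float(self.lo[j]), hi=float(k),
                            )
                        )

    # -- application -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.meta)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Expand a (n, p) covariate matrix into the (n, n_features) design matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.names):
            raise ValueError("matrix does not match the expander's covariates")
        idx = {n: j for j, n in enumerate(self.names)}
        cols = np.empty((X.shape[0], len(self.meta)))
        for f, m in enumerate(self.meta):
            if m.cls == "L":
                cols[:, f] = _minmax(X[:, idx[m.covariates[0]]], m.lo, m.hi)
            elif m.cls == "Q":
                cols[:, f] = _minmax(X[:, idx[m.covariates[0]]] ** 2, m.lo, m.hi)
            elif m.cls == "P":
                prod = X[:, idx[m.covariates[0]]] * X[:, idx[m.covariates[1]]]
                cols[:, f] = _minmax(prod, m.lo, m.hi)
            elif m.cls == "T":
                cols[:, f] = (X[:, idx[m.covariates[0]]] > m.knot).astype(float)
            elif m.cls == "H":
                x = X[:, idx[m.covariates[0]]]
                if m.direction == "fwd":
                    cols[:, f] = np.clip((x - m.knot) / (m.hi - m.knot), 0.0, None)
                else:
                    cols[:, f] = np.clip((m.knot - x) / (m.knot - m.lo), 0.0, None)
        return np.clip(cols, 0.0, 1.0)

    def feature_classes(self) -> np.ndarray:
        return np.array([m.cls for m in self.meta])

    def covariate_of(self) -> list[tuple[str, ...]]:
        return [m.covariates for m in self.meta]
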