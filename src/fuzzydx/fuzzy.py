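"""Mamdani fuzzy-inference primitives.

A linguistic variable is the tuple (name, domain, ordered labels, one fuzzy
set per label).  Crisp inputs are fuzzified into per-label membership
degrees, rule firing strengths clip the output sets (min implication), the
clipped sets are combined with max, and the crisp diagnosis value is the
centroid (centre of gravity) of the aggregated set on a uniform grid.

Membership functions are triangular, trapezoidal, or singleton; the first
two evaluate as exact piecewise-linear interpolants, the singleton form is
used for nonfuzzy ordinals such as APOE4 allele counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyOutput, NonFiniteInput

SINGLETON_TOL = 1e-9

_SHAPES = ("triangular", "trapezoidal", "singleton")


@dataclass(frozen=True)
class MembershipFunction:
    """A normalized fuzzy set on the real line.

    ``breakpoints`` are (a, b, c) for triangular (peak at b), (a, b, c, d)
    for trapezoidal (plateau on [b, c]) and a single point (p,) for
    singleton sets.  Breakpoints must be non-decreasing.
    """

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown membership shape {self.shape!r}")
        pts = tuple(float(p) for p in self.breakpoints)
        object.__setattr__(self, "breakpoints", pts)
        expected = {"triangular": 3, "trapezoidal": 4, "singleton": 1}[self.shape]
        if len(pts) != expected:
            raise ValueError(
                f"{self.shape} membership function needs {expected} breakpoints, got {len(pts)}"
            )
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"breakpoints must be non-decreasing: {pts}")

    # ---- evaluation --------------------------------------------------------

    def _corners(self) -> tuple[float, float, float, float]:
        """Internal trapezoid view (a, b, c, d); triangles have b == c."""
        if self.shape == "triangular":
            a, b, c = self.breakpoints
            return a, b, b, c
        a, b, c, d = self.breakpoints
        return a, b, c, d

    def __call__(self, x: float) -> float:
        """Exact scalar membership degree in [0, 1]; total on the reals."""
        if self.shape == "singleton":
            return 1.0 if abs(x - self.breakpoints[0]) <= SINGLETON_TOL else 0.0
        a, b, c, d = self._corners()
        if x < a or x > d:
            return 0.0
        if b <= x <= c:
            return 1.0
        if x < b:  # rising edge, b > a here
            return (x - a) / (b - a)
        return (d - x) / (d - c)  # falling edge, d > c here

    def evaluate_array(self, x: np.ndarray) -> np.ndarray:
        """Vectorized membership evaluation (same semantics as ``__call__``)."""
        x = np.asarray(x, dtype=float)
        if self.shape == "singleton":
            return (np.abs(x - self.breakpoints[0]) <= SINGLETON_TOL).astype(float)
        a, b, c, d = self._corners()
        out = np.zeros_like(x)
        if b > a:
            rise = (x >= a) & (x < b)
            out[rise] = (x[rise] - a) / (b - a)
        plateau = (x >= b) & (x <= c)
        out[plateau] = 1.0
        if d > c:
            fall = (x > c) & (x <= d)
            out[fall] = (d - x[fall]) / (d - c)
        return out

    @property
    def support(self) -> tuple[float, float]:
        return self.breakpoints[0], self.breakpoints[-1]


def triangular(a: float, b: float, c: float) -> MembershipFunction:
    return MembershipFunction("triangular", (a, b, c))


def trapezoidal(a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction("trapezoidal", (a, b, c, d))


def singleton(p: float) -> MembershipFunction:
    return MembershipFunction("singleton", (p,))


def evaluate_membership(mf: MembershipFunction, x: float) -> float:
    """Functional alias for ``mf(x)``."""
    return mf(x)


@dataclass(frozen=True)
class LinguisticVariable:
    """A labelled fuzzy partition over a closed numeric domain.

    ``labels`` is ordered (least to greatest for graded scales, or the
    severity order CN..AD for the diagnosis output variable); ``sets`` maps
    each label to its membership function.  ``aliases`` are alternative
    spellings accepted by rule files and cohort headers.
    """

    name: str
    domain: tuple[float, float]
    labels: tuple[str, ...]
    sets: Mapping[str, MembershipFunction]
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        lo, hi = (float(self.domain[0]), float(self.domain[1]))
        if not lo < hi:
            raise ValueError(f"{self.name}: degenerate domain {self.domain}")
        object.__setattr__(self, "domain", (lo, hi))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"{self.name}: duplicate labels")
        if set(self.sets) != set(self.labels):
            raise ValueError(f"{self.name}: need exactly one fuzzy set per label")
        eps = 1e-9 * (hi - lo)
        for label, mf in self.sets.items():
            s_lo, s_hi = mf.support
            if s_lo < lo - eps or s_hi > hi + eps:
                raise ValueError(
                    f"{self.name}/{label}: support {mf.support} outside domain {self.domain}"
                )

    def set_for(self, label: str) -> MembershipFunction:
        return self.sets[label]

    def resolve_label(self, label: str) -> str | None:
        """Case-insensitive label lookup; returns the canonical spelling."""
        for known in self.labels:
            if known.lower() == label.lower():
                return known
        return None


@dataclass(frozen=True)
class FuzzifiedValue:
    """Membership degrees of one crisp input in every set of its variable."""

    variable: str
    x0: float
    degrees: Mapping[str, float]

    def __getitem__(self, label: str) -> float:
        return self.degrees[label]


def fuzzify(var: LinguisticVariable, x0: float) -> FuzzifiedValue:
    """Map a crisp input to its degree in every fuzzy set of ``var``.

    Inputs outside the variable's domain are clamped to the nearest bound
    (with a warning): clinical values can legitimately exceed nominal
    ranges and the extreme linguistic label should then apply fully.
    NaN/inf raise :class:`NonFiniteInput` so callers treat the feature as
    missing rather than silently fuzzifying garbage.
    """
    x0 = float(x0)
    if not np.isfinite(x0):
        raise NonFiniteInput(f"{var.name}: non-finite crisp input {x0!r}")
    lo, hi = var.domain
    if x0 < lo or x0 > hi:
        warnings.warn(
            f"{var.name}: input {x0} outside domain [{lo}, {hi}]; clamping",
            stacklevel=2,
        )
        x0 = min(max(x0, lo), hi)
    degrees = {label: var.sets[label](x0) for label in var.labels}
    return FuzzifiedValue(variable=var.name, x0=x0, degrees=degrees)


@dataclass(frozen=True)
class OutputFuzzySet:
    """Per-label activation levels over the output partition.

    Implication is min (clipping); the clip is applied lazily at
    defuzzification time so the activation vector stays a compact summary.
    """

    partition: LinguisticVariable
    activations: Mapping[str, float]

    def __post_init__(self):
        acts = dict(self.activations)
        if set(acts) != set(self.partition.labels):
            raise ValueError("activation labels must equal the output partition labels")
        for label, level in acts.items():
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"activation for {label} outside [0, 1]: {level}")
        object.__setattr__(self, "activations", acts)


def aggregate_outputs(
    activations: Iterable[tuple[str, float]],
    partition: LinguisticVariable,
) -> OutputFuzzySet:
    """Combine per-rule (label, strength) pairs with the max t-conorm."""
    levels = {label: 0.0 for label in partition.labels}
    for label, strength in activations:
        if label not in levels:
            raise ValueError(f"unknown output label {label!r}")
        if not 0.0 <= strength <= 1.0:
            raise ValueError(f"firing strength outside [0, 1]: {strength}")
        levels[label] = max(levels[label], float(strength))
    return OutputFuzzySet(partition=partition, activations=levels)


def defuzzify_cog(out: OutputFuzzySet, resolution: int = 1001) -> float:
    """Centre-of-gravity defuzzification on a uniform grid.

    The aggregated set is the pointwise max of each output membership
    function clipped at its activation level; the centroid is computed by
    trapezoidal integration over ``resolution`` grid points.
    """
    if resolution < 100:
        raise ValueError("resolution must be at least 100")
    if max(out.activations.values(), default=0.0) <= 0.0:
        raise EmptyOutput("no rule fired; the output fuzzy set is empty")
    lo, hi = out.partition.domain
    grid = np.linspace(lo, hi, int(resolution))
    envelope = np.zeros_like(grid)
    for label in out.partition.labels:
        level = out.activations[label]
        if level <= 0.0:
            continue
        clipped = np.minimum(out.partition.sets[label].evaluate_array(grid), level)
        np.maximum(envelope, clipped, out=envelope)
    mass = np.trapezoid(envelope, grid)
    moment = np.trapezoid(envelope * grid, grid)
    dv = float(moment / mass)
    return min(max(dv, lo), hi)


def classify(dv: float, out_partition: LinguisticVariable) -> str:
    """Label with maximal output membership at ``dv``.

    Ties break toward the earlier label in the partition order, which for
    the diagnosis variable is the less severe class (CN < SMC < EMCI <
    LMCI < AD).
    """
    best_label = out_partition.labels[0]
    best_degree = -1.0
    for label in out_partition.labels:
        degree = out_partition.sets[label](dv)
        if degree > best_degree:
            best_label, best_degree = label, degree
    return best_label
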