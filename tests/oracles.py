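"""Independent literal Mamdani oracle used to cross-check the engine.

Written as plain branch-by-branch arithmetic and explicit loops on a
description-of-the-system dict, deliberately sharing no code with the
package.  The fine-grid centroid uses a manually coded trapezoid rule.
"""

from __future__ import annotations

import numpy as np


def mf_eval(shape: str, pts, x: float) -> float:
    if shape == "singleton":
        return 1.0 if abs(x - pts[0]) <= 1e-9 else 0.0
    if shape == "triangular":
        a, b, c = pts
        if x < a or x > c:
            return 0.0
        if x == b:
            return 1.0
        if x < b:
            return (x - a) / (b - a)
        return (c - x) / (c - b)
    a, b, c, d = pts
    if x < a or x > d:
        return 0.0
    if b <= x <= c:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (d - x) / (d - c)


def oracle_dv(system: dict, inputs: dict, resolution: int) -> float | None:
    """Literal min/max/COG evaluation of a described fuzzy system.

    ``system``: {"inputs": {name: {"domain":..,"sets":{label:(shape,pts)}}},
                 "output": same structure, "out_order": [labels],
                 "rules": [([(var,label),...], out_label), ...]}
    Returns None when no rule fires.
    """
    degrees = {}
    for name, var in system["inputs"].items():
        if name not in inputs:
            continue
        x = float(inputs[name])
        lo, hi = var["domain"]
        if x < lo:
            x = lo
        if x > hi:
            x = hi
        degrees[name] = {
            label: mf_eval(shape, pts, x) for label, (shape, pts) in var["sets"].items()
        }
    levels = {label: 0.0 for label in system["out_order"]}
    for atoms, out_label in system["rules"]:
        strength = 1.0
        fired = True
        for var, label in atoms:
            if var not in degrees:
                fired = False
                break
            if degrees[var][label] < strength:
                strength = degrees[var][label]
        if fired and strength > 0.0 and strength > levels[out_label]:
            levels[out_label] = strength
    if max(levels.values()) <= 0.0:
        return None
    lo, hi = system["output"]["domain"]
    xs = np.linspace(lo, hi, resolution)
    env = np.zeros(resolution)
    for label in system["out_order"]:
        level = levels[label]
        if level <= 0.0:
            continue
        shape, pts = system["output"]["sets"][label]
        vals = np.array([min(mf_eval(shape, pts, float(x)), level) for x in xs])
        env = np.maximum(env, vals)
    dx = xs[1] - xs[0]
    area = dx * (env.sum() - 0.5 * (env[0] + env[-1]))
    moment = dx * ((env * xs).sum() - 0.5 * (env[0] * xs[0] + env[-1] * xs[-1]))
    return moment / area


def _mf_eval_vec(shape: str, pts, xs: np.ndarray) -> np.ndarray:
    """Vectorized piecewise formulas (arithmetic written out independently)."""
    if shape == "singleton":
        return np.where(np.abs(xs - pts[0]) <= 1e-9, 1.0, 0.0)
    if shape == "triangular":
        a, b, c = pts
        left = (xs - a) / (b - a) if b > a else np.ones_like(xs)
        right = (c - xs) / (c - b) if c > b else np.ones_like(xs)
        return np.clip(np.minimum(left, right), 0.0, 1.0)
    a, b, c, d = pts
    left = (xs - a) / (b - a) if b > a else np.ones_like(xs)
    right = (d - xs) / (d - c) if d > c else np.ones_like(xs)
    return np.clip(np.minimum(left, right), 0.0, 1.0)


def fine_grid_centroid(output: dict, out_order, levels: dict, n_points: int = 1_000_000) -> float:
    """Trapezoidal-integration centroid of the clipped-max envelope."""
    lo, hi = output["domain"]
    xs = np.linspace(lo, hi, n_points)
    env = np.zeros(n_points)
    for label in out_order:
        level = levels[label]
        if level <= 0.0:
            continue
        shape, pts = output["sets"][label]
        env = np.maximum(env, np.minimum(_mf_eval_vec(shape, pts, xs), level))
    dx = xs[1] - xs[0]
    area = dx * (env.sum() - 0.5 * (env[0] + env[-1]))
    moment = dx * ((env * xs).sum() - 0.5 * (env[0] * xs[0] + env[-1] * xs[-1]))
    return float(moment / area)


# ---- random small systems ---------------------------------------------------

_OUT_LABELS = ("CN", "SMC", "EMCI", "LMCI", "AD")


def _random_set(rng, lo, hi):
    if rng.random() < 0.5:
        pts = tuple(sorted(rng.uniform(lo, hi, 3)))
        return ("triangular", pts)
    pts = tuple(sorted(rng.uniform(lo, hi, 4)))
    return ("trapezoidal", pts)


def random_system(rng) -> tuple[dict, dict]:
    """A random small system description plus crisp inputs for it."""
    n_inputs = rng.integers(1, 5)
    inputs = {}
    crisp = {}
    for i in range(n_inputs):
        name = f"V{i}"
        width = rng.uniform(1.0, 100.0)
        lo, hi = 0.0, width
        labels = [f"L{k}" for k in range(rng.integers(2, 5))]
        inputs[name] = {
            "domain": (lo, hi),
            "sets": {label: _random_set(rng, lo, hi) for label in labels},
        }
        crisp[name] = float(rng.uniform(lo, hi))
    output = {
        "domain": (0.0, 100.0),
        "sets": {label: _random_set(rng, 0.0, 100.0) for label in _OUT_LABELS},
    }
    rules = []
    for _ in range(rng.integers(1, 11)):
        k = rng.integers(1, n_inputs + 1)
        chosen = rng.choice(n_inputs, size=k, replace=False)
        atoms = []
        for idx in sorted(chosen):
            name = f"V{idx}"
            label = str(rng.choice(list(inputs[name]["sets"])))
            atoms.append((name, label))
        rules.append((atoms, str(rng.choice(_OUT_LABELS))))
    system = {"inputs": inputs, "output": output, "out_order": list(_OUT_LABELS), "rules": rules}
    return system, crisp
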