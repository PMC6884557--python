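"""Deterministic bead configurations with closed-form observables.

Used for exercising the shape descriptors and the force field against
analytic results: dimers, collinear rods, and beads filling a ball.
"""

from __future__ import annotations

import numpy as np


def dimer(d: float, origin=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0)
          ) -> np.ndarray:
    """Two beads at separation d.  R_g = d/2, Kirkwood R_h = 2d."""
    o = np.asarray(origin, dtype=float)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    return np.stack([o, o + d * u])


def collinear_rod(n: int, spacing: float = 1.0, origin=(0.0, 0.0, 0.0),
                  axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """n equally spaced beads on a line."""
    o = np.asarray(origin, dtype=float)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    return o + spacing * np.arange(n)[:, None] * u


def ball_filled(n: int, radius: float = 1.0, origin=(0.0, 0.0, 0.0),
                seed: int = 0) -> np.ndarray:
    """n beads quasi-uniformly filling a solid ball of the given radius.

    Deterministic for a fixed seed; for large n the bead cloud approaches
    the uniform ball (R_g -> sqrt(3/5) radius).
    """
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        cand = cand[(cand ** 2).sum(axis=1) <= radius ** 2]
        pts = np.vstack([pts, cand])
    return np.asarray(origin, dtype=float) + pts[:n]


def random_cluster(n: int, scale: float = 1.0, min_sep: float = 0.5,
                   seed: int = 0) -> np.ndarray:
    """n random beads with a guaranteed minimum separation (for oracles)."""
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = rng.normal(scale=scale, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts)
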