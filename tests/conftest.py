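"""Shared fixtures: geometry generators and scaled simulation ensembles.

The session-scoped ensembles are computed once and shared by the
statistics and acceptance tests; their replicate counts and horizons
are scaled-down study conditions (documented in docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

from iknm import RunConfig, run
from iknm.engine import run_ensemble


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_convex_20gon(rng, scale=1.0, center=(0.0, 0.0)):
    """Random convex 20-gon: convex hull of jittered circle points,
    resampled to exactly 20 vertices."""
    from iknm import geometry as geo
    for _ in range(100):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 60))
        r = scale * rng.uniform(0.7, 1.3, 60)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        hull = _convex_hull(pts)
        if len(hull) < 8:
            continue
        p = geo.resample_to_20(hull)
        p = np.asarray(center) + p
        if geo.is_convex(p, tol=1e-9) and geo.polygon_area(p) > 0:
            return p
    raise RuntimeError("could not generate a convex 20-gon")


def _convex_hull(pts):
    from scipy.spatial import ConvexHull
    h = ConvexHull(pts)
    return pts[h.vertices]


@pytest.fixture(scope="session")
def short_run():
    """One deterministic short run (72→78 h) shared across tests."""
    cfg = RunConfig.from_dict({"seed": 7, "cycle": {"t_end": 78.0}})
    return run(cfg, seed=7)


@pytest.fixture(scope="session")
def early_ensemble():
    """Scaled early-window ensemble: 5 replicates over 72→84 h."""
    cfg = RunConfig.from_dict({"seed": 100, "cycle": {"t_end": 84.0}})
    return run_ensemble(cfg, n=5, base_seed=100)


@pytest.fixture(scope="session")
def full_ensemble():
    """Scaled full-horizon ensemble: 2 replicates over 72→116 h."""
    cfg = RunConfig.from_dict({"seed": 200})
    return run_ensemble(cfg, n=2, base_seed=200)
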