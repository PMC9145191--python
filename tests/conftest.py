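import numpy as np
import pytest

from thromboseg import PhantomConfig, generate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic 96x96 phantom study shared across tests."""
    return generate_study(PhantomConfig(image_size=96, n_slices_range=(49, 90), seed=7))


def random_box_pair(rng, lo=0.0, hi=30.0, min_side=0.5):
    """A pair of random valid boxes, coordinates away from tie points."""
    def one():
        x1 = rng.uniform(lo, hi)
        y1 = rng.uniform(lo, hi)
        return np.array(
            [x1, y1, x1 + rng.uniform(min_side, hi - lo), y1 + rng.uniform(min_side, hi - lo)]
        )

    return one(), one()


def raster_areas(b1, b2, frame=64):
    """Cell-counting oracle for intersection/union/enclosing areas.

    Boxes must have integer corners inside the frame; each unit grid cell
    (r, c) is covered by a box iff [c, c+1) x [r, r+1) lies inside it.
    """
    def grid(b):
        g = np.zeros((frame, frame), dtype=bool)
        g[int(b[1]) : int(b[3]), int(b[0]) : int(b[2])] = True
        return g

    g1, g2 = grid(b1), grid(b2)
    inter = int((g1 & g2).sum())
    union = int((g1 | g2).sum())
    ex = (min(b1[0], b2[0]), min(b1[1], b2[1]), max(b1[2], b2[2]), max(b1[3], b2[3]))
    enclosing = int(grid(ex).sum())
    return inter, union, enclosing


def brute_force_runs(flags, min_run):
    """O(n^2) run finder: every maximal all-true window of length >= min_run."""
    n = len(flags)
    runs = []
    for s in range(n):
        for e in range(s + min_run, n + 1):
            if (
                all(flags[s:e])
                and (s == 0 or not flags[s - 1])
                and (e == n or not flags[e])
            ):
                runs.append((s, e))
    return runs
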