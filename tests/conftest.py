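"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library routines the package
itself uses (scipy.ndimage labeling, scipy.spatial hulls, the Newton Cox
solver): flood fills are hand-rolled BFS, hulls go through shapely, and
the Cox maximizer is a 1-D grid refinement of a directly-coded partial
likelihood.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# geometry oracles


def flood_fill_oracle(mask: np.ndarray) -> dict:
    """Area / filled area / hole count / extent by hand-rolled BFS.

    Holes are 8-connected components of background cells in the padded
    bounding box that a BFS from the pad frame cannot reach.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    box = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    box[1:-1, 1:-1] = mask[r0:r1, c0:c1]
    h, w = box.shape
    nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)]

    def bfs(start_cells, passable, visited):
        q = deque(start_cells)
        for cell in start_cells:
            visited.add(cell)
        while q:
            r, c = q.popleft()
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and passable[rr, cc] \
                        and (rr, cc) not in visited:
                    visited.add((rr, cc))
                    q.append((rr, cc))

    outside: set = set()
    frame = [(r, c) for r in range(h) for c in (0, w - 1)] + \
            [(r, c) for r in (0, h - 1) for c in range(w)]
    bfs([f for f in frame if not box[f]], ~box, outside)
    enclosed = [(r, c) for r in range(h) for c in range(w)
                if not box[r, c] and (r, c) not in outside]
    seen: set = set()
    n_holes = 0
    for cell in enclosed:
        if cell in seen:
            continue
        n_holes += 1
        bfs([cell], ~box, seen)
    area = int(mask.sum())
    return {
        "area": area,
        "filled_area": area + len(enclosed),
        "n_holes": n_holes,
        "extent": area / ((r1 - r0) * (c1 - c0)),
    }


def convex_area_oracle(mask: np.ndarray) -> int:
    """Convex area via shapely: hull of cell corners, count covered centers."""
    from shapely.geometry import MultiPoint, Point

    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    corners = [(r + dr, c + dc) for r, c in zip(rows, cols)
               for dr in (0, 1) for dc in (0, 1)]
    hull = MultiPoint(corners).convex_hull
    count = 0
    for r in range(rows.min(), rows.max() + 1):
        for c in range(cols.min(), cols.max() + 1):
            if hull.covers(Point(r + 0.5, c + 0.5)):
                count += 1
    return count


def random_masks(n: int, seed: int = 0, max_radius: float = 9.0):
    """A stream of varied small shapes from the synthetic generator."""
    from tumorshape import ShapeSpec, gen_tumor_mask

    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n):
        spec = ShapeSpec(
            base_radius=rng.uniform(2.5, max_radius),
            aspect=rng.uniform(1.0, 2.0),
            roughness=rng.uniform(0.0, 0.7),
            n_holes=int(rng.integers(0, 3)),
            n_satellites=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            masks.append(gen_tumor_mask(spec))
        except ValueError:
            continue  # degenerate spec (too small for holes); skip
    return masks


# ---------------------------------------------------------------------------
# survival oracles


def partial_loglik_direct(beta: float, x, time, event, ties="efron") -> float:
    """Cox partial log-likelihood for one covariate, coded directly."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        death = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(death.sum())
        ll += float(beta * x[death].sum())
        risk_sum = float(np.exp(beta * x[at_risk]).sum())
        death_sum = float(np.exp(beta * x[death]).sum())
        for l in range(d):
            if ties == "efron":
                ll -= np.log(risk_sum - (l / d) * death_sum)
            else:
                ll -= np.log(risk_sum)
    return ll


def grid_search_beta(x, time, event, ties="efron",
                     lo=-5.0, hi=5.0) -> float:
    """1-D grid-search maximizer of the partial likelihood, refined to 1e-6."""
    for step in (0.01, 1e-4, 1e-6):
        grid = np.arange(lo, hi + step / 2, step)
        lls = [partial_loglik_direct(b, x, time, event, ties) for b in grid]
        best = grid[int(np.argmax(lls))]
        lo, hi = best - step, best + step
    return float(best)


def simulate_simple_survival(n, beta, seed, censor_scale=None, p=1):
    """Minimal PH data: standard-normal covariates, exponential times."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta_vec = np.full(p, beta) if np.isscalar(beta) else np.asarray(beta)
    t_event = rng.exponential(1.0 / (0.01 * np.exp(X @ beta_vec)))
    if censor_scale is None:
        return X, t_event, np.ones(n, dtype=int)
    t_cens = rng.exponential(censor_scale, n)
    return X, np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)


@pytest.fixture(scope="session")
def small_cox_fixtures():
    """A suite of <=10-patient single-covariate datasets without ties."""
    datasets = []
    rng = np.random.default_rng(42)
    for i in range(6):
        n = int(rng.integers(6, 11))
        x = rng.normal(size=n)
        time = rng.permutation(np.arange(1.0, n + 1.0))  # distinct times
        event = np.ones(n, dtype=int)
        event[rng.integers(0, n)] = 0
        datasets.append((x, time, event))
    # the classic balanced 8-patient binary-covariate set
    datasets.append(
        (np.array([0, 1, 0, 1, 0, 1, 0, 1.0]),
         np.array([2.0, 5, 7, 3, 11, 13, 17, 19]),
         np.ones(8, dtype=int))
    )
    return datasets
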