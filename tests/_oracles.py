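"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the segmentation
oracle enumerates change-point placements exhaustively, and the planar
junction oracle scans inter-arm angles on a degree grid.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exhaustive_segmentation(
    y: np.ndarray, penalty: float, max_steps: int = 2
) -> tuple[float, tuple[int, ...]]:
    """Best penalized least-squares segmentation by full enumeration.

    Returns (total cost, change points) minimizing RSS + penalty per
    change point over all placements of at most ``max_steps`` change
    points. O(n^max_steps); keep instances small.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def rss(a: int, b: int) -> float:
        m = b - a
        return cum2[b] - cum2[a] - (cum[b] - cum[a]) ** 2 / m

    best_cost = rss(0, n)
    best_cps: tuple[int, ...] = ()
    for k in range(1, max_steps + 1):
        for cps in combinations(range(1, n), k):
            edges = (0,) + cps + (n,)
            cost = sum(rss(a, b) for a, b in zip(edges[:-1], edges[1:]))
            cost += penalty * k
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_cps = cps
    return best_cost, best_cps


def planar_junction_distances(
    lengths: dict[str, float],
    stacked: tuple[str, str],
    third_angle_deg: float,
) -> dict[frozenset, float]:
    """Tip-to-tip distances of a planar junction with one stacked pair.

    The stacked arms point in opposite directions from the junction; the
    third arm sits at ``third_angle_deg`` from the first stacked arm.
    """
    x, y = stacked
    z = next(n for n in lengths if n not in stacked)
    lx, ly, lz = lengths[x], lengths[y], lengths[z]
    ux = np.array([1.0, 0.0])
    uy = -ux
    th = np.deg2rad(third_angle_deg)
    uz = np.array([np.cos(th), np.sin(th)])
    tips = {x: lx * ux, y: ly * uy, z: lz * uz}
    return {
        frozenset({a, b}): float(np.linalg.norm(tips[a] - tips[b]))
        for a, b in combinations(lengths, 2)
    }


def rank_by_grid_search(
    lengths: dict[str, float],
    measurements: list[tuple[tuple[str, str], float]],
    angle_step_deg: float = 1.0,
    min_bend_deg: float = 20.0,
) -> list[tuple[float, tuple[str, str]]]:
    """Rank stacked-pair hypotheses by brute-force angle grid search."""
    names = sorted(lengths)
    out = []
    for pair in combinations(names, 2):
        best = np.inf
        for ang in np.arange(
            min_bend_deg, 180.0 - min_bend_deg + angle_step_deg, angle_step_deg
        ):
            d = planar_junction_distances(lengths, pair, ang)
            res = sum(abs(d[frozenset(m)] - v) for m, v in measurements)
            best = min(best, res)
        out.append((best, pair))
    return sorted(out)
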