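"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the package's own code paths: distances by
dense sampling, membership by ray casting, rank-test p-values by direct
enumeration, disk areas by pixel-center counting.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160610)


def dense_sample_distance(pt, vertices, closed, n_samples=100_000):
    """Min distance from pt to a polyline by sampling points along it."""
    v = np.asarray(vertices, float)
    if closed:
        v = np.vstack([v, v[:1]])
    seg = np.diff(v, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    best = np.inf
    for i in range(len(seg)):
        k = max(int(np.ceil(n_samples * seg_len[i] / total)), 2)
        t = np.linspace(0.0, 1.0, k)[:, None]
        pts = v[i] + t * seg[i]
        d = np.linalg.norm(pts - np.asarray(pt, float), axis=1).min()
        best = min(best, d)
    return float(best)


def raycast_inside(pt, vertices):
    """Even-odd membership by counting crossings of a ray cast from a
    shifted origin (horizontal ray toward +x)."""
    x, y = float(pt[0]), float(pt[1])
    v = np.asarray(vertices, float)
    n = len(v)
    inside = False
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x_cross > x:
                inside = not inside
    return inside


def brute_force_mw(x, y):
    """Exact two-sided Mann-Whitney p by direct enumeration, written
    independently: midranks recomputed with scipy, U recomputed per
    labeling from pair counts rather than rank sums."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks

    def u_of(indices):
        idx = np.zeros(n1 + n2, bool)
        idx[list(indices)] = True
        return ranks[idx].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for combo in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(combo) - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / total


def disk_pixel_count(center_x, center_y, radius, pixel_size, n_px, origin=0.0):
    """Rasterization oracle: number of pixels whose centers fall inside the
    disk, on a grid of n_px x n_px pixels starting at ``origin`` nm."""
    c = origin + (np.arange(n_px) + 0.5) * pixel_size
    X, Y = np.meshgrid(c, c)
    return int(np.sum((X - center_x) ** 2 + (Y - center_y) ** 2 <= radius ** 2))


def ellipse_perimeter_quad(a, b):
    """Ellipse perimeter by generic numerical quadrature of the arc-length
    integral (independent of the elliptic-integral route)."""
    from scipy.integrate import quad

    val, _ = quad(
        lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0.0, 2.0 * np.pi,
        limit=200,
    )
    return val
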