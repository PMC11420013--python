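"""Independent brute-force oracles and fixture generators shared by tests.

Everything here deliberately avoids the production code paths it is used
to check: moments are accumulated with explicit Python double loops, the
axial median by exhaustive candidate search, and the Mann-Whitney p-value
by enumerating rank arrangements.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_moments(pixels: np.ndarray, label: int) -> dict:
    """Double-loop pixel-moment oracle (area, centroid, y-up central
    second moments, eigenvalues, axes, orientation)."""
    rows, cols = [], []
    nr, nc = pixels.shape
    for r in range(nr):
        for c in range(nc):
            if pixels[r, c] == label:
                rows.append(r)
                cols.append(c)
    n = len(rows)
    r0 = sum(rows) / n
    c0 = sum(cols) / n
    mu20 = mu02 = mu11 = 0.0
    for r, c in zip(rows, cols):
        dx = c - c0
        dy = -(r - r0)
        mu20 += dx * dx
        mu02 += dy * dy
        mu11 += dx * dy
    mu20 /= n
    mu02 /= n
    mu11 /= n
    mean = 0.5 * (mu20 + mu02)
    root = math.hypot(0.5 * (mu20 - mu02), mu11)
    lam1, lam2 = mean + root, max(mean - root, 0.0)
    theta = 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    return {
        "area": n,
        "centroid": (r0, c0),
        "mu20": mu20,
        "mu11": mu11,
        "mu02": mu02,
        "lam1": lam1,
        "lam2": lam2,
        "major_len": 4.0 * math.sqrt(lam1),
        "minor_len": 4.0 * math.sqrt(lam2),
        "orientation_deg": theta,
    }


def random_blob(
    rng: np.random.Generator,
    shape: tuple[int, int] = (64, 64),
    min_area: int = 20,
) -> np.ndarray:
    """Rasterized random ellipse as a binary label image (label 1)."""
    nr, nc = shape
    while True:
        r0 = rng.uniform(0.3 * nr, 0.7 * nr)
        c0 = rng.uniform(0.3 * nc, 0.7 * nc)
        a = rng.uniform(3.0, 0.25 * min(nr, nc))
        b = rng.uniform(2.0, a)
        phi = rng.uniform(-np.pi / 2, np.pi / 2)
        rr, cc = np.mgrid[0:nr, 0:nc]
        x = cc - c0
        y = -(rr - r0)
        u = np.cos(phi) * x + np.sin(phi) * y
        v = -np.sin(phi) * x + np.cos(phi) * y
        blob = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.int32)
        if blob.sum() >= min_area:
            return blob


def axial_median_exhaustive(orientations) -> float:
    """Axial median by exhaustive candidate search over data values."""

    def wrap(x):
        d = (x + 90.0) % 180.0 - 90.0
        return d + 180.0 if d <= -90.0 else d

    vals = sorted({wrap(t) for t in orientations})
    best, best_cost = None, math.inf
    for m in vals:
        cost = sum(abs(wrap(t - m)) for t in orientations)
        if cost < best_cost - 1e-9:
            best, best_cost = m, cost
    return best


def mann_whitney_exact_p(x, y) -> float:
    """Two-tailed exact Mann-Whitney p by enumerating which pooled
    positions belong to x (no ties allowed)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    nx = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    n = len(pooled)
    mean_u = nx * (n - nx) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), nx):
        u = sum(combo) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def dunn_z_oracle(groups) -> list[tuple[int, int, float]]:
    """Independent Dunn z computation with manual mid-ranks and explicit
    tie correction; returns (i, j, z) per pair."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda k: pooled[k])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    tie_sum = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        t = j - i + 1
        tie_sum += t**3 - t
        i = j + 1
    var = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    bounds = [0]
    for g in groups:
        bounds.append(bounds[-1] + len(g))
    means = [
        sum(ranks[bounds[i] : bounds[i + 1]]) / len(groups[i])
        for i in range(len(groups))
    ]
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
            out.append((i, j, (means[i] - means[j]) / se))
    return out
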