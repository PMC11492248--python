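"""Independent reference implementations used only by the test suite.

These are deliberately naive (O(N^2), longhand, finite-difference)
and share no code with the package's optimized paths.
"""

from __future__ import annotations

import numpy as np


def brute_contacts(points_a: np.ndarray, points_b: np.ndarray,
                   cutoff: float, box=None, periodic_xy: bool = False,
                   ) -> np.ndarray:
    """All-pairs double loop contact matrix with strict '<' at cutoff."""
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    out = np.zeros((len(a), len(b)), dtype=bool)
    for i in range(len(a)):
        for j in range(len(b)):
            d = a[i] - b[j]
            if periodic_xy:
                for dim in (0, 1):
                    L = box[dim]
                    d[dim] -= L * round(d[dim] / L)
            out[i, j] = float(np.sqrt(np.dot(d, d))) < cutoff
    return out


def textbook_dbscan(points: np.ndarray, eps: float, min_pts: int,
                    ) -> np.ndarray:
    """Reference DBSCAN from a precomputed distance matrix.

    Points are visited in ascending index order with FIFO expansion,
    the common deterministic convention (border points join the first
    cluster that reaches them).
    """
    pts = np.asarray(points, float)
    n = len(pts)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    neighbors = [list(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    labels = np.full(n, -1, dtype=int)
    processed = np.zeros(n, dtype=bool)
    cid = 0
    for i in range(n):
        if processed[i]:
            continue
        processed[i] = True
        if len(neighbors[i]) < min_pts:
            continue
        labels[i] = cid
        queue = list(neighbors[i])
        qi = 0
        while qi < len(queue):
            q = queue[qi]
            qi += 1
            if labels[q] == -1:
                labels[q] = cid
            if not processed[q]:
                processed[q] = True
                if len(neighbors[q]) >= min_pts:
                    queue.extend(neighbors[q])
        cid += 1
    return labels


def clusters_as_sets(labels: np.ndarray) -> set[frozenset[int]]:
    """Partition view of a labeling (relabeling-invariant comparison)."""
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            out.setdefault(int(lab), set()).add(i)
    return {frozenset(v) for v in out.values()}


def pearson_longhand(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass population Pearson coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    sx = np.sqrt(sum((a - mx) ** 2 for a in x) / len(x))
    sy = np.sqrt(sum((b - my) ** 2 for b in y) / len(y))
    return cov / (sx * sy)


def fd_curvatures(height_fn, x: np.ndarray, y: np.ndarray, h: float = 1e-3,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Central finite-difference normal curvatures along x and y of a
    height function z(x, y)."""
    zx = (height_fn(x + h, y) - height_fn(x - h, y)) / (2 * h)
    zy = (height_fn(x, y + h) - height_fn(x, y - h)) / (2 * h)
    zxx = (height_fn(x + h, y) - 2 * height_fn(x, y)
           + height_fn(x - h, y)) / h**2
    zyy = (height_fn(x, y + h) - 2 * height_fn(x, y)
           + height_fn(x, y - h)) / h**2
    kx = zxx / (1 + zx**2) ** 1.5
    ky = zyy / (1 + zy**2) ** 1.5
    return kx, ky


def analytic_dimple_abs_gaussian(params, x: np.ndarray, y: np.ndarray,
                                 ) -> np.ndarray:
    """Closed-form |K| of the plane + Gaussian-dimple surface, written
    independently of the package's derivative code."""
    c0, c1, c2, A, x0, y0, sx, sy = params
    u = x - x0
    v = y - y0
    g = np.exp(-(u**2 / (2 * sx**2) + v**2 / (2 * sy**2)))
    zx = c1 - A * g * u / sx**2
    zy = c2 - A * g * v / sy**2
    zxx = A * g * (u**2 / sx**4 - 1 / sx**2)
    zyy = A * g * (v**2 / sy**4 - 1 / sy**2)
    kx = zxx / (1 + zx**2) ** 1.5
    ky = zyy / (1 + zy**2) ** 1.5
    return np.abs(kx * ky)


def rodrigues_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues' formula)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rolling_mean_longhand(values, window: int) -> np.ndarray:
    vals = list(values)
    out = []
    for i in range(len(vals)):
        lo = max(0, i - window + 1)
        chunk = vals[lo:i + 1]
        out.append(sum(chunk) / len(chunk))
    return np.array(out)
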