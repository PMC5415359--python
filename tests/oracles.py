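"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the 27-image scan
replaces the analytic minimum-image formula, the quaternion search
replaces the SVD-based superposition, and the run-length encoder
replaces the dewetting interval scan.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def distance_27_images(a, b, box):
    """Minimum distance over all 27 periodic image shifts."""
    best = np.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        shift = np.array([sx, sy, sz]) * box
        best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def _quat_to_matrix(q):
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def brute_force_rmsd(mobile, reference, n_grid=3000, seed=0):
    """Minimum RMSD over rotations by quaternion-grid search + local
    simplex refinement.  Centres both point sets, scans a uniform random
    quaternion grid, then polishes the best candidates numerically."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    n = x.shape[0]

    def rmsd_of(q):
        r = _quat_to_matrix(q)
        return float(np.sqrt(((x @ r.T - y) ** 2).sum() / n))

    rng = np.random.default_rng(seed)
    grid = rng.normal(size=(n_grid, 4))
    values = [rmsd_of(q) for q in grid]
    best = np.inf
    for i in np.argsort(values)[:5]:
        res = minimize(rmsd_of, grid[i], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


def run_length_dry_intervals(dry, min_duration):
    """Run-length encoding of a boolean series -> maximal dry runs."""
    intervals = []
    i = 0
    n = len(dry)
    while i < n:
        if dry[i]:
            j = i
            while j + 1 < n and dry[j + 1]:
                j += 1
            if j - i + 1 >= min_duration:
                intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals


def lens_area(r1, r2, d):
    """Analytic area of the union of two disks at centre distance d."""
    if d >= r1 + r2:
        return np.pi * (r1 * r1 + r2 * r2)
    if d <= abs(r1 - r2):
        return np.pi * max(r1, r2) ** 2
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    intersection = a1 + a2 - tri
    return np.pi * (r1 * r1 + r2 * r2) - intersection
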