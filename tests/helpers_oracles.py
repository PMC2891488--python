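"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive quantities by brute force (grids,
enumeration, Monte Carlo, direct sums) and stay independent of the
library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def finite_difference_force(potential, x, eps=1e-6):
    """Central-difference gradient (force = -grad) of a scalar
    potential at a 3-vector."""
    f = np.zeros(3)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = eps
        f[k] = -(potential(x + dp) - potential(x - dp)) / (2 * eps)
    return f


def rotation_grid(n_per_axis: int = 14):
    """A dense grid of proper rotations (Euler angles)."""
    a = np.linspace(0, 2 * np.pi, n_per_axis, endpoint=False)
    b = np.linspace(0, np.pi, n_per_axis // 2 + 1)
    rots = []
    for za, yb, zc in itertools.product(a, b, a):
        rots.append(Rotation.from_euler("zyz", [za, yb, zc]).as_matrix())
    return rots


def tm_objective(model, native, R, t, d0):
    d = np.linalg.norm(model @ R.T + t - native, axis=1)
    return np.mean(1.0 / (1.0 + (d / d0) ** 2))


def tm_grid_oracle(model, native, d0, n_per_axis: int = 12):
    """Maximise the TM objective by a dense rotation grid with
    translation refinement, then polish the best candidates over all
    six rigid-motion parameters."""
    model = np.asarray(model, float)
    native = np.asarray(native, float)
    candidates = []   # (score, rotation, translation)
    cm, cn = model.mean(axis=0), native.mean(axis=0)
    for R in rotation_grid(n_per_axis):
        t0 = cn - R @ cm
        res = minimize(lambda t: -tm_objective(model, native, R, t, d0),
                       t0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
        candidates.append((-res.fun, R, res.x))
    candidates.sort(key=lambda c: -c[0])

    def neg(p):
        Rp = Rotation.from_rotvec(p[:3]).as_matrix()
        return -tm_objective(model, native, Rp, p[3:], d0)

    # the objective is spiky for small d0: polish many diverse starts
    best = candidates[0][0]
    for score, R, t in candidates[:40]:
        rv0 = Rotation.from_matrix(R).as_rotvec()
        res = minimize(neg, np.concatenate([rv0, t]), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-11,
                                "maxiter": 3000})
        best = max(best, -res.fun)
    # plus residue-pair alignment starts: superpose every contiguous
    # triple and polish
    from crowdfold.analysis import _kabsch  # Kabsch is standard linear algebra
    L = len(model)
    for s in range(L - 2):
        sel = np.arange(s, s + 3)
        try:
            R, t = _kabsch(model[sel], native[sel])
        except np.linalg.LinAlgError:
            continue
        rv0 = Rotation.from_matrix(R).as_rotvec()
        res = minimize(neg, np.concatenate([rv0, t]), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-11,
                                "maxiter": 3000})
        best = max(best, -res.fun)
    return best


def superpose_grid_oracle(A, B, n_per_axis: int = 12):
    """Minimum RMSD by rotation grid + Nelder-Mead polish."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    best = np.inf
    for R in rotation_grid(n_per_axis):
        d = (A - ca) @ R.T + cb - B
        best = min(best, np.sqrt((d * d).sum() / len(A)))

    def f(p):
        Rp = Rotation.from_rotvec(p[:3]).as_matrix()
        d = A @ Rp.T + p[3:] - B
        return np.sqrt((d * d).sum() / len(A))

    res = minimize(f, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-10})
    return min(best, res.fun)


def maxsub_subset_oracle(model, native, d_cut, min_size: int = 3):
    """Exhaustive-subset alignable count: superpose on every subset of
    size >= min_size (small L only) and count residues within d_cut."""
    from crowdfold.analysis import _kabsch

    model = np.asarray(model, float)
    native = np.asarray(native, float)
    L = len(model)
    best = 0
    idx = list(range(L))
    for size in range(min_size, L + 1):
        for sub in itertools.combinations(idx, size):
            sel = np.asarray(sub)
            try:
                R, t = _kabsch(model[sel], native[sel])
            except np.linalg.LinAlgError:
                continue
            d = np.linalg.norm(model @ R.T + t - native, axis=1)
            best = max(best, int((d < d_cut).sum()))
    return best


def fixation_bruteforce(frames, theta):
    """Literal O(n^2) evaluation of the fixation definition."""
    from scipy.spatial.distance import pdist

    D = [pdist(f) for f in frames]
    n = len(frames)
    for t in range(n):
        ok = True
        for u in range(t + 1, n):
            if np.abs(D[t] - D[u]).mean() >= theta:
                ok = False
                break
        if ok:
            return t
    return n - 1


def montecarlo_available_volume(scene, n_points: int, seed: int = 0):
    """Monte-Carlo estimate of the ribosome-free container volume."""
    rng = np.random.default_rng(seed)
    R = scene.container_radius
    pts = rng.uniform(-R, R, (n_points, 3)) + scene.container_center
    inside = np.linalg.norm(pts - scene.container_center, axis=1) <= R
    outside_rib = np.linalg.norm(pts - scene.ribosome_center, axis=1) \
        >= scene.ribosome_radius
    frac = np.mean(inside & outside_rib)
    return frac * (2 * R) ** 3


def spherical_cap_fraction(occluder_radius, distance):
    """Solid-angle fraction of the sphere blocked by one occluder as
    seen from a point at ``distance``."""
    sin_a = occluder_radius / distance
    cos_a = np.sqrt(1.0 - sin_a**2)
    return (1.0 - cos_a) / 2.0
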