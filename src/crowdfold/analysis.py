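"""Structural observables for trajectories and conformation pools.

A conformation is an (L, 3) array of backbone coordinates in residue
order.  The module provides rigid superposition (Kabsch), TM-score with
the standard length-dependent distance scale d0, the largest alignable
fraction at a distance cutoff (MaxSub-style), radius of gyration
relative to the native, the fixation index of a trajectory (earliest
sample that stays within a mean internal-distance difference of all
later samples), native-like time (percentage of samples above a
TM-score threshold), smoothed secondary-structure-aware contact maps
and simple summary percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["superpose", "tm_d0", "tm_score", "maxsub_fraction",
           "radius_of_gyration", "relative_rg", "fixation_time",
           "native_like_time", "ContactMap", "contact_map", "smooth_trace",
           "summarize", "select_foldable"]


def _as_conf(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"conformation must be (L, 3), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("conformation contains non-finite coordinates")
    return a


def _kabsch(P: np.ndarray, Q: np.ndarray,
            weights: Optional[np.ndarray] = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising
    sum w_i |R p_i + t - q_i|^2."""
    if weights is None:
        weights = np.ones(len(P))
    w = weights / weights.sum()
    cp = (w[:, None] * P).sum(axis=0)
    cq = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - cp)).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def superpose(A, B) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of A onto B.

    Returns ``(rotation, translation, rmsd)`` with
    ``rotation @ A[i] + translation ~ B[i]``; the rotation is proper
    (no reflection).  Fewer than three points or collinear points are
    rejected.
    """
    A = _as_conf(A)
    B = _as_conf(B)
    if A.shape != B.shape:
        raise ValueError("conformations must have equal length")
    if len(A) < 3:
        raise ValueError("superposition needs at least 3 points")
    if (np.linalg.matrix_rank(A - A.mean(axis=0), tol=1e-8) < 2
            or np.linalg.matrix_rank(B - B.mean(axis=0), tol=1e-8) < 2):
        raise ValueError("superposition undefined for collinear points")
    R, t = _kabsch(A, B)
    d = A @ R.T + t - B
    rmsd = float(np.sqrt((d * d).sum() / len(A)))
    return R, t, rmsd


def tm_d0(L: int) -> float:
    """The raw TM-score distance scale: 1.24 (L - 15)^(1/3) - 1.8.

    Only meaningful for L > 15; scoring clamps the value at 0.5 from
    below (and uses 0.5 outright for L <= 15).
    """
    if L <= 15:
        return 1.24 * math.copysign(abs(L - 15.0) ** (1.0 / 3.0), L - 15.0) - 1.8
    return 1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8


def _tm_terms(model: np.ndarray, native: np.ndarray, R, t, d0: float
              ) -> np.ndarray:
    d = np.linalg.norm(model @ R.T + t - native, axis=1)
    return 1.0 / (1.0 + (d / d0) ** 2)


def _fragment_starts(L: int, flen: int) -> range:
    stride = max(1, flen // 2)
    return range(0, L - flen + 1, stride)


def tm_score(model, native, return_transform: bool = False):
    """Template-modelling score of ``model`` against ``native``.

    Residue correspondence is fixed by sequence order.  The score is
    the maximum over fragment-seeded superpositions of
    ``mean(1 / (1 + (d_i/d0)^2))`` with ``d0 = 1.24 (L-15)^(1/3) - 1.8``
    clamped at 0.5; superpositions are seeded from contiguous fragments
    of lengths L, L/2 and 4, extended by iterating inclusion of
    residues within d0 and polished by distance-weighted
    re-superposition.
    """
    model = _as_conf(model)
    native = _as_conf(native)
    if model.shape != native.shape:
        raise ValueError("model and native must have equal length")
    L = len(native)
    if L < 5:
        raise ValueError("TM score undefined for fewer than 5 residues")
    d0 = max(tm_d0(L), 0.5)

    best = -1.0
    best_Rt = None
    lengths = sorted({L, max(L // 2, 4), 4}, reverse=True)
    for flen in lengths:
        if flen > L:
            continue
        for s in _fragment_starts(L, flen):
            sel = np.arange(s, s + flen)
            try:
                R, t = _kabsch(model[sel], native[sel])
            except np.linalg.LinAlgError:
                continue
            # iterate inclusion of residues within d0
            for _ in range(20):
                d = np.linalg.norm(model @ R.T + t - native, axis=1)
                new = np.flatnonzero(d < d0)
                if len(new) < 3 or np.array_equal(new, sel):
                    break
                sel = new
                R, t = _kabsch(model[sel], native[sel])
            # distance-weighted polish toward the TM objective optimum
            for _ in range(30):
                d = np.linalg.norm(model @ R.T + t - native, axis=1)
                w = 1.0 / (1.0 + (d / d0) ** 2) ** 2
                R2, t2 = _kabsch(model, native, weights=w)
                if np.allclose(R2, R, atol=1e-10) and np.allclose(t2, t, atol=1e-10):
                    break
                R, t = R2, t2
            score = float(_tm_terms(model, native, R, t, d0).mean())
            if score > best:
                best = score
                best_Rt = (R, t)
    if return_transform:
        return best, best_Rt
    return best


def maxsub_fraction(model, native, d_cut: float = 5.0) -> float:
    """Largest fraction of residues superposable to within ``d_cut``.

    Greedy seed-and-extend: every contiguous 4-residue seed (plus the
    full chain) is superposed, residues within ``d_cut`` are added and
    the superposition recomputed until the subset is stable; the
    largest self-consistent subset size over all seeds, divided by L,
    is returned.
    """
    model = _as_conf(model)
    native = _as_conf(native)
    if model.shape != native.shape:
        raise ValueError("model and native must have equal length")
    L = len(native)
    best = 0
    seeds = [np.arange(L)]
    if L >= 4:
        seeds += [np.arange(s, s + 4) for s in range(L - 3)]
    for sel in seeds:
        if len(sel) < 3:
            continue
        R, t = _kabsch(model[sel], native[sel])
        for _ in range(30):
            d = np.linalg.norm(model @ R.T + t - native, axis=1)
            new = np.flatnonzero(d < d_cut)
            if len(new) < 3:
                break
            if np.array_equal(new, sel):
                best = max(best, len(new))
                break
            sel = new
            R, t = _kabsch(model[sel], native[sel])
    return best / L


def radius_of_gyration(conf) -> float:
    """Root-mean-square distance of the beads from their centroid."""
    conf = _as_conf(conf)
    c = conf - conf.mean(axis=0)
    return float(np.sqrt((c * c).sum(axis=1).mean()))


def relative_rg(conf, native) -> float:
    """Rg of ``conf`` relative to the Rg of the native state."""
    rg_native = radius_of_gyration(native)
    if rg_native <= 0:
        raise ValueError("native structure has zero radius of gyration")
    return radius_of_gyration(conf) / rg_native


def fixation_time(samples, theta: float = 4.0) -> int:
    """Index of the earliest sample similar to every later sample.

    Two conformations are similar when the mean absolute difference of
    their internal pairwise distances (all residue pairs i < j) is
    below ``theta``; the comparison is superposition-free.  If no
    earlier sample qualifies the last index is returned (it qualifies
    vacuously).
    """
    frames = np.asarray(samples, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need at least one (L, 3) sample")
    n = frames.shape[0]
    if frames.shape[1] < 2:
        return 0
    D = np.stack([pdist(f) for f in frames])
    for t in range(n):
        if t == n - 1:
            return t
        diffs = np.abs(D[t + 1:] - D[t]).mean(axis=1)
        if np.all(diffs < theta):
            return t
    return n - 1


def native_like_time(samples, native, tau: float = 0.3) -> float:
    """Percentage of samples whose TM score to the native exceeds tau."""
    frames = np.asarray(samples, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need at least one (L, 3) sample")
    hits = sum(1 for f in frames if tm_score(f, native) > tau)
    return 100.0 * hits / frames.shape[0]


@dataclass
class ContactMap:
    """L x L contact values plus the eligibility mask.

    Values are binary for a single structure and in [0, 1] for a
    consensus mean; pairs within the same maximal run of identical
    non-coil secondary structure (and the diagonal) are ineligible.
    """

    values: np.ndarray     # (L, L)
    eligible: np.ndarray   # (L, L) bool

    @property
    def L(self) -> int:
        return self.values.shape[0]


def ss_units(ss: str) -> np.ndarray:
    """Unit label per residue: maximal contiguous runs of identical
    non-coil secondary structure get positive ids, coil gets 0."""
    labels = np.zeros(len(ss), dtype=int)
    unit = 0
    prev = None
    for i, s in enumerate(ss):
        if s == "C":
            prev = None
            continue
        if s != prev:
            unit += 1
            prev = s
        labels[i] = unit
    return labels


def eligibility_mask(ss: str) -> np.ndarray:
    labels = ss_units(ss)
    L = len(ss)
    same_unit = (labels[:, None] == labels[None, :]) & (labels[:, None] > 0)
    mask = ~same_unit
    np.fill_diagonal(mask, False)
    return mask


def smooth_trace(conf: np.ndarray, window: int = 9) -> np.ndarray:
    """Centred moving average of the backbone trace; the window is
    truncated symmetrically at the termini."""
    conf = _as_conf(conf)
    L = len(conf)
    half = window // 2
    out = np.empty_like(conf)
    for i in range(L):
        k = min(half, i, L - 1 - i)
        out[i] = conf[i - k:i + k + 1].mean(axis=0)
    return out


def contact_map(conf, ss: str, window: int = 9, cut_EE: float = 8.0,
                cut_other: float = 11.0) -> ContactMap:
    """Smoothed-trace contact map with secondary-structure-aware
    cutoffs: 8 A when both residues are strand, 11 A otherwise; pairs
    inside the same helix/strand unit are ineligible."""
    conf = _as_conf(conf)
    if len(ss) != len(conf):
        raise ValueError("secondary structure length must match conformation")
    sm = smooth_trace(conf, window)
    d = np.linalg.norm(sm[:, None, :] - sm[None, :, :], axis=2)
    is_E = np.array([s == "E" for s in ss])
    cut = np.where(is_E[:, None] & is_E[None, :], cut_EE, cut_other)
    eligible = eligibility_mask(ss)
    values = ((d < cut) & eligible).astype(float)
    return ContactMap(values=values, eligible=eligible)


def summarize(values) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty collection")
    med, p25, p75 = np.percentile(arr, [50, 25, 75])
    return float(med), float(p25), float(p75)


def select_foldable(native_like_times: dict, threshold: float = 10.0) -> list:
    """Proteins whose pooled native-like time is at least ``threshold``
    percent (inclusive boundary)."""
    return [name for name, pct in native_like_times.items()
            if pct >= threshold]
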