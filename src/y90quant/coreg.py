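"""Mutual-information comparison of co-registered SPECT pairs.

Planning (⁹⁹ᵐTc-MAA) and post-therapy (⁹⁰Y) SPECT studies are registered by
external tools; this module scores candidate registrations with the mutual
information I(A,B) = H(A) + H(B) − H(A,B) computed from a joint intensity
histogram, and selects the candidate with the highest MI.  A small
exhaustive translation-only aligner is included for closed-loop synthetic
tests.

Entropies are in bits (log₂).  The joint histogram uses linear binning over
each image's own (min, max); by default only voxels where either image is
positive are sampled ("body" support), since large empty regions would
otherwise dominate the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgcore import VoxelGrid

__all__ = [
    "JointHistogram",
    "MIResult",
    "joint_histogram",
    "entropy_bits",
    "mutual_information",
    "select_registration",
    "translate_register",
]


@dataclass
class JointHistogram:
    bins: int
    counts: np.ndarray  # (bins, bins)
    ranges: tuple[tuple[float, float], tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class MIResult:
    mi_bits: float
    h_a: float
    h_b: float
    h_ab: float
    candidate_label: str = ""


def _support_mask(a: np.ndarray, b: np.ndarray, support: str) -> np.ndarray:
    if support == "all":
        return np.ones(a.shape, dtype=bool)
    if support == "body":
        return (a > 0) | (b > 0)
    raise ValueError(f"support must be 'body' or 'all', got {support!r}")


def _edges(vals: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:  # constant image: single-bin fallback
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(
    a: VoxelGrid, b: VoxelGrid, bins: int = 64, support: str = "body"
) -> JointHistogram:
    """Joint intensity histogram of two aligned grids."""
    if a.shape != b.shape:
        raise ValueError("grids must share a shape")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    m = _support_mask(a.data, b.data, support)
    if not m.any():
        raise ValueError("empty support: both images are zero everywhere")
    av, bv = a.data[m], b.data[m]
    ea, eb = _edges(av, bins), _edges(bv, bins)
    counts, _, _ = np.histogram2d(av, bv, bins=[ea, eb])
    return JointHistogram(
        bins=bins,
        counts=counts,
        ranges=((float(av.min()), float(av.max())), (float(bv.min()), float(bv.max()))),
    )


def entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy −Σ p log₂ p over the nonzero cells of a count table."""
    c = np.asarray(counts, dtype=np.float64).ravel()
    total = c.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    a: VoxelGrid, b: VoxelGrid, bins: int = 64, support: str = "body", label: str = ""
) -> MIResult:
    """Mutual information of two aligned grids under a shared binning."""
    jh = joint_histogram(a, b, bins=bins, support=support)
    h_ab = entropy_bits(jh.counts)
    h_a = entropy_bits(jh.counts.sum(axis=1))
    h_b = entropy_bits(jh.counts.sum(axis=0))
    return MIResult(mi_bits=h_a + h_b - h_ab, h_a=h_a, h_b=h_b, h_ab=h_ab, candidate_label=label)


def select_registration(
    fixed: VoxelGrid,
    candidates: "dict[str, VoxelGrid] | list[tuple[str, VoxelGrid]]",
    bins: int = 64,
    support: str = "body",
) -> tuple[str, dict[str, MIResult]]:
    """Score candidate registrations against ``fixed``; return the MI argmax.

    Candidates are already resampled to the fixed grid.  Ties break toward
    the earlier candidate.
    """
    items = list(candidates.items()) if isinstance(candidates, dict) else list(candidates)
    if len(items) < 2:
        raise ValueError("need at least 2 candidate registrations")
    results: dict[str, MIResult] = {}
    best_label, best_mi = None, -np.inf
    for label, grid in items:
        res = mutual_information(fixed, grid, bins=bins, support=support, label=label)
        results[label] = res
        if res.mi_bits > best_mi:
            best_label, best_mi = label, res.mi_bits
    assert best_label is not None
    return best_label, results


def _overlap_slices(shift: tuple[int, int, int], shape) -> tuple[tuple, tuple]:
    """Index slices of fixed and moving arrays overlapping under an integer shift.

    The moving image is conceptually translated by ``shift`` voxels; we
    compare fixed[x] with moving[x - shift] on the common region.
    """
    fix_sl, mov_sl = [], []
    for s, n in zip(shift, shape):
        if abs(s) >= n:
            raise ValueError("shift exceeds grid extent")
        if s >= 0:
            fix_sl.append(slice(s, n))
            mov_sl.append(slice(0, n - s))
        else:
            fix_sl.append(slice(0, n + s))
            mov_sl.append(slice(-s, n))
    return tuple(fix_sl), tuple(mov_sl)


def translate_register(
    moving: VoxelGrid,
    fixed: VoxelGrid,
    search_radius: int = 4,
    bins: int = 64,
    support: str = "body",
) -> tuple[int, int, int]:
    """Exhaustive integer-translation search maximising MI.

    Returns the voxel shift to apply to ``moving`` that best aligns it with
    ``fixed``.  Intended for synthetic closed-loop tests, not as a clinical
    registration engine.
    """
    if not moving.same_geometry(fixed):
        raise ValueError("grids must share geometry")
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    if search_radius >= min(fixed.shape):
        raise ValueError("search radius exceeds grid extent")
    rng = range(-search_radius, search_radius + 1)
    best_shift, best_mi = (0, 0, 0), -np.inf
    for dx in rng:
        for dy in rng:
            for dz in rng:
                fs, ms = _overlap_slices((dx, dy, dz), fixed.shape)
                sub_f = VoxelGrid(fixed.data[fs], fixed.spacing, units=fixed.units)
                sub_m = VoxelGrid(moving.data[ms], moving.spacing, units=moving.units)
                try:
                    mi = mutual_information(sub_f, sub_m, bins=bins, support=support).mi_bits
                except ValueError:
                    continue
                if mi > best_mi:
                    best_mi, best_shift = mi, (dx, dy, dz)
    return best_shift
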