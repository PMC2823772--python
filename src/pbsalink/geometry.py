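"""Superposition and trajectory geometry: RMSD schemes, RMSF, distances.

Conformational stability of a two-protein complex is summarized by four
RMSD schemes over Cα atoms: (1) fit and measure on the whole complex,
(2) fit and measure on the G protein, (3) fit and measure on the GEF,
(4) fit on the G protein, measure on the GEF.  Scheme 4 isolates the
orientational fluctuation of one partner relative to the other and is
expected to exceed scheme 3 whenever the partners move relative to each
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import SnapshotEnsemble

__all__ = [
    "SuperpositionResult",
    "SeriesStatistic",
    "superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "distance_series",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid-body transform mapping mobile onto reference."""

    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector, Å
    fit_rmsd: float  # Å, over the fit subset after transformation


@dataclass
class SeriesStatistic:
    """Per-frame scalar series with its mean and standard deviation."""

    values: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _check_subset(coords, subset):
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("atom subset is empty")
    if subset.max() >= len(coords):
        raise ValueError("subset index outside coordinate array")
    return subset


def superpose(mobile, reference, fit_subset=None) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns rotation R and translation t such that ``x @ R.T + t``
    minimizes the RMSD over ``fit_subset`` (all atoms if None).  A proper
    rotation (det = +1) is always returned.  Degenerate (collinear) fit
    subsets raise ValueError.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile/reference shape mismatch")
    if fit_subset is None:
        fit_subset = np.arange(len(mobile))
    fit_subset = _check_subset(mobile, fit_subset)
    if fit_subset.size < 3:
        raise ValueError("need at least 3 fit atoms")

    m = mobile[fit_subset]
    r = reference[fit_subset]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    # Collinearity check: rank of the centered point cloud
    sv = np.linalg.svd(m - mc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("fit subset is collinear or degenerate")

    rot, rssd = Rotation.align_vectors(r - rc, m - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    fitted = m @ R.T + t
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, fit_rmsd=fit_rmsd)


def apply_transform(coords, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def rmsd(a, b, subset=None) -> float:
    """Plain coordinate RMSD (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if subset is not None:
        subset = _check_subset(a, subset)
        a, b = a[subset], b[subset]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    ensemble: SnapshotEnsemble,
    reference,
    fit_subset,
    measure_subset=None,
) -> SeriesStatistic:
    """Per-frame RMSD of measure_subset after rigid fitting on fit_subset.

    The four standard schemes are obtained by choosing
    (fit, measure) = (complex, complex), (Arf1, Arf1), (GEF, GEF) and
    (Arf1, GEF).
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != ensemble.frames.shape[1:]:
        raise ValueError("reference atom count does not match ensemble")
    fit_subset = _check_subset(reference, fit_subset)
    measure_subset = (
        fit_subset if measure_subset is None else _check_subset(reference, measure_subset)
    )
    values = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.frames):
        res = superpose(frame, reference, fit_subset)
        fitted = apply_transform(frame, res)
        values[i] = rmsd(fitted, reference, measure_subset)
    return SeriesStatistic(values, ensemble.frame_times.copy())


def rmsf(ensemble: SnapshotEnsemble, fit_subset, target) -> float:
    """RMS fluctuation of the target-group centroid in the fit group's frame.

    Each frame is first superposed on the ensemble's first frame using
    fit_subset (e.g. the nucleotide), then the centroid of ``target``
    (e.g. the divalent ion) is collected; the result is the root
    mean-square deviation of that centroid about its ensemble mean, in Å.
    Invariant to rigid motion of the fit group.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    fit_subset = _check_subset(ensemble.frames[0], fit_subset)
    target = _check_subset(ensemble.frames[0], target)
    ref = ensemble.frames[0]
    centroids = np.empty((ensemble.n_frames, 3))
    for i, frame in enumerate(ensemble.frames):
        res = superpose(frame, ref, fit_subset)
        centroids[i] = apply_transform(frame[target], res).mean(axis=0)
    dev = centroids - centroids.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def distance_series(ensemble: SnapshotEnsemble, atom_a: int, atom_b: int) -> SeriesStatistic:
    """Euclidean distance between two atoms per frame, in Å."""
    n = ensemble.frames.shape[1]
    if not (0 <= atom_a < n and 0 <= atom_b < n):
        raise ValueError("atom index outside topology")
    if atom_a == atom_b:
        raise ValueError("distance of an atom to itself is not meaningful")
    d = np.linalg.norm(ensemble.frames[:, atom_a] - ensemble.frames[:, atom_b], axis=1)
    return SeriesStatistic(d, ensemble.frame_times.copy())
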