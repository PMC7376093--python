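"""Domain-level conformational metrics: plane angle, RMSD, trajectory PCA.

The inter-domain angle is measured between the oriented normals of two
planes, each defined by an ordered residue triplet (backbone beads for
coarse-grained systems, C-alpha atoms for atomistic ones). The normals
are ``normalize((P2-P1) x (P3-P1))`` with the vertex order exactly as
configured, and the angle is ``arccos(clamp(n1 . n2))`` in degrees — no
folding to <= 90 degrees, so the orientation convention is fixed purely
by the stated vertex order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from lipdyn.trajectory_model import (
    EmptySelectionError,
    FrameSeries,
    ParticleMeta,
)

logger = logging.getLogger(__name__)

COLLINEAR_TOL = 1e-9  # nm^2, cross-product norm below which a triplet is flat


class ConformationError(ValueError):
    pass


@dataclass(frozen=True)
class PlaneSpec:
    """Ordered residue triplets defining the two domain planes.

    ``particle_rule`` selects which particle represents each residue:
    ``backbone_bead`` matches names ``{"BB"}``, ``CA`` matches ``{"CA"}``.
    """

    domain1_residues: tuple[int, int, int]
    domain2_residues: tuple[int, int, int]
    particle_rule: str = "backbone_bead"

    _RULE_NAMES = {"backbone_bead": ("BB",), "CA": ("CA",)}

    def __post_init__(self) -> None:
        if self.particle_rule not in self._RULE_NAMES:
            raise ConformationError(
                f"particle_rule must be one of {sorted(self._RULE_NAMES)}")
        for trip in (self.domain1_residues, self.domain2_residues):
            if len(trip) != 3:
                raise ConformationError("each domain needs exactly 3 residues")

    def resolve(self, meta: ParticleMeta) -> tuple[np.ndarray, np.ndarray]:
        names = self._RULE_NAMES[self.particle_rule]
        out = []
        for trip in (self.domain1_residues, self.domain2_residues):
            idx = []
            for rid in trip:
                mask = (meta.residue_ids == rid) & np.isin(
                    meta.particle_names, names)
                hits = np.flatnonzero(mask)
                if hits.size != 1:
                    raise ConformationError(
                        f"residue {rid} with particle {names} resolves to "
                        f"{hits.size} particles (need exactly 1)")
                idx.append(int(hits[0]))
            out.append(np.array(idx))
        return out[0], out[1]


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame inter-plane angle in degrees with validity mask."""

    angles: np.ndarray  # degrees, NaN on excluded frames
    valid: np.ndarray  # bool per frame

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.angles[self.valid]))

    @property
    def std(self) -> float:
        return float(np.nanstd(self.angles[self.valid]))


@dataclass(frozen=True)
class PCAResult:
    """Eigen-decomposition of fitted-coordinate covariance."""

    mean_coordinates: np.ndarray  # (M, 3) time mean of analysis selection
    eigenvalues: np.ndarray  # nm^2, non-increasing
    eigenvectors: np.ndarray  # (n_components, 3M), rows orthonormal
    projections: np.ndarray  # (n_frames, n_components)
    extreme_low: np.ndarray  # (M, 3) mean + min projection along PC1
    extreme_high: np.ndarray  # (M, 3) mean + max projection along PC1

    @property
    def fraction_first(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues.sum())


def _plane_normals(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normals for (F, 3, 3) ordered triplets; returns (normals, valid)."""
    v1 = points[:, 1] - points[:, 0]
    v2 = points[:, 2] - points[:, 0]
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n, axis=1)
    valid = norm > COLLINEAR_TOL
    safe = np.where(valid, norm, 1.0)
    return n / safe[:, None], valid


def interdomain_angle(
    frames: FrameSeries,
    spec: PlaneSpec,
    meta: ParticleMeta | None = None,
    indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> AngleSeries:
    """Per-frame oriented angle between the two domain planes, in degrees.

    Pass either ``meta`` (residue triplets are resolved via the spec's
    particle rule) or pre-resolved ``indices``. Frames with a collinear
    triplet are excluded (NaN) and logged, not fatal.
    """
    if indices is None:
        if meta is None:
            raise ConformationError("need meta or pre-resolved indices")
        indices = spec.resolve(meta)
    idx1, idx2 = indices
    p1 = frames.coordinates[:, idx1, :]
    p2 = frames.coordinates[:, idx2, :]
    n1, valid1 = _plane_normals(p1)
    n2, valid2 = _plane_normals(p2)
    valid = valid1 & valid2
    cosang = np.clip((n1 * n2).sum(axis=1), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    if not valid.all():
        bad = np.flatnonzero(~valid)
        logger.warning("collinear plane triplet in %d frame(s): %s ...",
                       bad.size, bad[:5].tolist())
        angles = angles.astype(float)
        angles[~valid] = np.nan
    if not valid.any():
        raise ConformationError("all frames have collinear plane triplets")
    return AngleSeries(angles=angles, valid=valid)


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns ``(transformed, rotation, translation)`` where
    ``transformed = (mobile - mobile_fit_centroid) @ R.T + ref_fit_centroid``
    and the rotation minimizes the RMSD over ``fit_indices`` (all points if
    None). The rotation always has det = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    if fit.size < 3:
        raise ConformationError("need >= 3 fit particles for superposition")
    mob_fit = mobile[fit]
    ref_fit = reference[fit]
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    h = (mob_fit - mob_c).T @ (ref_fit - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transformed = (mobile - mob_c) @ rot.T + ref_c
    translation = ref_c - rot @ mob_c
    return transformed, rot, translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (nm) between equal-shape point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def domain_rmsd(
    frames: FrameSeries,
    fit_indices: np.ndarray,
    rmsd_indices: np.ndarray,
) -> np.ndarray:
    """Per-frame RMSD vs frame 0 over ``rmsd_indices``, after fitting each
    frame to frame 0 on ``fit_indices`` (e.g. ECD RMSD superposed on the TMD).
    """
    fit_indices = np.asarray(fit_indices)
    rmsd_indices = np.asarray(rmsd_indices)
    if fit_indices.size == 0 or rmsd_indices.size == 0:
        raise EmptySelectionError("fit or rmsd selection")
    ref = frames.coordinates[0]
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        transformed, _, _ = superpose(frames.coordinates[f], ref, fit_indices)
        out[f] = rmsd(transformed[rmsd_indices], ref[rmsd_indices])
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def trajectory_pca(
    frames: FrameSeries,
    fit_indices: np.ndarray,
    analysis_indices: np.ndarray,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of analysis-selection coordinates after fitting frames to frame 0.

    Covariance is taken about the time mean of the flattened fitted
    coordinates (ddof=0, so the eigenvalue sum equals total variance
    exactly). A warning is logged when ``n_frames <= 3 x n_analysis``
    (undersampled covariance); zero total variance is an error.
    """
    fit_indices = np.asarray(fit_indices)
    analysis_indices = np.asarray(analysis_indices)
    n_frames = frames.n_frames
    m = analysis_indices.size
    if n_frames <= 3 * m:
        logger.warning(
            "PCA with %d frames for %d particles (3M=%d dof) is undersampled",
            n_frames, m, 3 * m)
    fitted = np.empty((n_frames, m, 3))
    ref = frames.coordinates[0]
    for f in range(n_frames):
        transformed, _, _ = superpose(frames.coordinates[f], ref, fit_indices)
        fitted[f] = transformed[analysis_indices]
    flat = fitted.reshape(n_frames, 3 * m)
    mean = flat.mean(axis=0)
    centered = flat - mean
    total_var = float((centered ** 2).sum() / n_frames)
    scale = max(float((flat ** 2).mean()), 1.0)
    if total_var <= 1e-18 * scale:  # zero up to superposition round-off
        raise ConformationError("no motion to analyze (zero total variance)")
    # SVD of the centered data matrix; eigenvalues = s^2 / n_frames
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / n_frames
    if n_components is None:
        n_components = len(eigenvalues)
    eigenvalues = eigenvalues[:n_components]
    eigenvectors = vt[:n_components]
    projections = centered @ eigenvectors.T
    pc1 = eigenvectors[0]
    lo = mean + projections[:, 0].min() * pc1
    hi = mean + projections[:, 0].max() * pc1
    return PCAResult(
        mean_coordinates=mean.reshape(m, 3),
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
        extreme_low=lo.reshape(m, 3),
        extreme_high=hi.reshape(m, 3),
    )
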