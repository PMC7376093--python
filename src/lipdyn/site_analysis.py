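"""Binding-site occupancy time series and lateral radial lipid distribution.

Occupancy counts lipid headgroup particles within a cutoff (default 0.6 nm,
i.e. 6 A) of any site residue particle, per frame, and normalizes the
series by its maximum. The radial distribution is 2D/lateral: distances
are measured in the membrane (xy) plane from the reference selection's
center of geometry, and the histogram is normalized by annulus area, frame
count, and the species' mean lateral number density so a uniformly
distributed species gives g(r) ~ 1 at large r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from lipdyn.trajectory_model import FrameSeries, ParticleMeta

DEFAULT_SITE_CUTOFF = 0.6  # nm (= 6 A)


class SiteAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class BindingSite:
    """A labeled set of protein residues probed at a distance cutoff."""

    label: str
    residue_ids: tuple[int, ...]
    cutoff: float = DEFAULT_SITE_CUTOFF

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise SiteAnalysisError(f"site {self.label!r} has no residues")
        if self.cutoff <= 0:
            raise SiteAnalysisError("cutoff must be > 0")

    def particle_indices(self, meta: ParticleMeta,
                         protein_indices: np.ndarray | None = None) -> np.ndarray:
        mask = np.isin(meta.residue_ids, self.residue_ids)
        mask &= meta.categories == "protein"
        idx = np.flatnonzero(mask)
        if protein_indices is not None:
            idx = np.intersect1d(idx, protein_indices)
        if idx.size == 0:
            raise SiteAnalysisError(
                f"site {self.label!r} residues {self.residue_ids} not found "
                "in the protein")
        return idx


@dataclass(frozen=True)
class OccupancySeries:
    """Per-frame raw headgroup-particle counts near a site, plus normalized."""

    site_label: str
    raw: np.ndarray  # int counts per frame
    normalized: np.ndarray  # raw / max(raw), or all 0

    def __post_init__(self) -> None:
        if np.any((self.normalized < 0) | (self.normalized > 1)):
            raise SiteAnalysisError("normalized occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class RadialProfile:
    """Lateral g(r) around a reference axis with uniform bins."""

    r: np.ndarray  # bin centers, nm
    g: np.ndarray
    counts: np.ndarray  # raw observations per bin
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise SiteAnalysisError("g(r) must be >= 0")


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def site_occupancy(
    frames: FrameSeries,
    meta: ParticleMeta,
    site: BindingSite,
    headgroup_indices: np.ndarray,
    count_molecules: bool = False,
) -> OccupancySeries:
    """Count headgroup particles within the site cutoff, per frame.

    ``count_molecules=True`` counts lipid molecules with at least one
    headgroup particle in range instead of individual particles.
    Normalization: ``raw / max(raw)`` when any frame has a nonzero count,
    otherwise all zeros.
    """
    site_idx = site.particle_indices(meta)
    headgroup_indices = np.asarray(headgroup_indices)
    if headgroup_indices.size == 0:
        raise SiteAnalysisError("headgroup selection is empty")
    raw = np.zeros(frames.n_frames, dtype=int)
    mol_keys = meta.molecule_keys()[headgroup_indices]
    for f in range(frames.n_frames):
        hg = frames.coordinates[f, headgroup_indices]
        sp = frames.coordinates[f, site_idx]
        delta = _min_image(hg[:, None, :] - sp[None, :, :],
                           frames.box[f][None, None, :])
        dmin = np.sqrt((delta ** 2).sum(axis=-1)).min(axis=1)
        in_range = dmin <= site.cutoff
        if count_molecules:
            raw[f] = len(set(mol_keys[in_range]))
        else:
            raw[f] = int(in_range.sum())
    peak = raw.max()
    normalized = raw / peak if peak > 0 else np.zeros_like(raw, dtype=float)
    return OccupancySeries(site_label=site.label, raw=raw, normalized=normalized)


def lateral_rdf(
    frames: FrameSeries,
    reference_indices: np.ndarray,
    species_indices: np.ndarray,
    r_max: float,
    n_bins: int = 50,
    leaflet_z_range: tuple[float, float] | None = None,
) -> RadialProfile:
    """Lateral (xy) radial distribution of species beads around a reference.

    Per frame, the lateral minimum-image distance from each species
    headgroup bead to the xy center of geometry of ``reference_indices``
    is histogrammed on ``[0, r_max]``. Normalization divides by annulus
    area ``2 pi r dr``, the frame count, and the mean lateral number
    density of the species (particles per box xy-area), so a uniform
    species yields g ~ 1.

    ``leaflet_z_range`` restricts counted beads to a z slab, keeping
    extracellular and intracellular species from mixing leaflets.
    """
    reference_indices = np.asarray(reference_indices)
    species_indices = np.asarray(species_indices)
    if reference_indices.size == 0 or species_indices.size == 0:
        raise SiteAnalysisError("reference and species selections must be non-empty")
    min_lateral = float(frames.box[:, :2].min())
    if r_max > min_lateral / 2.0:
        raise SiteAnalysisError(
            f"r_max={r_max} nm exceeds half the smallest lateral box length "
            f"({min_lateral / 2.0} nm)")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins, dtype=float)
    density_sum = 0.0
    for f in range(frames.n_frames):
        ref_xy = frames.coordinates[f, reference_indices, :2].mean(axis=0)
        sp = frames.coordinates[f, species_indices]
        if leaflet_z_range is not None:
            zlo, zhi = leaflet_z_range
            sp = sp[(sp[:, 2] >= zlo) & (sp[:, 2] <= zhi)]
        delta = _min_image(sp[:, :2] - ref_xy[None, :],
                           frames.box[f][None, :2])
        r = np.sqrt((delta ** 2).sum(axis=-1))
        hist, _ = np.histogram(r, bins=edges)
        counts += hist
        area = frames.box[f, 0] * frames.box[f, 1]
        density_sum += len(sp) / area
    mean_density = density_sum / frames.n_frames
    if mean_density == 0:
        raise SiteAnalysisError("species selection contributes no particles")
    dr = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    annulus = 2.0 * np.pi * centers * dr
    g = counts / (frames.n_frames * annulus * mean_density)
    return RadialProfile(r=centers, g=g, counts=counts, bin_width=float(dr))
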