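"""Synthetic trajectories and duration samples with known ground truth.

The generators encode only the statistical structure the analyses assume:
Markovian binding/unbinding at labeled protein sites, lateral diffusion in a
leaflet plane, rigid two-domain hinge motion, and exponential-mixture
duration samples. No physical realism is attempted.

Placement geometry is constructed strictly inside/outside the dual-cutoff
band (bound headgroups < 0.45 nm from a site residue, unbound headgroups
>= 1.2 nm from every protein bead) so that contact detection under the
0.55/1.0 nm rule recovers the Markov state exactly, frame for frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from lipdyn.trajectory_model import (
    CATEGORY_LIPID,
    CATEGORY_PROTEIN,
    FrameSeries,
    ParticleMeta,
    TrajectoryModelError,
)

BOUND_DISTANCE = 0.30  # nm, lateral offset of a bound headgroup from its site bead
BOUND_MAX = 0.45  # nm, guaranteed upper bound while bound
UNBOUND_MIN = 1.2  # nm, guaranteed clearance while unbound
MAX_KOFF_DT = 0.2  # dimensionless bound on k_off*dt for faithful discretization


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class BoundInterval:
    """One true bound episode: frames ``start``..``end`` inclusive."""

    lipid_id: int
    site_index: int
    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class SyntheticGroundTruth:
    """True parameters a generated trajectory encodes, for recovery tests."""

    rng_seed: int
    site_residue_ids: list[list[int]] = field(default_factory=list)
    k_on: list[float] = field(default_factory=list)  # ns^-1 per site
    k_off: list[float] = field(default_factory=list)  # ns^-1 per site
    bound_intervals: list[BoundInterval] = field(default_factory=list)
    angle_series_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        for rate_list in (self.k_on, self.k_off):
            if any(r <= 0 for r in rate_list):
                raise SyntheticDataError("k_on and k_off must be > 0")
        if self.angle_series_deg is not None:
            a = np.asarray(self.angle_series_deg, dtype=float)
            if np.any((a < 0) | (a > 180)):
                raise SyntheticDataError("angles must lie in [0, 180] degrees")
        by_key: dict[tuple[int, int], list[BoundInterval]] = {}
        for iv in self.bound_intervals:
            by_key.setdefault((iv.lipid_id, iv.site_index), []).append(iv)
        for ivs in by_key.values():
            ivs = sorted(ivs, key=lambda iv: iv.start_frame)
            for a_iv, b_iv in zip(ivs, ivs[1:]):
                if b_iv.start_frame <= a_iv.end_frame:
                    raise SyntheticDataError("overlapping bound intervals")

    def durations_ns(self, dt: float) -> np.ndarray:
        """True bound durations in ns under the inclusive-frame convention."""
        return np.array([iv.n_frames * dt for iv in self.bound_intervals])


def _site_centers(n_sites: int, box: float, spacing: float = 2.0) -> np.ndarray:
    """Lateral site-bead centers around the box center, pairwise >= spacing apart."""
    cx = cy = box / 2.0
    if n_sites == 1:
        return np.array([[cx, cy]])
    radius = spacing / (2.0 * np.sin(np.pi / n_sites))
    angles = 2.0 * np.pi * np.arange(n_sites) / n_sites
    return np.stack(
        [cx + radius * np.cos(angles), cy + radius * np.sin(angles)], axis=1)


def make_binding_trajectory(
    n_lipids: int,
    sites: Sequence[tuple[Sequence[int], float, float]],
    dt: float,
    n_frames: int,
    box: float,
    seed: int,
    species: str = "GM3",
    protein_residue_ids: Sequence[int] | None = None,
    step_sigma: float = 0.3,
    leaflet_z: float | None = None,
) -> tuple[ParticleMeta, FrameSeries, SyntheticGroundTruth]:
    """Generate a leaflet of lipids binding/unbinding at protein sites.

    Parameters
    ----------
    n_lipids
        Number of single-bead lipid headgroups.
    sites
        ``(residue_ids, k_on, k_off)`` per site; rates in ns^-1. Pass an
        empty k_on as a positive number; degenerate "never binds" behavior
        is obtained with a tiny k_on only if exact zero is not needed —
        ``k_on=0.0`` is accepted as the explicit no-binding case.
    dt, n_frames, box
        Frame spacing (ns), frame count, and cubic box edge (nm).
    seed
        Seeds all randomness; identical seeds give bit-identical output.
    protein_residue_ids
        Full protein residue set; defaults to the union of site residues.
        Site residues must be a subset.

    Each lipid follows a two-state Markov chain: unbound -> bound with
    probability ``1 - exp(-k_on_total*dt)`` (site chosen proportionally to
    its k_on), bound(site s) -> unbound with probability ``1 - exp(-k_off_s*dt)``.
    A lipid occupies at most one site at a time. Unbound lipids do a
    reflected 2D random walk at fixed z, kept >= 1.2 nm laterally from all
    protein beads; bound lipids sit 0.3 nm from their site bead.
    """
    if dt <= 0:
        raise SyntheticDataError("dt must be > 0")
    if n_frames < 1 or n_lipids < 0:
        raise SyntheticDataError("n_frames >= 1 and n_lipids >= 0 required")
    k_on = np.array([float(s[1]) for s in sites])
    k_off = np.array([float(s[2]) for s in sites])
    if np.any(k_on < 0) or np.any(k_off <= 0):
        raise SyntheticDataError("k_on must be >= 0 and k_off > 0")
    bad = k_off * dt > MAX_KOFF_DT
    if np.any(bad):
        raise SyntheticDataError(
            f"k_off*dt exceeds {MAX_KOFF_DT} for site(s) "
            f"{np.flatnonzero(bad).tolist()}; decrease dt so the discrete "
            "chain approximates the continuous process")

    site_rids = [list(int(r) for r in s[0]) for s in sites]
    if protein_residue_ids is None:
        protein_residue_ids = sorted({r for rids in site_rids for r in rids})
        if not protein_residue_ids:
            protein_residue_ids = [1]
    protein_residue_ids = [int(r) for r in protein_residue_ids]
    missing = {r for rids in site_rids for r in rids} - set(protein_residue_ids)
    if missing:
        raise SyntheticDataError(
            f"site residue_ids not in protein residue set: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    z0 = leaflet_z if leaflet_z is not None else box / 2.0

    centers = _site_centers(max(n_sites, 1), box)
    # protein bead per residue: site residues cluster within 0.1 nm of their
    # site center; non-site residues sit at the box center.
    rid_xy: dict[int, np.ndarray] = {}
    for s, rids in enumerate(site_rids):
        for j, rid in enumerate(rids):
            offset = 0.1 * np.array(
                [np.cos(2 * np.pi * j / max(len(rids), 1)),
                 np.sin(2 * np.pi * j / max(len(rids), 1))])
            rid_xy[rid] = centers[s] + (offset if len(rids) > 1 else 0.0)
    center_xy = np.array([box / 2.0, box / 2.0])
    for rid in protein_residue_ids:
        rid_xy.setdefault(rid, center_xy)
    protein_xy = np.stack([rid_xy[r] for r in protein_residue_ids])
    n_protein = len(protein_residue_ids)

    # lateral exclusion radius around each protein bead for unbound lipids
    exclusion = UNBOUND_MIN

    def push_out(xy: np.ndarray) -> np.ndarray:
        """Project points radially out of every protein bead's exclusion disk.

        Disks of neighboring sites overlap, so iterate until clean.
        """
        for _ in range(20):
            clean = True
            for bead in protein_xy:
                d = xy - bead
                r = np.linalg.norm(d, axis=1)
                inside = r < exclusion
                if np.any(inside):
                    clean = False
                    safe = np.where(r[inside] < 1e-12, 1.0, r[inside])
                    xy[inside] = bead + d[inside] / safe[:, None] * (exclusion + 1e-6)
            if clean:
                break
        return np.clip(xy, 1e-6, box - 1e-6)

    # uniform initial placement outside exclusion zones (stationary start)
    lipid_xy = rng.uniform(0.0, box, size=(n_lipids, 2))
    for _ in range(50):
        bad_mask = np.zeros(n_lipids, dtype=bool)
        for bead in protein_xy:
            bad_mask |= np.linalg.norm(lipid_xy - bead, axis=1) < exclusion
        if not bad_mask.any():
            break
        lipid_xy[bad_mask] = rng.uniform(0.0, box, size=(int(bad_mask.sum()), 2))
    lipid_xy = push_out(lipid_xy)

    p_off = 1.0 - np.exp(-k_off * dt)
    k_on_total = k_on.sum()
    p_on = 1.0 - np.exp(-k_on_total * dt) if n_sites else 0.0
    site_prob = k_on / k_on_total if k_on_total > 0 else np.zeros(n_sites)

    state = np.full(n_lipids, -1, dtype=int)  # -1 unbound, else site index
    bound_since = np.full(n_lipids, -1, dtype=int)
    intervals: list[BoundInterval] = []

    n_particles = n_protein + n_lipids
    coords = np.empty((n_frames, n_particles, 3), dtype=float)
    # non-site protein residues sit 2.5 nm above the leaflet plane so they
    # never enter the dual-cutoff band of any lipid; site beads are in-plane
    site_rid_set = {r for rids in site_rids for r in rids}
    protein_z = np.array(
        [z0 if rid in site_rid_set else z0 + 2.5 for rid in protein_residue_ids])
    protein_pos = np.column_stack([protein_xy, protein_z])

    bound_offsets = rng.uniform(0.0, 2 * np.pi, size=n_lipids)
    for f in range(n_frames):
        if f > 0:
            # Markov step first (state at frame f), then place coordinates.
            if n_sites:
                unbinding = (state >= 0) & (
                    rng.random(n_lipids) < p_off[np.clip(state, 0, None)])
                for i in np.flatnonzero(unbinding):
                    intervals.append(BoundInterval(
                        lipid_id=int(i), site_index=int(state[i]),
                        start_frame=int(bound_since[i]), end_frame=f - 1))
                    # respawn just outside the exclusion zone, random direction
                    theta = rng.uniform(0.0, 2 * np.pi)
                    s_idx = state[i]
                    lipid_xy[i] = centers[s_idx] + (exclusion + 0.05) * np.array(
                        [np.cos(theta), np.sin(theta)])
                state[unbinding] = -1
                # a lipid that unbound this frame may not rebind until the
                # next frame; otherwise adjacent true intervals would merge
                # into a single detected contact event
                binding = (state < 0) & ~unbinding & (rng.random(n_lipids) < p_on)
                if binding.any():
                    chosen = rng.choice(n_sites, size=int(binding.sum()), p=site_prob)
                    idxs = np.flatnonzero(binding)
                    state[idxs] = chosen
                    bound_since[idxs] = f
                    bound_offsets[idxs] = rng.uniform(
                        0.0, 2 * np.pi, size=len(idxs))
            free = state < 0
            steps = rng.normal(0.0, step_sigma, size=(n_lipids, 2))
            lipid_xy[free] += steps[free]
            # reflect at box walls, then clear protein exclusion disks
            lipid_xy = np.where(lipid_xy < 0, -lipid_xy, lipid_xy)
            lipid_xy = np.where(lipid_xy > box, 2 * box - lipid_xy, lipid_xy)
            lipid_xy[free] = push_out(lipid_xy[free])
        else:
            if n_sites and k_on_total > 0:
                binding = rng.random(n_lipids) < p_on
                if binding.any():
                    chosen = rng.choice(n_sites, size=int(binding.sum()), p=site_prob)
                    idxs = np.flatnonzero(binding)
                    state[idxs] = chosen
                    bound_since[idxs] = 0

        pos = np.column_stack([lipid_xy, np.full(n_lipids, z0)])
        bound = state >= 0
        if bound.any():
            s_idx = state[bound]
            first_rid = np.array([site_rids[s][0] for s in s_idx])
            anchors = np.stack([rid_xy[r] for r in first_rid])
            ang = bound_offsets[bound]
            pos[bound, 0] = anchors[:, 0] + BOUND_DISTANCE * np.cos(ang)
            pos[bound, 1] = anchors[:, 1] + BOUND_DISTANCE * np.sin(ang)
        coords[f, :n_protein] = protein_pos
        coords[f, n_protein:] = pos

    for i in np.flatnonzero(state >= 0):  # close episodes still bound at end
        intervals.append(BoundInterval(
            lipid_id=int(i), site_index=int(state[i]),
            start_frame=int(bound_since[i]), end_frame=n_frames - 1))
    intervals.sort(key=lambda iv: (iv.lipid_id, iv.start_frame))

    meta = ParticleMeta(
        residue_ids=np.array(protein_residue_ids + list(range(1, n_lipids + 1))),
        residue_names=np.array(["ALA"] * n_protein + [species] * n_lipids),
        segment_ids=np.array(["PROT"] * n_protein + ["MEMB"] * n_lipids),
        particle_names=np.array(["BB"] * n_protein + ["HG"] * n_lipids),
        categories=np.array(
            [CATEGORY_PROTEIN] * n_protein + [CATEGORY_LIPID] * n_lipids),
        species=np.array([""] * n_protein + [species] * n_lipids),
    )
    frames = FrameSeries(
        times=np.arange(n_frames, dtype=float) * dt,
        coordinates=coords,
        box=np.tile(np.array([box, box, box], dtype=float), (n_frames, 1)),
    )
    truth = SyntheticGroundTruth(
        rng_seed=seed,
        site_residue_ids=site_rids,
        k_on=[float(k) for k in np.maximum(k_on, np.finfo(float).tiny)],
        k_off=[float(k) for k in k_off],
        bound_intervals=intervals,
    )
    return meta, frames, truth


# ---------------------------------------------------------------------------
# hinge trajectories
# ---------------------------------------------------------------------------

def _triplet_normal(points: np.ndarray) -> np.ndarray:
    p1, p2, p3 = points
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise SyntheticDataError("plane-defining triplet is collinear")
    return n / norm


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def make_hinge_trajectory(
    domain_a_points: np.ndarray,
    domain_b_points: np.ndarray,
    angle_series: Sequence[float],
    dt: float = 1.0,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    n_filler: int = 5,
    box: float = 50.0,
) -> tuple[ParticleMeta, FrameSeries, SyntheticGroundTruth]:
    """Two rigid domains hinged so the inter-plane angle tracks ``angle_series``.

    ``domain_a_points`` / ``domain_b_points`` are ``(3+, 3)`` arrays whose
    first three rows are the plane-defining particles (ordered as the
    angle measurement expects); extra rows are rigid filler. Domain A is
    fixed; domain B is rigid-rotated per frame about a fixed hinge axis
    (perpendicular to both initial normals) so the oriented inter-plane
    angle equals ``angle_series`` exactly. Gaussian jitter of
    ``jitter_sigma`` nm, if requested, is added to filler beads only.
    """
    a_pts = np.asarray(domain_a_points, dtype=float)
    b_pts = np.asarray(domain_b_points, dtype=float)
    angle_series = np.asarray(angle_series, dtype=float)
    if np.any((angle_series < 0) | (angle_series > 180)):
        raise SyntheticDataError("angle_series values must lie in [0, 180]")
    if a_pts.shape[0] < 3 or b_pts.shape[0] < 3:
        raise SyntheticDataError("each domain needs >= 3 points")

    n_a = _triplet_normal(a_pts[:3])
    n_b0 = _triplet_normal(b_pts[:3])

    axis = np.cross(n_a, n_b0)
    if np.linalg.norm(axis) < 1e-9:
        # normals parallel/antiparallel: any axis perpendicular to n_a works
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, n_a)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        axis = np.cross(n_a, trial)
    axis = axis / np.linalg.norm(axis)

    # signed angle of n_b0 relative to n_a in the plane perpendicular to axis
    phi0 = float(np.degrees(np.arctan2(
        np.dot(np.cross(n_a, n_b0), axis), np.dot(n_a, n_b0))))

    hinge_point = b_pts[:3].mean(axis=0)
    rng = np.random.default_rng(seed)

    n_frames = len(angle_series)
    extra_a = max(a_pts.shape[0] - 3, 0)
    extra_b = max(b_pts.shape[0] - 3, 0)
    filler = rng.uniform(-2.0, 2.0, size=(n_filler, 3)) + hinge_point
    all_b_template = np.vstack([b_pts, filler]) if n_filler else b_pts
    n_particles = a_pts.shape[0] + all_b_template.shape[0]

    coords = np.empty((n_frames, n_particles, 3), dtype=float)
    for f, theta in enumerate(angle_series):
        rot = _rotation_about_axis(axis, np.radians(theta - phi0))
        b_now = (all_b_template - hinge_point) @ rot.T + hinge_point
        if jitter_sigma > 0:
            jitter = rng.normal(0.0, jitter_sigma, size=b_now.shape)
            jitter[:3] = 0.0  # plane-defining particles stay exact
            b_now = b_now + jitter
        coords[f, : a_pts.shape[0]] = a_pts
        coords[f, a_pts.shape[0]:] = b_now
    coords += box / 2.0  # center in the box

    n_b_total = all_b_template.shape[0]
    meta = ParticleMeta(
        residue_ids=np.arange(1, n_particles + 1),
        residue_names=np.array(["ALA"] * n_particles),
        segment_ids=np.array(
            ["DOMA"] * a_pts.shape[0] + ["DOMB"] * n_b_total),
        particle_names=np.array(
            ["CA"] * 3 + ["FIL"] * extra_a + ["CA"] * 3 + ["FIL"] * (n_b_total - 3)),
        categories=np.array([CATEGORY_PROTEIN] * n_particles),
        species=np.array([""] * n_particles),
    )
    frames = FrameSeries(
        times=np.arange(n_frames, dtype=float) * dt,
        coordinates=coords,
        box=np.tile(np.array([box, box, box], dtype=float), (n_frames, 1)),
    )
    truth = SyntheticGroundTruth(
        rng_seed=seed, angle_series_deg=angle_series.copy())
    return meta, frames, truth


# ---------------------------------------------------------------------------
# duration samples
# ---------------------------------------------------------------------------

def sample_durations(
    amplitude_fast: float,
    k_fast: float,
    k_slow: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` i.i.d. durations (ns) from a two-exponential mixture.

    The mixture is ``amplitude_fast * Exp(k_fast) + (1 - amplitude_fast)
    * Exp(k_slow)`` with rates in ns^-1.
    """
    if not 0.0 <= amplitude_fast <= 1.0:
        raise SyntheticDataError("amplitude_fast must lie in [0, 1]")
    if not (k_fast >= k_slow > 0):
        raise SyntheticDataError("require k_fast >= k_slow > 0")
    if n < 1:
        raise SyntheticDataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < amplitude_fast
    out = np.where(
        fast,
        rng.exponential(1.0 / k_fast, size=n),
        rng.exponential(1.0 / k_slow, size=n),
    )
    return out
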