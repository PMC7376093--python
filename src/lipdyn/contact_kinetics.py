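"""Dual-cutoff lipid-protein contact detection and residence-time kinetics.

The contact rule is a two-state hysteresis automaton per (lipid, target):
a contact starts when the minimum headgroup-target distance drops below
``d_on``, persists while it stays at or below ``d_off``, and ends at the
first frame above ``d_off`` (that frame is unbound; the event's last frame
is the preceding one). Events still open at the final frame are closed
there and flagged censored. Default cutoffs are 0.55/1.0 nm for
coarse-grained systems and 0.35/0.55 nm for atomistic ones.

Pooled contact durations feed an empirical survival curve sigma(t) =
fraction of events lasting at least t, which is fitted with a
bi-exponential ``A*exp(-k_fast*t) + (1-A)*exp(-k_slow*t)``; ``k_off`` is
the slow rate and the residence time is ``1/k_off``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from lipdyn.trajectory_model import FrameSeries, ParticleMeta

logger = logging.getLogger(__name__)

#: dual-cutoff presets (d_on, d_off) in nm per resolution
CUTOFF_PRESETS: dict[str, tuple[float, float]] = {
    "cg": (0.55, 1.0),
    "at": (0.35, 0.55),
}

GROUPINGS = ("residue", "site", "whole_protein")

#: minimum pooled event count for a survival fit; below this the profile
#: reports the mean duration instead
MIN_EVENTS_FOR_FIT = 10

#: mixture components with amplitude below this are treated as spurious
#: (on near-mono-exponential data the optimizer parks ~0.1% of amplitude on
#: an arbitrary tail rate; reporting that rate as k_off would be noise)
AMPLITUDE_FLOOR = 0.02


class ContactKineticsError(ValueError):
    pass


@dataclass(frozen=True)
class ContactSpec:
    """Dual-cutoff contact definition.

    ``d_on`` and ``d_off`` in nm with ``0 < d_on <= d_off``; ``grouping``
    selects the target granularity (per residue, per declared site, or the
    whole protein surface).
    """

    d_on: float = 0.55
    d_off: float = 1.0
    grouping: str = "residue"

    def __post_init__(self) -> None:
        if not 0 < self.d_on <= self.d_off:
            raise ContactKineticsError(
                f"require 0 < d_on <= d_off, got d_on={self.d_on}, "
                f"d_off={self.d_off}")
        if self.grouping not in GROUPINGS:
            raise ContactKineticsError(
                f"grouping must be one of {GROUPINGS}, got {self.grouping!r}")

    @classmethod
    def from_preset(cls, resolution: str, grouping: str = "residue") -> "ContactSpec":
        try:
            d_on, d_off = CUTOFF_PRESETS[resolution]
        except KeyError:
            raise ContactKineticsError(
                f"unknown resolution preset {resolution!r}; "
                f"choose from {sorted(CUTOFF_PRESETS)}") from None
        return cls(d_on=d_on, d_off=d_off, grouping=grouping)


@dataclass(frozen=True)
class ContactEvent:
    """One continuous lipid-target contact under the dual-cutoff rule."""

    lipid_id: str
    target_id: str
    start_frame: int
    end_frame: int  # inclusive
    duration: float  # ns, (end - start + 1) * dt
    censored: bool = False

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ContactKineticsError("start_frame must be <= end_frame")


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival sigma(t) of contact durations on a uniform grid."""

    times: np.ndarray  # ns, from 0
    sigma: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        if abs(self.sigma[0] - 1.0) > 1e-12:
            raise ContactKineticsError("sigma(0) must be 1")
        if np.any(np.diff(self.sigma) > 1e-12):
            raise ContactKineticsError("sigma must be non-increasing")
        if np.any((self.sigma < 0) | (self.sigma > 1)):
            raise ContactKineticsError("sigma must lie in [0, 1]")


@dataclass(frozen=True)
class KineticFit:
    """Bi-exponential survival-fit parameters.

    ``k_off`` is the slow component's rate and ``residence_time = 1/k_off``.
    ``converged`` is False (never an exception) when the optimizer failed;
    in that case a mono-exponential fallback fit is reported.
    """

    amplitude_fast: float
    k_fast: float  # ns^-1
    k_slow: float  # ns^-1
    ssr: float
    n_events: int
    converged: bool

    @property
    def k_off(self) -> float:
        return self.k_slow

    @property
    def residence_time(self) -> float:
        return 1.0 / self.k_slow


@dataclass(frozen=True)
class ResidueInteractionProfile:
    """Per-target residence time, occupancy fraction, and event count."""

    target_ids: list[str]
    residence_times: np.ndarray  # ns
    occupancy: np.ndarray  # fraction of frames with >= 1 active contact
    event_counts: np.ndarray
    from_fit: np.ndarray  # bool: fitted (True) vs mean-duration fallback
    fits: dict[str, KineticFit] = field(default_factory=dict)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "target": self.target_ids,
            "residence_time_ns": self.residence_times,
            "occupancy": self.occupancy,
            "n_events": self.event_counts,
            "from_fit": self.from_fit,
        })


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _group_indices_by_key(keys: Sequence[str], indices: np.ndarray
                          ) -> tuple[list[str], list[np.ndarray]]:
    order: dict[str, list[int]] = {}
    for i in indices:
        order.setdefault(keys[i], []).append(int(i))
    labels = list(order)
    return labels, [np.array(v) for v in order.values()]


def build_targets(
    meta: ParticleMeta,
    protein_indices: np.ndarray,
    grouping: str,
    sites: Mapping[str, Sequence[int]] | None = None,
) -> tuple[list[str], list[np.ndarray]]:
    """Partition protein particle indices into labeled target groups.

    ``grouping='residue'`` yields one target per residue_id, ``'site'``
    one per declared site (label -> residue_ids), ``'whole_protein'`` a
    single target labeled ``'protein'``.
    """
    protein_indices = np.asarray(protein_indices)
    if grouping == "whole_protein":
        return ["protein"], [protein_indices]
    if grouping == "residue":
        keys = [str(int(r)) for r in meta.residue_ids]
        return _group_indices_by_key(keys, protein_indices)
    if grouping == "site":
        if not sites:
            raise ContactKineticsError("grouping='site' requires site definitions")
        labels, groups = [], []
        rid = meta.residue_ids
        for label, residue_ids in sites.items():
            mask = np.isin(rid, list(residue_ids))
            idx = np.intersect1d(np.flatnonzero(mask), protein_indices)
            if idx.size == 0:
                raise ContactKineticsError(
                    f"site {label!r} resolves to no protein particles")
            labels.append(str(label))
            groups.append(idx)
        return labels, groups
    raise ContactKineticsError(f"unknown grouping {grouping!r}")


def group_lipids(meta: ParticleMeta, headgroup_indices: np.ndarray
                 ) -> tuple[list[str], list[np.ndarray]]:
    """Group headgroup particle indices by lipid molecule (segment/residue)."""
    keys = meta.molecule_keys()
    return _group_indices_by_key([str(k) for k in keys],
                                 np.asarray(headgroup_indices))


def min_distance_series(
    frames: FrameSeries,
    lipid_groups: Sequence[np.ndarray],
    target_groups: Sequence[np.ndarray],
    chunk_frames: int | None = None,
) -> np.ndarray:
    """Per-frame minimum-image minimum distance per (lipid, target).

    Returns an array of shape ``(n_frames, n_lipids, n_targets)`` in nm.
    The minimum runs over all (headgroup particle, target particle) pairs
    of the group. Orthorhombic periodic boxes only.
    """
    if not lipid_groups or not target_groups:
        raise ContactKineticsError("lipid and target selections must be non-empty")
    if np.any(frames.box <= 0):
        raise ContactKineticsError("zero-size box encountered")
    n_frames = frames.n_frames
    lipid_idx = np.concatenate(lipid_groups)
    target_idx = np.concatenate(target_groups)
    lipid_owner = np.repeat(np.arange(len(lipid_groups)),
                            [len(g) for g in lipid_groups])
    target_owner = np.repeat(np.arange(len(target_groups)),
                             [len(g) for g in target_groups])
    if chunk_frames is None:  # keep the pairwise delta array near ~500 MB
        chunk_frames = max(1, int(2e7 / max(len(lipid_idx) * len(target_idx), 1)))
    out = np.full((n_frames, len(lipid_groups), len(target_groups)), np.inf)
    lipid_masks = [lipid_owner == li for li in range(len(lipid_groups))]
    target_masks = [target_owner == ti for ti in range(len(target_groups))]
    for lo in range(0, n_frames, chunk_frames):
        hi = min(lo + chunk_frames, n_frames)
        a = frames.coordinates[lo:hi][:, lipid_idx, :]  # (F, La, 3)
        b = frames.coordinates[lo:hi][:, target_idx, :]  # (F, Tb, 3)
        box = frames.box[lo:hi][:, None, None, :]
        delta = a[:, :, None, :] - b[:, None, :, :]
        delta -= box * np.round(delta / box)
        dist2 = (delta ** 2).sum(axis=-1)  # (F, La, Tb)
        # reduce particle-level distances to group-level minima
        for li, lmask in enumerate(lipid_masks):
            sub = dist2[:, lmask, :]
            for ti, tmask in enumerate(target_masks):
                out[lo:hi, li, ti] = sub[:, :, tmask].min(axis=(1, 2))
    return np.sqrt(out)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def _hysteresis_states(distances: np.ndarray, d_on: float, d_off: float
                       ) -> np.ndarray:
    """Vectorized bound/unbound state per frame for one distance series.

    State is 1 (bound) after crossing below d_on, until the first frame
    strictly above d_off. Initial state is unbound: frames within
    (d_on, d_off] before any d_on crossing are not contacts.
    """
    signal = np.zeros(distances.shape, dtype=np.int8)
    signal[distances < d_on] = 1
    signal[distances > d_off] = -1
    # forward-fill the last nonzero signal; 0 before any signal
    idx = np.arange(len(signal))
    has = signal != 0
    last = np.maximum.accumulate(np.where(has, idx, -1))
    filled = np.where(last >= 0, signal[np.clip(last, 0, None)], 0)
    return (filled == 1)


def detect_contacts(
    distances: np.ndarray,
    spec: ContactSpec,
    lipid_ids: Sequence[str],
    target_ids: Sequence[str],
    dt: float,
) -> list[ContactEvent]:
    """Run the dual-cutoff automaton over a ``(F, L, T)`` distance array.

    ``dt`` is the frame spacing in ns; durations count inclusive frames
    times ``dt``. Events reaching the final frame are flagged censored.
    """
    n_frames, n_lipids, n_targets = distances.shape
    if len(lipid_ids) != n_lipids or len(target_ids) != n_targets:
        raise ContactKineticsError("id lists must match distance array shape")
    events: list[ContactEvent] = []
    for li in range(n_lipids):
        for ti in range(n_targets):
            bound = _hysteresis_states(distances[:, li, ti], spec.d_on, spec.d_off)
            if not bound.any():
                continue
            edges = np.diff(bound.astype(np.int8))
            starts = np.flatnonzero(edges == 1) + 1
            ends = np.flatnonzero(edges == -1)
            if bound[0]:
                starts = np.concatenate([[0], starts])
            censored_last = bound[-1]
            if censored_last:
                ends = np.concatenate([ends, [n_frames - 1]])
            for k, (s, e) in enumerate(zip(starts, ends)):
                events.append(ContactEvent(
                    lipid_id=str(lipid_ids[li]),
                    target_id=str(target_ids[ti]),
                    start_frame=int(s),
                    end_frame=int(e),
                    duration=float((e - s + 1) * dt),
                    censored=bool(censored_last and k == len(starts) - 1),
                ))
    return events


def contacts_from_frames(
    meta: ParticleMeta,
    frames: FrameSeries,
    spec: ContactSpec,
    lipid_headgroup_indices: np.ndarray,
    protein_indices: np.ndarray,
    sites: Mapping[str, Sequence[int]] | None = None,
) -> list[ContactEvent]:
    """Convenience pipeline: distances then detection for one replicate."""
    lipid_ids, lipid_groups = group_lipids(meta, lipid_headgroup_indices)
    target_ids, target_groups = build_targets(
        meta, protein_indices, spec.grouping, sites)
    distances = min_distance_series(frames, lipid_groups, target_groups)
    dt = frames.dt if frames.n_frames > 1 else 1.0
    return detect_contacts(distances, spec, lipid_ids, target_ids, dt)


# ---------------------------------------------------------------------------
# survival curves and k_off fitting
# ---------------------------------------------------------------------------

def survival_curve(
    durations: Sequence[float],
    max_lag: float | None = None,
    n_points: int = 101,
) -> SurvivalCurve:
    """Empirical survival sigma(t) = fraction of durations >= t on a grid.

    The grid is uniform from 0 to ``max_lag`` (default: the longest
    duration) with ``n_points`` points.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ContactKineticsError("cannot build a survival curve from no events")
    if np.any(durations <= 0):
        raise ContactKineticsError("all durations must be > 0")
    if max_lag is None:
        max_lag = float(durations.max())
    times = np.linspace(0.0, max_lag, n_points)
    sigma = (durations[None, :] >= times[:, None]).mean(axis=1)
    sigma[0] = 1.0  # sigma(0) is 1 by definition (durations > 0)
    return SurvivalCurve(times=times, sigma=sigma, n_events=int(durations.size))


def _biexp(t, a, k_fast, k_slow):
    return a * np.exp(-k_fast * t) + (1.0 - a) * np.exp(-k_slow * t)


def fit_koff(curve: SurvivalCurve) -> KineticFit:
    """Fit sigma(t) with A*exp(-k_fast t) + (1-A)*exp(-k_slow t).

    Bounds: A in [0, 1], rates > 0; the slower fitted rate is reported as
    ``k_slow`` (= k_off) and the faster as ``k_fast``, swapping if the
    optimizer crosses. On optimizer failure a mono-exponential fallback is
    fitted and ``converged`` is False; no exception is raised for fit
    trouble, only for unusable input.
    """
    usable = curve.sigma > 0
    if usable.sum() < 5:
        raise ContactKineticsError(
            f"need >= 5 grid points with sigma > 0, got {int(usable.sum())}")
    t = curve.times
    y = curve.sigma
    # mean duration estimated from the area under the survival curve
    mean_dur = max(float(np.trapezoid(y, t)), 1e-9)
    p0 = (0.8, 10.0 / mean_dur, 1.0 / mean_dur)
    eps = 1e-12
    try:
        popt, _ = curve_fit(
            _biexp, t, y, p0=p0,
            bounds=([0.0, eps, eps], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
        a, k1, k2 = popt
        if k1 < k2:  # enforce k_fast >= k_slow by relabeling
            k1, k2 = k2, k1
            a = 1.0 - a
        if 1.0 - a < AMPLITUDE_FLOOR:
            # slow component carries negligible mass: the data are
            # effectively mono-exponential at the dominant rate
            k2 = k1
        resid = y - _biexp(t, a, k1, k2)
        return KineticFit(
            amplitude_fast=float(a), k_fast=float(k1), k_slow=float(k2),
            ssr=float((resid ** 2).sum()), n_events=curve.n_events,
            converged=True)
    except RuntimeError:
        logger.warning("bi-exponential fit failed; reporting mono-exponential")
        try:
            popt, _ = curve_fit(
                lambda tt, k: np.exp(-k * tt), t, y,
                p0=(1.0 / mean_dur,), bounds=(eps, np.inf), maxfev=20000)
            k = float(popt[0])
        except RuntimeError:
            k = 1.0 / mean_dur
        resid = y - np.exp(-k * t)
        return KineticFit(
            amplitude_fast=0.0, k_fast=k, k_slow=k,
            ssr=float((resid ** 2).sum()), n_events=curve.n_events,
            converged=False)


def residence_time_from_durations(
    durations: Sequence[float],
    n_points: int = 101,
) -> tuple[float, KineticFit | None]:
    """Pooled durations -> survival curve -> bi-exponential residence time.

    Fewer than :data:`MIN_EVENTS_FOR_FIT` events: returns the mean
    duration with ``fit=None`` (flagged fallback, matching the per-residue
    profile contract).
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        return 0.0, None
    if durations.size < MIN_EVENTS_FOR_FIT:
        return float(durations.mean()), None
    curve = survival_curve(durations, n_points=n_points)
    if int((curve.sigma > 0).sum()) < 5:
        return float(durations.mean()), None
    fit = fit_koff(curve)
    return fit.residence_time, fit


def residue_profile(
    events: Iterable[ContactEvent],
    n_frames: int,
    target_ids: Sequence[str] | None = None,
) -> ResidueInteractionProfile:
    """Aggregate events into per-target residence time/occupancy/counts.

    Durations are pooled across lipids (and replicates, if the caller
    pooled events) before fitting. Targets with no events report zeros;
    targets with < 10 events report the mean duration, flagged via
    ``from_fit=False``.
    """
    events = list(events)
    by_target: dict[str, list[ContactEvent]] = {}
    for ev in events:
        by_target.setdefault(ev.target_id, []).append(ev)
    if target_ids is None:
        target_ids = sorted(by_target)
    residence = np.zeros(len(target_ids))
    occupancy = np.zeros(len(target_ids))
    counts = np.zeros(len(target_ids), dtype=int)
    from_fit = np.zeros(len(target_ids), dtype=bool)
    fits: dict[str, KineticFit] = {}
    for i, tid in enumerate(target_ids):
        evs = by_target.get(str(tid), [])
        counts[i] = len(evs)
        if not evs:
            continue
        covered = np.zeros(n_frames, dtype=bool)
        for ev in evs:
            covered[ev.start_frame: ev.end_frame + 1] = True
        occupancy[i] = covered.mean()
        res, fit = residence_time_from_durations([ev.duration for ev in evs])
        residence[i] = res
        if fit is not None:
            from_fit[i] = True
            fits[str(tid)] = fit
    return ResidueInteractionProfile(
        target_ids=[str(t) for t in target_ids],
        residence_times=residence,
        occupancy=occupancy,
        event_counts=counts,
        from_fit=from_fit,
        fits=fits,
    )
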