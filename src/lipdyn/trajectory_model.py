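"""Data model and I/O for topologies, trajectories, and particle selections.

Internal unit conventions, applied at the I/O boundary and nowhere else:

* lengths in **nm** (PDB Angstrom coordinates are divided by 10 on read,
  multiplied by 10 on write),
* times in **ns**,
* frames 0-based, residue ids preserve the author numbering of the input file,
* periodic boxes must be orthorhombic; triclinic input is rejected.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: residue names treated as protein (three-letter amino acids plus common
#: protonation variants); everything else is classified via the species map.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP ASH GLH LYN CYX CYM ACE NME NMA
    """.split()
)

CATEGORY_PROTEIN = "protein"
CATEGORY_LIPID = "lipid"
CATEGORY_OTHER = "other"

ANGSTROM_PER_NM = 10.0
PS_PER_NS = 1000.0

_BOX_ANGLE_TOL = 1e-3


class TrajectoryModelError(ValueError):
    """Structured error for topology/trajectory/selection problems."""


class ParticleCountMismatch(TrajectoryModelError):
    def __init__(self, topology_count: int, trajectory_count: int):
        self.topology_count = topology_count
        self.trajectory_count = trajectory_count
        super().__init__(
            f"trajectory particle count ({trajectory_count}) does not match "
            f"topology particle count ({topology_count})"
        )


class EmptySelectionError(TrajectoryModelError):
    def __init__(self, expression: str):
        self.expression = expression
        super().__init__(f"selection resolved to no particles: {expression!r}")


class TriclinicBoxError(TrajectoryModelError):
    pass


@dataclass(frozen=True)
class ParticleMeta:
    """Per-particle metadata for one system.

    All arrays are aligned: entry ``i`` describes particle ``i`` (0-based,
    contiguous). ``category`` is one of ``{"protein", "lipid", "other"}``;
    ``species`` is a lipid species label ("GM3", "PIP2", ...) and is empty
    for non-lipids. A ``(segment_id, residue_id)`` pair identifies exactly
    one molecule-residue.
    """

    residue_ids: np.ndarray  # int, author numbering
    residue_names: np.ndarray  # str
    segment_ids: np.ndarray  # str
    particle_names: np.ndarray  # str (bead or atom name)
    categories: np.ndarray  # str in {protein, lipid, other}
    species: np.ndarray  # str, "" for non-lipids

    def __post_init__(self) -> None:
        n = len(self.residue_ids)
        for name in ("residue_names", "segment_ids", "particle_names",
                     "categories", "species"):
            if len(getattr(self, name)) != n:
                raise TrajectoryModelError(f"{name} length != {n}")
        bad = set(np.unique(self.categories)) - {
            CATEGORY_PROTEIN, CATEGORY_LIPID, CATEGORY_OTHER}
        if bad:
            raise TrajectoryModelError(f"unknown categories: {sorted(bad)}")
        lipid = self.categories == CATEGORY_LIPID
        if np.any(lipid & (self.species == "")):
            raise TrajectoryModelError("lipid particles must carry a species label")

    @property
    def n_particles(self) -> int:
        return len(self.residue_ids)

    def molecule_keys(self) -> np.ndarray:
        """``(segment_id, residue_id)`` key per particle, as structured strings."""
        return np.char.add(
            np.char.add(self.segment_ids.astype(str), "/"),
            self.residue_ids.astype(str),
        )


@dataclass(frozen=True)
class FrameSeries:
    """Per-frame coordinates, box, and times for one trajectory replicate.

    ``coordinates`` has shape ``(n_frames, n_particles, 3)`` in nm;
    ``box`` has shape ``(n_frames, 3)`` (orthorhombic edge lengths, nm);
    ``times`` are ns, strictly increasing.
    """

    times: np.ndarray
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryModelError("coordinates must have shape (F, N, 3)")
        f = self.coordinates.shape[0]
        if f < 1:
            raise TrajectoryModelError("need at least one frame")
        if self.times.shape != (f,):
            raise TrajectoryModelError("times length must equal n_frames")
        if self.box.shape != (f, 3):
            raise TrajectoryModelError("box must have shape (F, 3)")
        if np.any(self.box <= 0):
            raise TrajectoryModelError("all box lengths must be > 0")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryModelError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (mean spacing; single-frame series report 0)."""
        if self.n_frames < 2:
            return 0.0
        return float((self.times[-1] - self.times[0]) / (self.n_frames - 1))


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<word>[^\s()]+)
    )""",
    re.VERBOSE,
)


def _tokenize(expression: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            break
        if m.group("lparen"):
            tokens.append("(")
        elif m.group("rparen"):
            tokens.append(")")
        else:
            tokens.append(m.group("word"))
        pos = m.end()
    return tokens


_FIELD_KEYWORDS = {
    "residue_id", "residue_name", "segment_id", "particle_name",
    "category", "species",
}


class _SelectionParser:
    """Recursive-descent parser for the small selection grammar.

    Grammar (values are comma-separated alternatives; ranges ``a-b`` are
    inclusive of both endpoints and only valid for ``residue_id``)::

        expr     := or_expr
        or_expr  := and_expr ('or' and_expr)*
        and_expr := not_expr ('and' not_expr)*
        not_expr := 'not' not_expr | '(' expr ')' | predicate | 'all'
        predicate := FIELD value (',' value)*
    """

    def __init__(self, tokens: list[str], meta: ParticleMeta):
        self.tokens = tokens
        self.pos = 0
        self.meta = meta

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise TrajectoryModelError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise TrajectoryModelError(
                f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() == "and":
            self.take()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.not_expr()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise TrajectoryModelError("unbalanced parenthesis in selection")
            return mask
        if tok == "all":
            self.take()
            return np.ones(self.meta.n_particles, dtype=bool)
        return self.predicate()

    def predicate(self) -> np.ndarray:
        fld = self.take()
        if fld not in _FIELD_KEYWORDS:
            raise TrajectoryModelError(f"unknown selection field: {fld!r}")
        values: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in {"and", "or", "not", ")", "("}:
                break
            values.extend(v for v in self.take().split(",") if v)
        if not values:
            raise TrajectoryModelError(f"field {fld!r} given without values")
        return self._match(fld, values)

    def _match(self, fld: str, values: list[str]) -> np.ndarray:
        meta = self.meta
        if fld == "residue_id":
            mask = np.zeros(meta.n_particles, dtype=bool)
            rid = meta.residue_ids
            for v in values:
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    if lo > hi:
                        raise TrajectoryModelError(f"bad residue range {v!r}")
                    mask |= (rid >= lo) & (rid <= hi)
                else:
                    mask |= rid == int(v)
            return mask
        column = {
            "residue_name": meta.residue_names,
            "segment_id": meta.segment_ids,
            "particle_name": meta.particle_names,
            "category": meta.categories,
            "species": meta.species,
        }[fld]
        return np.isin(column, values)


@dataclass
class SelectionSpec:
    """A selection expression plus its resolved particle indices.

    Resolution against a :class:`ParticleMeta` is deterministic; the
    resolved set is cached in ``resolved_indices`` after the first call.
    """

    expression: str
    resolved_indices: frozenset[int] | None = field(default=None)

    def resolve(self, meta: ParticleMeta) -> np.ndarray:
        idx = resolve_selection(meta, self)
        self.resolved_indices = frozenset(int(i) for i in idx)
        return idx


def resolve_selection(meta: ParticleMeta, spec: SelectionSpec | str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of particle indices.

    Raises :class:`EmptySelectionError` when no particle matches — downstream
    analyses are meaningless on empty selections, so silence is not an option.
    """
    expression = spec.expression if isinstance(spec, SelectionSpec) else spec
    tokens = _tokenize(expression)
    if not tokens:
        raise TrajectoryModelError("empty selection expression")
    mask = _SelectionParser(tokens, meta).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(expression)
    return idx


# ---------------------------------------------------------------------------
# system loading (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions: np.ndarray, where: str) -> None:
    angles = np.asarray(dimensions[3:6], dtype=float)
    if np.any(np.abs(angles - 90.0) > _BOX_ANGLE_TOL):
        raise TriclinicBoxError(
            f"{where}: box angles {angles} deg — only orthorhombic boxes "
            "are supported"
        )


def _categorize(
    residue_names: np.ndarray,
    species_map: Mapping[str, tuple[str, Sequence[str]]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    species_map = species_map or {}
    categories = np.empty(len(residue_names), dtype=object)
    species = np.empty(len(residue_names), dtype=object)
    unknown: set[str] = set()
    for i, rname in enumerate(residue_names):
        if rname in species_map:
            categories[i] = CATEGORY_LIPID
            species[i] = str(species_map[rname][0])
        elif rname in PROTEIN_RESNAMES:
            categories[i] = CATEGORY_PROTEIN
            species[i] = ""
        else:
            categories[i] = CATEGORY_OTHER
            species[i] = ""
            unknown.add(str(rname))
    if unknown:
        logger.warning(
            "residue names not in species map and not protein, "
            "categorized as 'other': %s", sorted(unknown))
    return categories.astype(str), species.astype(str)


def load_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    species_map: Mapping[str, tuple[str, Sequence[str]]] | None = None,
) -> tuple[ParticleMeta, FrameSeries]:
    """Load a PDB/GRO topology and optional XTC/TRR/DCD trajectory.

    Parameters
    ----------
    topology_path
        PDB or GRO file supplying names, residues, and (if no trajectory)
        the single frame of coordinates.
    trajectory_path
        Optional trajectory whose particle count must match the topology.
    species_map
        Mapping ``residue_name -> (species_label, headgroup particle names)``.
        Residues present here are categorized as lipids; unknown, non-protein
        residue names fall back to ``other`` with a logged warning.

    Returns
    -------
    (ParticleMeta, FrameSeries)
        Coordinates in nm and times in ns regardless of the source format.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            universe = mda.Universe(str(topology_path))
        else:
            trajectory_path = Path(trajectory_path)
            try:
                universe = mda.Universe(str(topology_path), str(trajectory_path))
            except (OSError, ValueError) as exc:
                topo_only = mda.Universe(str(topology_path))
                n_topo = topo_only.atoms.n_atoms
                numbers = [int(n) for n in re.findall(r"\b(\d+)\b", str(exc))]
                n_traj = next((n for n in numbers if n != n_topo), -1)
                raise ParticleCountMismatch(n_topo, n_traj) from exc

    atoms = universe.atoms
    residue_names = atoms.resnames.astype(str)
    categories, species = _categorize(residue_names, species_map)
    try:
        segids = atoms.segids.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        segids = np.full(atoms.n_atoms, "SYSTEM", dtype=str)
    meta = ParticleMeta(
        residue_ids=atoms.resids.astype(int),
        residue_names=residue_names,
        segment_ids=segids,
        particle_names=atoms.names.astype(str),
        categories=categories,
        species=species,
    )

    n_frames = len(universe.trajectory)
    coords = np.empty((n_frames, atoms.n_atoms, 3), dtype=float)
    box = np.empty((n_frames, 3), dtype=float)
    times = np.empty(n_frames, dtype=float)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Reader has no dt information",
            category=UserWarning)
        for i, ts in enumerate(universe.trajectory):
            if ts.dimensions is None or np.all(ts.dimensions[:3] == 0):
                # topology files without a box: synthesize a generous box so
                # the FrameSeries invariant (box > 0) holds; flagged in the log
                span = atoms.positions.max(axis=0) - atoms.positions.min(axis=0)
                dims = np.concatenate([span + 100.0, [90.0, 90.0, 90.0]])
                logger.warning(
                    "no box in %s; using bounding box + 10 nm", topology_path)
            else:
                dims = np.asarray(ts.dimensions, dtype=float)
            _check_orthorhombic(dims, f"frame {i}")
            coords[i] = atoms.positions / ANGSTROM_PER_NM
            box[i] = dims[:3] / ANGSTROM_PER_NM
            times[i] = ts.time / PS_PER_NS
    if n_frames > 1 and np.all(times == times[0]):
        times = np.arange(n_frames, dtype=float)  # reader gave no times
    frames = FrameSeries(times=times, coordinates=coords, box=box)
    return meta, frames


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_residue_scalar_pdb(
    meta: ParticleMeta,
    coordinates: np.ndarray,
    values: Mapping[int, float],
    out_path: str | Path,
    box: np.ndarray | None = None,
) -> Path:
    """Write one frame as PDB with per-residue scalars in the B-factor column.

    Values are linearly rescaled to ``[0, 99.99]`` (the printable B-factor
    range); residues absent from ``values`` get 0.00. Intended for mapping
    per-residue residence times onto a structure for surface coloring.
    """
    import MDAnalysis as mda

    vals = np.asarray(list(values.values()), dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise TrajectoryModelError("non-finite residue values cannot be mapped")
    known = {int(k) for k in values}
    missing = known - set(int(r) for r in meta.residue_ids)
    if missing:
        raise TrajectoryModelError(
            f"values keyed by residue_ids absent from the system: {sorted(missing)}")

    if vals.size and vals.max() > vals.min():
        lo, hi = vals.min(), vals.max()
        scaled = {k: (float(v) - lo) / (hi - lo) * 99.99 for k, v in values.items()}
    else:
        scaled = {k: 0.0 for k in values}

    bfactors = np.array(
        [scaled.get(int(rid), 0.0) for rid in meta.residue_ids], dtype=float)

    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (meta.n_particles, 3):
        raise TrajectoryModelError(
            f"expected one frame of shape ({meta.n_particles}, 3), "
            f"got {coordinates.shape}")

    universe = mda.Universe.empty(
        n_atoms=meta.n_particles,
        n_residues=len(np.unique(meta.molecule_keys())),
        atom_resindex=_residue_indices(meta),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", meta.particle_names)
    universe.add_TopologyAttr("resids", _per_residue(meta, meta.residue_ids))
    universe.add_TopologyAttr("resnames", _per_residue(meta, meta.residue_names))
    universe.add_TopologyAttr("tempfactors", bfactors)
    universe.atoms.positions = coordinates * ANGSTROM_PER_NM
    if box is not None:
        universe.dimensions = np.concatenate(
            [np.asarray(box, dtype=float) * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]])
    out_path = Path(out_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe.atoms.write(str(out_path))
    return out_path


def _residue_indices(meta: ParticleMeta) -> np.ndarray:
    keys = meta.molecule_keys()
    _, first = np.unique(keys, return_index=True)
    order = {keys[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([order[k] for k in keys], dtype=int)


def _per_residue(meta: ParticleMeta, column: np.ndarray) -> np.ndarray:
    keys = meta.molecule_keys()
    resindex = _residue_indices(meta)
    out = np.empty(resindex.max() + 1, dtype=column.dtype)
    out[resindex] = column
    return out


def write_gro_xtc(
    meta: ParticleMeta,
    frames: FrameSeries,
    gro_path: str | Path,
    xtc_path: str | Path | None = None,
) -> None:
    """Write a generated system as GRO (frame 0) plus optional XTC trajectory."""
    import MDAnalysis as mda

    universe = mda.Universe.empty(
        n_atoms=meta.n_particles,
        n_residues=len(np.unique(meta.molecule_keys())),
        atom_resindex=_residue_indices(meta),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", meta.particle_names)
    universe.add_TopologyAttr("resids", _per_residue(meta, meta.residue_ids))
    universe.add_TopologyAttr("resnames", _per_residue(meta, meta.residue_names))
    universe.atoms.positions = frames.coordinates[0] * ANGSTROM_PER_NM
    universe.dimensions = np.concatenate(
        [frames.box[0] * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe.atoms.write(str(gro_path))
        if xtc_path is not None:
            with mda.Writer(str(xtc_path), meta.n_particles) as writer:
                for f in range(frames.n_frames):
                    universe.atoms.positions = frames.coordinates[f] * ANGSTROM_PER_NM
                    universe.dimensions = np.concatenate(
                        [frames.box[f] * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]])
                    universe.trajectory.ts.time = frames.times[f] * PS_PER_NS
                    universe.trajectory.ts.frame = f
                    writer.write(universe.atoms)
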