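"""Molecular data model and structure/trajectory I/O.

The package keeps a deliberately small in-memory model,
:class:`MolecularSystem`: a flat atom table, an author-numbered residue
table, a mapping of *entities* (receptor, individual glycan chains,
ligand chains) to residues, and a stack of coordinate frames with
orthorhombic periodic boxes.  All downstream analyses consume only this
model.

Units are GROMACS conventions throughout: lengths in nm (PDB Angstrom
converted on read), times in ns.  File parsing and writing is delegated
to MDAnalysis; this module only translates between MDAnalysis objects
and the data model and never re-implements a format.
"""

from __future__ import annotations

import fnmatch
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    FormatError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "MolecularSystem",
    "Selection",
    "load_structure",
    "load_trajectory",
    "write_system",
    "resolve",
    "load_vdw_radii",
    "parse_entity_map",
]

#: Angstrom per nm, the only unit conversion in the package.
ANGSTROM_PER_NM = 10.0

_RADII_CACHE: dict[str, float] | None = None


def load_vdw_radii() -> dict[str, float]:
    """Return the bundled element → van der Waals radius (nm) table."""
    global _RADII_CACHE
    if _RADII_CACHE is None:
        table: dict[str, float] = {}
        text = (
            resources.files("glycocover").joinpath("data/vdw_radii_bondi.tsv").read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("element"):
                continue
            element, radius = line.split("\t")
            table[element.upper()] = float(radius)
        _RADII_CACHE = table
    return dict(_RADII_CACHE)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class MolecularSystem:
    """Topology plus zero or more coordinate frames.

    Parameters
    ----------
    atom_names, elements, vdw_radii
        Per-atom arrays (radii in nm; NaN when the element is unknown).
    atom_resindex
        For each atom, the index into the residue table.
    residue_ids
        Author-assigned residue numbers (never re-indexed from zero).
    residue_names
        Per-residue names.
    entities
        Mapping from entity label (``"receptor"``, ``"glycan_N25"``,
        ``"ligand_HA6_1"`` ...) to an array of residue_ids.  Every residue
        belongs to exactly one entity.
    frames
        ``(n_frames, n_atoms, 3)`` coordinates in nm.
    boxes
        ``(n_frames, 3)`` orthorhombic box lengths in nm, or ``None`` for
        non-periodic analysis.
    time_per_frame
        Sampling interval in ns.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    vdw_radii: np.ndarray
    atom_resindex: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    entities: dict[str, np.ndarray]
    frames: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0, 3), dtype=float)
    )
    boxes: np.ndarray | None = None
    time_per_frame: float = 0.1

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=np.intp)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.entities = {k: np.asarray(v, dtype=np.int64) for k, v in self.entities.items()}
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:  # a single frame is allowed as (n_atoms, 3)
            self.frames = self.frames[None]
        if self.boxes is not None:
            self.boxes = np.atleast_2d(np.asarray(self.boxes, dtype=float))
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        n_atoms = len(self.atom_names)
        if not (len(self.elements) == len(self.vdw_radii) == len(self.atom_resindex) == n_atoms):
            raise ConfigurationError("atom table columns have inconsistent lengths")
        if self.atom_resindex.size and (
            self.atom_resindex.min() < 0 or self.atom_resindex.max() >= len(self.residue_ids)
        ):
            raise ConfigurationError("atom_resindex points outside the residue table")
        if len(np.unique(self.residue_ids)) != len(self.residue_ids):
            raise ConfigurationError("duplicate residue_ids in the residue table")
        seen: dict[int, str] = {}
        for label, rids in self.entities.items():
            for rid in rids.tolist():
                if rid in seen:
                    raise ConfigurationError(
                        f"residue {rid} assigned to both entities "
                        f"{seen[rid]!r} and {label!r}"
                    )
                seen[rid] = label
        known = set(self.residue_ids.tolist())
        for label, rids in self.entities.items():
            missing = sorted(set(rids.tolist()) - known)
            if missing:
                raise ConfigurationError(
                    f"entity {label!r} references unknown residues {missing}"
                )
        unassigned = known - set(seen)
        if unassigned:
            raise ConfigurationError(
                f"residues not assigned to any entity: {sorted(unassigned)} "
                "(add them to the entity map or use an explicit 'unassigned' entity)"
            )
        if self.frames.size and self.frames.shape[1] != n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms but the topology has {n_atoms}"
            )
        if self.boxes is not None:
            if len(self.boxes) != len(self.frames):
                raise ConfigurationError("one box per frame required")
            if np.any(self.boxes <= 0):
                raise ConfigurationError("periodic box lengths must be strictly positive")

    # -- convenience --------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def periodic(self) -> bool:
        return self.boxes is not None

    def residue_id_of_atoms(self) -> np.ndarray:
        """Author residue id for every atom."""
        return self.residue_ids[self.atom_resindex]

    def entity_of_residues(self) -> dict[int, str]:
        return {
            int(rid): label for label, rids in self.entities.items() for rid in rids
        }

    def atoms_of_residue_ids(self, rids) -> np.ndarray:
        """Atom indices belonging to the given author residue ids, in atom order."""
        rids = np.asarray(rids, dtype=np.int64)
        mask = np.isin(self.residue_id_of_atoms(), rids)
        return np.nonzero(mask)[0]

    def with_frames(self, frames: np.ndarray, boxes: np.ndarray | None,
                    time_per_frame: float | None = None) -> "MolecularSystem":
        """A copy of the topology carrying different coordinate frames."""
        return MolecularSystem(
            atom_names=self.atom_names,
            elements=self.elements,
            vdw_radii=self.vdw_radii,
            atom_resindex=self.atom_resindex,
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            entities={k: v.copy() for k, v in self.entities.items()},
            frames=frames,
            boxes=boxes,
            time_per_frame=self.time_per_frame if time_per_frame is None else time_per_frame,
        )


# ---------------------------------------------------------------------------
# entity maps
# ---------------------------------------------------------------------------


def _parse_residue_spec(spec) -> list[int]:
    """``"20-169"``, ``"20-30,40"``, ``41``, or a list of those → residue ids."""
    if isinstance(spec, (int, np.integer)):
        return [int(spec)]
    if isinstance(spec, str):
        out: list[int] = []
        for token in spec.replace(" ", "").split(","):
            if not token:
                continue
            if "-" in token[1:]:  # allow negative ids, split on interior dash
                lo, hi = token.rsplit("-", 1) if not token.startswith("-") else (token, "")
                try:
                    lo_i, hi_i = int(lo), int(hi)
                except ValueError as exc:
                    raise ConfigurationError(f"bad residue range {token!r}") from exc
                if hi_i < lo_i:
                    raise ConfigurationError(f"empty residue range {token!r}")
                out.extend(range(lo_i, hi_i + 1))
            else:
                try:
                    out.append(int(token))
                except ValueError as exc:
                    raise ConfigurationError(f"bad residue token {token!r}") from exc
        return out
    if isinstance(spec, (list, tuple)):
        out = []
        for item in spec:
            out.extend(_parse_residue_spec(item))
        return out
    raise ConfigurationError(f"cannot interpret residue specification {spec!r}")


def parse_entity_map(entity_map: dict) -> dict[str, np.ndarray]:
    """Normalise a user entity map (label → residue ranges) to id arrays."""
    out: dict[str, np.ndarray] = {}
    for label, spec in entity_map.items():
        rids = np.array(sorted(set(_parse_residue_spec(spec))), dtype=np.int64)
        if rids.size == 0:
            raise ConfigurationError(f"entity {label!r} resolves to no residues")
        out[str(label)] = rids
    return out


# ---------------------------------------------------------------------------
# file I/O (via MDAnalysis)
# ---------------------------------------------------------------------------


def _import_mda():
    import MDAnalysis as mda  # deferred: heavy import

    return mda


def _universe_to_system(u, entity_map: dict, allow_unassigned: bool,
                        time_per_frame: float) -> MolecularSystem:
    atoms = u.atoms
    radii_table = load_vdw_radii()
    try:
        elements = [str(e).upper() for e in atoms.elements]
    except Exception:
        # fall back to a guess from atom names (common PDB practice)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from MDAnalysis.topology.guessers import guess_types

            elements = [str(e).upper() for e in guess_types(atoms.names)]
    radii = np.array([radii_table.get(e, np.nan) for e in elements])

    res = u.residues
    residue_ids = res.resids.astype(np.int64)
    residue_names = res.resnames.astype(object)
    atom_resindex = atoms.resindices.astype(np.intp)

    entities = parse_entity_map(entity_map)
    covered = set(np.concatenate(list(entities.values())).tolist()) if entities else set()
    leftover = sorted(set(residue_ids.tolist()) - covered)
    if leftover:
        if not allow_unassigned:
            raise ConfigurationError(
                f"entity map leaves residues unassigned: {leftover[:8]}"
                f"{'...' if len(leftover) > 8 else ''}; pass allow_unassigned=True "
                "to collect them under an 'unassigned' entity"
            )
        entities["unassigned"] = np.array(leftover, dtype=np.int64)

    frames = []
    boxes = []
    periodic = True
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float) / ANGSTROM_PER_NM)
        dims = ts.dimensions
        if dims is None or not np.all(np.asarray(dims[:3]) > 0):
            periodic = False
        else:
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise ConfigurationError(
                    "only orthorhombic periodic boxes are supported "
                    f"(got angles {tuple(dims[3:])})"
                )
            boxes.append(np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM)

    return MolecularSystem(
        atom_names=atoms.names.astype(object),
        elements=np.array(elements, dtype=object),
        vdw_radii=radii,
        atom_resindex=atom_resindex,
        residue_ids=residue_ids,
        residue_names=residue_names,
        entities=entities,
        frames=np.array(frames) if frames else np.empty((0, len(atoms), 3)),
        boxes=np.array(boxes) if periodic and boxes else None,
        time_per_frame=time_per_frame,
    )


def load_structure(path, format: str | None = None, entity_map: dict | None = None,
                   allow_unassigned: bool = False,
                   time_per_frame: float = 0.1) -> MolecularSystem:
    """Read a PDB or GRO file into a single-frame :class:`MolecularSystem`.

    PDB coordinates (Angstrom) are converted to nm on read; GRO files are
    already in nm.  ``entity_map`` maps entity labels to residue ranges
    (e.g. ``{"receptor": "20-169", "glycan_N25": [1001]}``) and must cover
    every residue unless ``allow_unassigned`` is set.
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"structure file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in {"PDB", "GRO"}:
        raise FormatError(f"unsupported structure format {fmt!r} (expected PDB or GRO)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises many types on parse failure
        raise FormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return _universe_to_system(
        u, entity_map or {}, allow_unassigned, time_per_frame
    )


def load_trajectory(path, system: MolecularSystem, format: str | None = None,
                    time_per_frame: float | None = None,
                    replace: bool = False) -> MolecularSystem:
    """Append frames from an XTC/DCD/multi-frame-PDB file to ``system``.

    Returns a new system; ``system`` itself is not modified.  The frame atom
    count must match the topology.  With ``replace=True`` the structure's own
    coordinate frame is dropped first, which is what trajectory analysis
    normally wants (the topology file is then coordinates-as-metadata only).
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in {"XTC", "DCD", "PDB"}:
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    u = mda.Universe.empty(system.n_atoms, trajectory=True)
    try:
        u.load_new(str(path), format=fmt)
    except ValueError as exc:
        raise TopologyError(
            f"trajectory {path} does not match the {system.n_atoms}-atom topology: {exc}"
        ) from exc
    except Exception as exc:
        raise FormatError(f"failed to read {path} as {fmt}: {exc}") from exc

    frames, boxes, times = [], [], []
    periodic = True
    try:
        for ts in u.trajectory:
            if ts.n_atoms != system.n_atoms:
                raise TopologyError(
                    f"frame {len(frames)} has {ts.n_atoms} atoms, topology has {system.n_atoms}"
                )
            frames.append(ts.positions.astype(float) / ANGSTROM_PER_NM)
            times.append(float(ts.time))  # ps in MDAnalysis
            dims = ts.dimensions
            if dims is None or not np.all(np.asarray(dims[:3]) > 0):
                periodic = False
            else:
                boxes.append(np.asarray(dims[:3], dtype=float) / ANGSTROM_PER_NM)
    except TopologyError:
        raise
    except Exception as exc:
        raise FormatError(
            f"truncated or corrupt trajectory {path}: last good frame index "
            f"{len(frames) - 1}: {exc}"
        ) from exc

    if time_per_frame is None:
        if len(times) >= 2 and times[1] > times[0]:
            time_per_frame = (times[1] - times[0]) / 1000.0  # ps → ns
        else:
            time_per_frame = system.time_per_frame

    new_frames = np.array(frames)
    new_boxes = np.array(boxes) if periodic and boxes else None
    if system.n_frames and not replace:
        all_frames = np.concatenate([system.frames, new_frames])
        if system.boxes is not None and new_boxes is not None:
            all_boxes = np.concatenate([system.boxes, new_boxes])
        else:
            all_boxes = None
    else:
        all_frames, all_boxes = new_frames, new_boxes
    return system.with_frames(all_frames, all_boxes, time_per_frame)


def _system_to_universe(system: MolecularSystem, frame: int | None = None):
    """Build an MDAnalysis Universe mirroring ``system`` (positions in Angstrom)."""
    mda = _import_mda()
    n_res = system.n_residues
    u = mda.Universe.empty(
        system.n_atoms,
        n_residues=n_res,
        atom_resindex=system.atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", system.atom_names.astype(str))
    u.add_TopologyAttr("elements", system.elements.astype(str))
    u.add_TopologyAttr("resids", system.residue_ids)
    u.add_TopologyAttr("resnames", system.residue_names.astype(str))
    if frame is not None and system.n_frames:
        u.atoms.positions = system.frames[frame] * ANGSTROM_PER_NM
        if system.boxes is not None:
            u.dimensions = np.concatenate(
                [system.boxes[frame] * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
            )
    return u


def write_system(system: MolecularSystem, structure_path, trajectory_path=None) -> None:
    """Write the first frame as GRO/PDB and, optionally, all frames as XTC/DCD.

    PDB output is written in Angstrom, GRO and XTC in nm, matching the
    formats' own conventions.
    """
    mda = _import_mda()
    u = _system_to_universe(system, frame=0 if system.n_frames else None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=system.n_atoms) as w:
                for i in range(system.n_frames):
                    u.atoms.positions = system.frames[i] * ANGSTROM_PER_NM
                    if system.boxes is not None:
                        u.dimensions = np.concatenate(
                            [system.boxes[i] * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]]
                        )
                    u.trajectory.ts.time = i * system.time_per_frame * 1000.0  # ns → ps
                    w.write(u.atoms)


def write_bfactor_pdb(system: MolecularSystem, values_by_residue: dict[int, float],
                      path, frame: int = 0) -> None:
    """Export per-residue values into the PDB B-factor column for rendering.

    Residues absent from ``values_by_residue`` get a B-factor of 0.
    """
    u = _system_to_universe(system, frame=frame)
    u.add_TopologyAttr("tempfactors", np.zeros(system.n_atoms))
    per_atom = np.array(
        [values_by_residue.get(int(rid), 0.0) for rid in system.residue_id_of_atoms()]
    )
    u.atoms.tempfactors = per_atom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Selection:
    """A selection expression over entity labels, residue ids, and atom names.

    Grammar (whitespace-separated, case-sensitive labels)::

        expr    := or_expr
        or_expr := and_expr ("or" and_expr)*
        and_expr:= unary ("and" unary)*
        unary   := "not" unary | "(" expr ")" | term
        term    := "entity" PATTERN+ | "resid" RANGE+ | "name" NAME+ | "all"

    ``PATTERN`` supports ``fnmatch`` wildcards (``glycan_*``); ``RANGE`` is
    an integer or ``lo-hi``.  Unresolvable tokens raise
    :class:`~glycocover.errors.SelectionError` rather than matching nothing.
    """

    expression: str

    def __str__(self) -> str:
        return self.expression


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    """Recursive-descent parser producing a per-atom boolean mask."""

    KEYWORDS = {"and", "or", "not", "(", ")", "entity", "resid", "name", "all"}

    def __init__(self, tokens: list[str], system: MolecularSystem):
        self.tokens = tokens
        self.pos = 0
        self.system = system
        self.atom_rids = system.residue_id_of_atoms()
        self.known_rids = set(system.residue_ids.tolist())

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.term()

    def _arguments(self) -> list[str]:
        args = []
        while self.peek() is not None and self.peek() not in self.KEYWORDS:
            args.append(self.take())
        if not args:
            raise SelectionError("selection keyword requires at least one argument")
        return args

    def term(self) -> np.ndarray:
        tok = self.take()
        n = self.system.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "entity":
            mask = np.zeros(n, dtype=bool)
            for pattern in self._arguments():
                labels = fnmatch.filter(self.system.entities.keys(), pattern)
                if not labels:
                    raise SelectionError(f"unknown entity {pattern!r}")
                rids = np.concatenate([self.system.entities[l] for l in labels])
                mask |= np.isin(self.atom_rids, rids)
            return mask
        if tok == "resid":
            rids: list[int] = []
            for token in self._arguments():
                parsed = _parse_residue_spec(token)
                missing = [r for r in parsed if r not in self.known_rids]
                if missing:
                    raise SelectionError(f"unknown residue id(s) {missing} in {token!r}")
                rids.extend(parsed)
            return np.isin(self.atom_rids, np.array(rids, dtype=np.int64))
        if tok == "name":
            names = set(self._arguments())
            present = set(self.system.atom_names.tolist())
            unknown = sorted(names - present)
            if unknown:
                raise SelectionError(f"unknown atom name(s) {unknown}")
            return np.isin(self.system.atom_names, list(names))
        raise SelectionError(f"unknown selection keyword {tok!r}")


def resolve(selection: Selection | str, system: MolecularSystem,
            allow_empty: bool = False) -> np.ndarray:
    """Resolve a selection to a sorted, duplicate-free array of atom indices."""
    expr = selection.expression if isinstance(selection, Selection) else str(selection)
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, system).parse()
    idx = np.nonzero(mask)[0]
    if idx.size == 0 and not allow_empty:
        raise SelectionError(f"selection {expr!r} resolves to no atoms")
    return idx
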