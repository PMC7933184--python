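"""Distance, contact, coverage, contact-map, and binding-event analysis.

The central primitive is the per-frame minimum distance between each
residue of a group and any atom of a target selection (the gmx-mindist
style quantity); everything else — contact fractions, averaged surface
distance maps, inter-entity contact counts, and association/dissociation
event detection — is derived from it.

Two distance backends are provided: an O(N*M) vectorised all-pairs path
and a KD-tree path (periodic boxes handled through the tree's toroidal
metric).  They agree to floating-point round-off; the brute-force path
doubles as the reference in the test suite.

Periodicity: minimum-image convention for orthorhombic boxes only;
triclinic boxes are rejected upstream at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError, ParameterError, SelectionError
from .system import MolecularSystem, Selection, resolve

__all__ = [
    "ResidueDistanceSeries",
    "ResidueCoverage",
    "ContactMatrix",
    "BindingEvent",
    "min_distance_per_residue",
    "contact_fraction",
    "pair_contact_counts",
    "surface_distance_map",
    "binding_events",
    "events_from_series",
]

#: default coverage cutoff in nm
COVERAGE_CUTOFF = 0.3
#: default inter-entity contact-count cutoff in nm
CONTACT_COUNT_CUTOFF = 0.6


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class ResidueDistanceSeries:
    """Per-frame minimum distance (nm) from each residue to a target selection."""

    residue_ids: np.ndarray          # (n_res,)
    distances: np.ndarray            # (n_frames, n_res), nm
    time_per_frame: float            # ns

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[1] != self.residue_ids.size:
            raise AnalysisError("distances must be (n_frames, n_residues)")
        if self.distances.size and self.distances.min() < 0:
            raise AnalysisError("negative distances are impossible")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]


@dataclass
class ResidueCoverage:
    """Fraction of frames each residue spends within ``cutoff`` of the target.

    This is the per-residue coverage C_res: the ratio of frames where the
    minimum distance from any atom of the residue to any atom of the target
    is strictly below the cutoff (default 0.3 nm).
    """

    residue_ids: np.ndarray
    coverage: np.ndarray
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.size and (self.coverage.min() < 0 or self.coverage.max() > 1):
            raise AnalysisError("coverage values must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(c) for r, c in zip(self.residue_ids, self.coverage)}


@dataclass
class ContactMatrix:
    """Mean atom-pair contact counts between entities (Fig. 2d-style map)."""

    labels: list[str]
    counts: np.ndarray               # (n_entities, n_entities)
    cutoff: float
    n_frames: int
    count_mode: str = "pairs"        # "pairs" (gmx mindist semantics) or "atoms"

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class BindingEvent:
    """One bound interval of a ligand on the receptor."""

    ligand: str
    start_frame: int
    end_frame: int                   # inclusive
    duration_ns: float

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise AnalysisError("binding event ends before it starts")


# ---------------------------------------------------------------------------
# distance backends
# ---------------------------------------------------------------------------


def _min_image_diff(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def _frame_min_dist_brute(group_xyz: np.ndarray, target_xyz: np.ndarray,
                          box: np.ndarray | None) -> np.ndarray:
    """Min distance from each group atom to the target set, one frame."""
    diff = group_xyz[:, None, :] - target_xyz[None, :, :]
    if box is not None:
        diff = _min_image_diff(diff, box)
    return np.sqrt((diff * diff).sum(axis=-1)).min(axis=1)


def _frame_min_dist_kdtree(group_xyz: np.ndarray, target_xyz: np.ndarray,
                           box: np.ndarray | None) -> np.ndarray:
    if box is None:
        tree = cKDTree(target_xyz)
        d, _ = tree.query(group_xyz)
        return d
    tree = cKDTree(np.mod(target_xyz, box), boxsize=box)
    d, _ = tree.query(np.mod(group_xyz, box))
    return d


def _pick_method(method: str, n_group: int, n_target: int) -> str:
    if method not in {"auto", "brute", "kdtree"}:
        raise ParameterError(f"unknown distance method {method!r}")
    if method != "auto":
        return method
    return "brute" if n_group * n_target <= 250_000 else "kdtree"


def _frames_range(system: MolecularSystem, frames) -> np.ndarray:
    if system.n_frames == 0:
        raise AnalysisError("system carries no coordinate frames")
    if frames is None:
        return np.arange(system.n_frames)
    idx = np.arange(system.n_frames)[frames]
    if np.size(idx) == 0:
        raise AnalysisError("empty frame range")
    return np.atleast_1d(idx)


def min_distance_per_residue(system: MolecularSystem,
                             group_residues: Selection | str,
                             target: Selection | str,
                             frames=None,
                             method: str = "auto") -> ResidueDistanceSeries:
    """Per-frame minimum distance from each residue of a group to a target.

    For every residue in ``group_residues`` and every frame, the minimum over
    all atom pairs (any atom of the residue × any atom of ``target``) is
    computed, with the minimum-image convention applied when the system has a
    periodic box.  The group and target selections must be disjoint: a shared
    atom would pin the distance at zero and corrupt any coverage built on it.
    """
    gidx = resolve(group_residues, system)
    tidx = resolve(target, system)
    if np.intersect1d(gidx, tidx).size:
        raise AnalysisError(
            "group and target selections overlap; self-distances of 0 would "
            "corrupt coverage statistics"
        )
    frame_idx = _frames_range(system, frames)
    meth = _pick_method(method, gidx.size, tidx.size)

    # order group atoms by residue so that per-residue mins are contiguous
    atom_rids = system.residue_id_of_atoms()[gidx]
    order = np.argsort(atom_rids, kind="stable")
    gidx = gidx[order]
    atom_rids = atom_rids[order]
    residue_ids, starts = np.unique(atom_rids, return_index=True)

    dist = np.empty((frame_idx.size, residue_ids.size))
    for i, f in enumerate(frame_idx):
        box = system.boxes[f] if system.boxes is not None else None
        xyz = system.frames[f]
        if meth == "brute":
            per_atom = _frame_min_dist_brute(xyz[gidx], xyz[tidx], box)
        else:
            per_atom = _frame_min_dist_kdtree(xyz[gidx], xyz[tidx], box)
        dist[i] = np.minimum.reduceat(per_atom, starts)
    return ResidueDistanceSeries(residue_ids, dist, system.time_per_frame)


# ---------------------------------------------------------------------------
# coverage and maps
# ---------------------------------------------------------------------------


def contact_fraction(series: ResidueDistanceSeries,
                     cutoff: float = COVERAGE_CUTOFF) -> ResidueCoverage:
    """Per-residue fraction of frames with min distance strictly below cutoff."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if series.n_frames == 0:
        raise AnalysisError("cannot compute a contact fraction over zero frames")
    frac = (series.distances < cutoff).mean(axis=0)
    return ResidueCoverage(series.residue_ids, frac, cutoff, series.n_frames)


def surface_distance_map(replica_systems: list[MolecularSystem],
                         group_residues: Selection | str,
                         target: Selection | str,
                         clamp: tuple[float, float] = (0.3, 1.5),
                         frames=None,
                         method: str = "auto"):
    """Replica-averaged per-residue mean minimum distance to a target.

    For each replica the per-residue min-distance series is time-averaged;
    replicas are then averaged with equal weight.  The returned DataFrame
    carries both the raw mean (nm) and a display column clamped to
    ``clamp`` — the convention used to colour receptor surfaces from bright
    (close, glycan-covered) to pale (distant, exposed).
    """
    import pandas as pd

    if not replica_systems:
        raise AnalysisError("at least one replica is required")
    lo, hi = clamp
    if hi <= lo:
        raise ParameterError("clamp ceiling must exceed clamp floor")
    per_replica = []
    rid_ref = None
    lengths = set()
    for sysm in replica_systems:
        series = min_distance_per_residue(sysm, group_residues, target,
                                          frames=frames, method=method)
        lengths.add(series.n_frames)
        if rid_ref is None:
            rid_ref = series.residue_ids
        elif not np.array_equal(rid_ref, series.residue_ids):
            raise AnalysisError("replicas resolve to different residue sets")
        per_replica.append(series.distances.mean(axis=0))
    if len(lengths) > 1:
        warnings.warn(
            "replicas have unequal frame counts; they are still weighted equally",
            stacklevel=2,
        )
    mean = np.mean(per_replica, axis=0)
    return pd.DataFrame(
        {
            "residue_id": rid_ref,
            "mean_min_distance_nm": mean,
            "clamped_nm": np.clip(mean, lo, hi),
        }
    )


# ---------------------------------------------------------------------------
# inter-entity contact counts
# ---------------------------------------------------------------------------


def _entity_atoms(system: MolecularSystem, label: str) -> np.ndarray:
    if label not in system.entities:
        raise SelectionError(f"unknown entity {label!r}")
    idx = system.atoms_of_residue_ids(system.entities[label])
    if idx.size == 0:
        raise SelectionError(f"entity {label!r} has no atoms")
    return idx


def _frame_pair_count(xa: np.ndarray, xb: np.ndarray, box: np.ndarray | None,
                      cutoff: float, count_mode: str) -> float:
    diff = xa[:, None, :] - xb[None, :, :]
    if box is not None:
        diff = _min_image_diff(diff, box)
    within = (diff * diff).sum(axis=-1) < cutoff * cutoff  # strict <
    if count_mode == "pairs":
        return float(within.sum())
    # "atoms": distinct atoms of either entity participating in any contact
    return float(within.any(axis=1).sum() + within.any(axis=0).sum())


def pair_contact_counts(systems: MolecularSystem | list[MolecularSystem],
                        entities: list[str],
                        cutoff: float = CONTACT_COUNT_CUTOFF,
                        frames=None,
                        count_mode: str = "pairs") -> ContactMatrix:
    """Mean number of inter-entity atom contacts per frame (Fig. 2d analogue).

    Entry (i, j) is the time-averaged number of atom pairs — one atom from
    entity i, one from entity j — closer than ``cutoff`` (default 0.6 nm,
    strict inequality).  With a list of replica systems, the replica means
    are averaged with equal weight.  ``count_mode="atoms"`` counts distinct
    participating atoms instead of pairs.
    """
    if count_mode not in {"pairs", "atoms"}:
        raise ParameterError(f"unknown count_mode {count_mode!r}")
    if len(entities) < 2:
        raise AnalysisError("need at least two entities for a contact map")
    replicas = systems if isinstance(systems, (list, tuple)) else [systems]
    if not replicas:
        raise AnalysisError("no systems given")

    n = len(entities)
    per_replica = []
    total_frames = 0
    for sysm in replicas:
        atom_idx = [_entity_atoms(sysm, lab) for lab in entities]
        frame_idx = _frames_range(sysm, frames)
        total_frames += frame_idx.size
        counts = np.zeros((n, n))
        for f in frame_idx:
            box = sysm.boxes[f] if sysm.boxes is not None else None
            xyz = sysm.frames[f]
            for i in range(n):
                for j in range(i + 1, n):
                    c = _frame_pair_count(xyz[atom_idx[i]], xyz[atom_idx[j]],
                                          box, cutoff, count_mode)
                    counts[i, j] += c
                    counts[j, i] += c
        per_replica.append(counts / frame_idx.size)
    return ContactMatrix(list(entities), np.mean(per_replica, axis=0),
                         cutoff, total_frames, count_mode)


# ---------------------------------------------------------------------------
# binding events
# ---------------------------------------------------------------------------


def _hysteresis_states(distances: np.ndarray, on_cutoff: float,
                       off_cutoff: float) -> np.ndarray:
    """Boolean bound/unbound state per frame under two-threshold hysteresis."""
    states = np.empty(distances.size, dtype=bool)
    bound = distances[0] < on_cutoff
    for i, d in enumerate(distances):
        if bound and d > off_cutoff:
            bound = False
        elif not bound and d < on_cutoff:
            bound = True
        states[i] = bound
    return states


def _runs(states: np.ndarray) -> list[list]:
    """Alternating [state, length] runs of a boolean sequence."""
    runs: list[list] = []
    for s in states:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([bool(s), 1])
    return runs


def _merge_short_runs(runs: list[list], min_frames: int) -> list[list]:
    """Merge runs shorter than ``min_frames`` into the surrounding state.

    Deterministic order: always merge the shortest offending run first
    (earliest on ties).  An interior short run is absorbed by its equal-state
    neighbours; an edge run flips into its single neighbour's state.
    """
    runs = [r[:] for r in runs]
    while len(runs) > 1:
        cands = [i for i, (_, ln) in enumerate(runs) if ln < min_frames]
        if not cands:
            break
        i = min(cands, key=lambda k: (runs[k][1], k))
        if 0 < i < len(runs) - 1:
            runs[i - 1][1] += runs[i][1] + runs[i + 1][1]
            del runs[i:i + 2]
        elif i == 0:
            runs[1][1] += runs[0][1]
            del runs[0]
        else:
            runs[i - 1][1] += runs[i][1]
            del runs[i]
    return runs


def events_from_series(distances: np.ndarray, time_per_frame: float,
                       ligand_label: str = "ligand",
                       on_cutoff: float = 0.3, off_cutoff: float = 0.5,
                       min_dwell: float = 1.0) -> list[BindingEvent]:
    """Detect bound episodes in a min-distance series (nm) by hysteresis.

    The bound state is entered when the distance drops below ``on_cutoff``
    and left when it rises above ``off_cutoff``; bound and unbound intervals
    shorter than ``min_dwell`` (ns) are merged into the surrounding state.
    """
    distances = np.asarray(distances, dtype=float)
    if off_cutoff < on_cutoff:
        raise ParameterError("off_cutoff must not be below on_cutoff")
    if min_dwell < 0:
        raise ParameterError("min_dwell must be non-negative")
    if distances.ndim != 1 or distances.size == 0:
        raise AnalysisError("distance series must be a non-empty 1-D array")
    total_ns = distances.size * time_per_frame
    if total_ns < min_dwell:
        raise AnalysisError(
            f"trajectory ({total_ns:g} ns) is shorter than min_dwell ({min_dwell:g} ns)"
        )
    states = _hysteresis_states(distances, on_cutoff, off_cutoff)
    # an interval of k frames spans k * dt ns; "shorter than min_dwell" in frames:
    min_frames = int(np.ceil(min_dwell / time_per_frame)) if min_dwell > 0 else 0
    runs = _merge_short_runs(_runs(states), min_frames)
    events = []
    start = 0
    for state, length in runs:
        if state:
            events.append(BindingEvent(ligand_label, start, start + length - 1,
                                       length * time_per_frame))
        start += length
    return events


def binding_events(system: MolecularSystem, ligand: Selection | str,
                   receptor: Selection | str,
                   on_cutoff: float = 0.3, off_cutoff: float = 0.5,
                   min_dwell: float = 1.0, frames=None,
                   method: str = "auto") -> list[BindingEvent]:
    """Association/dissociation events of a ligand selection on a receptor.

    The ligand's overall min distance to the receptor (min over its residues)
    is thresholded with hysteresis; see :func:`events_from_series`.
    """
    series = min_distance_per_residue(system, ligand, receptor,
                                      frames=frames, method=method)
    overall = series.distances.min(axis=1)
    label = str(ligand)
    return events_from_series(overall, system.time_per_frame, label,
                              on_cutoff, off_cutoff, min_dwell)
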