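"""Solvent-accessible surface areas and buried-interface areas.

SASA is computed with the Shrake–Rupley sphere-sampling algorithm, written
here from first principles: each atom's van der Waals sphere is expanded by
the probe radius (0.14 nm water probe by default), quasi-uniform test
points are placed on the expanded sphere with a deterministic golden-section
spiral (seedless, so results are bit-stable), and a point is accessible if
it lies outside every other expanded sphere.  The per-atom area is the
accessible fraction of 4*pi*(r+probe)^2.

Buried interface between two molecular parts A and B is measured the usual
way: (SASA(A alone) + SASA(B alone) - SASA(A and B together)) / 2, with the
un-halved "total buried" available by flag since both conventions exist in
the literature.  Waters and ions are expected to be excluded by selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError, ConfigurationError, ParameterError
from .system import MolecularSystem, Selection, resolve

__all__ = [
    "SASAResult",
    "InterfaceReport",
    "sphere_points",
    "sasa",
    "sasa_points",
    "interface_area",
    "interface_series",
]

#: water probe radius, nm
DEFAULT_PROBE = 0.14
DEFAULT_N_POINTS = 960


@dataclass
class SASAResult:
    """Per-atom and total accessible area (nm^2) of one selection at one frame."""

    atom_indices: np.ndarray
    per_atom: np.ndarray             # nm^2
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class InterfaceReport:
    """Replica-resolved buried interface area between two parts."""

    pair: str
    per_replica: np.ndarray          # nm^2
    mean: float
    se: float | None
    n_replicas: int


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points from a golden-section spiral."""
    if n < 32:
        raise ParameterError("at least 32 sphere points are required")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_points(centers: np.ndarray, radii: np.ndarray,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Shrake–Rupley per-sphere accessible areas (nm^2) for raw coordinates."""
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3 or centers.shape[0] != radii.size:
        raise ParameterError("centers must be (n, 3) with one radius per center")
    if probe < 0:
        raise ParameterError("probe radius must be non-negative")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ConfigurationError(
            "every atom needs a finite positive van der Waals radius "
            "(unknown element in the radii table?)"
        )
    unit = sphere_points(n_points)
    expanded = radii + probe
    n = centers.shape[0]
    areas = np.empty(n)
    tree = cKDTree(centers)
    rmax = expanded.max()
    for i in range(n):
        # neighbours whose expanded sphere could reach atom i's test points
        neigh = tree.query_ball_point(centers[i], expanded[i] + rmax)
        neigh = [j for j in neigh if j != i]
        # exactly coincident spheres: the lowest-index (or largest) one owns
        # the surface, the others are fully buried — the point test is
        # numerically undefined at zero separation
        coincident = [j for j in neigh
                      if np.array_equal(centers[j], centers[i])
                      and expanded[j] == expanded[i]]
        if any(j < i for j in coincident):
            areas[i] = 0.0
            continue
        neigh = [j for j in neigh if j not in coincident]
        pts = centers[i] + expanded[i] * unit
        if neigh:
            d2 = ((pts[:, None, :] - centers[neigh][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < expanded[neigh][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def sasa(system: MolecularSystem, selection: Selection | str = "all",
         probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
         frame: int = 0) -> SASAResult:
    """Solvent-accessible surface area of a selection at one frame.

    Only the selected atoms participate: atoms outside the selection are
    removed entirely (they neither contribute area nor occlude), which is
    exactly what interface-area bookkeeping requires.
    """
    idx = resolve(selection, system)
    if system.n_frames == 0:
        raise AnalysisError("system carries no coordinate frames")
    centers = system.frames[frame][idx]
    radii = system.vdw_radii[idx]
    per_atom = sasa_points(centers, radii, probe=probe, n_points=n_points)
    return SASAResult(idx, per_atom, probe, n_points)


def interface_area(system: MolecularSystem, part_a: Selection | str,
                   part_b: Selection | str, frame: int = 0,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS,
                   halved: bool = True) -> float:
    """Buried interface area (nm^2) between two disjoint parts at one frame.

    ``halved=True`` (default) reports the per-face buried area
    (SASA_A + SASA_B - SASA_AB) / 2; ``halved=False`` the total buried area.
    """
    ia = resolve(part_a, system)
    ib = resolve(part_b, system)
    if np.intersect1d(ia, ib).size:
        raise AnalysisError("interface partners must not share atoms")
    xyz = system.frames[frame]
    a = sasa_points(xyz[ia], system.vdw_radii[ia], probe, n_points).sum()
    b = sasa_points(xyz[ib], system.vdw_radii[ib], probe, n_points).sum()
    both_idx = np.sort(np.concatenate([ia, ib]))  # order-independent ⇒ A/B symmetric
    ab = sasa_points(xyz[both_idx], system.vdw_radii[both_idx], probe, n_points).sum()
    buried = a + b - ab
    return float(buried / 2.0) if halved else float(buried)


def interface_series(replica_systems: list[MolecularSystem],
                     part_a: Selection | str, part_b: Selection | str,
                     at="final", pair_label: str | None = None,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS,
                     halved: bool = True) -> InterfaceReport:
    """Replica mean ± SE of the interface area at designated frame(s).

    ``at="final"`` evaluates the last frame of each replica (the end-state
    convention); an integer picks one frame, and a slice or index array is
    averaged within each replica before the replica statistics.
    """
    if not replica_systems:
        raise AnalysisError("empty replica list")
    values = []
    for sysm in replica_systems:
        if sysm.n_frames == 0:
            raise AnalysisError("replica carries no frames")
        if at == "final":
            frames = [sysm.n_frames - 1]
        elif isinstance(at, (int, np.integer)):
            frames = [int(at)]
        else:
            frames = list(np.arange(sysm.n_frames)[at])
            if not frames:
                raise AnalysisError("empty frame window")
        per_frame = [
            interface_area(sysm, part_a, part_b, frame=f, probe=probe,
                           n_points=n_points, halved=halved)
            for f in frames
        ]
        values.append(float(np.mean(per_frame)))
    values = np.array(values)
    n = values.size
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    label = pair_label or f"{part_a}-{part_b}"
    return InterfaceReport(label, values, float(values.mean()), se, n)
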