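"""Shared fixtures: random toy systems and tiny hand-written structures."""

from __future__ import annotations

import numpy as np
import pytest

from glycocover.system import MolecularSystem


def make_random_system(rng: np.random.Generator, n_group_atoms: int = 20,
                       n_target_atoms: int = 15, n_frames: int = 5,
                       periodic: bool = True,
                       n_group_residues: int = 6) -> MolecularSystem:
    """A random two-entity system (groupA residues vs one groupB blob)."""
    n_atoms = n_group_atoms + n_target_atoms
    group_res = rng.integers(0, n_group_residues, n_group_atoms)
    # every residue needs at least one atom: remap to used ids
    used = np.unique(group_res)
    remap = {int(u): i for i, u in enumerate(used)}
    group_res = np.array([remap[int(g)] for g in group_res])
    n_res_a = len(used)
    resindex = np.concatenate([group_res, np.full(n_target_atoms, n_res_a)])
    residue_ids = np.concatenate([10 + np.arange(n_res_a), [500]])
    box = rng.uniform(2.0, 4.0, 3) if periodic else None
    frames = rng.uniform(0.0, 4.0, (n_frames, n_atoms, 3))
    return MolecularSystem(
        atom_names=np.array([f"X{i}" for i in range(n_atoms)], dtype=object),
        elements=np.array(["C"] * n_atoms, dtype=object),
        vdw_radii=np.full(n_atoms, 0.17),
        atom_resindex=resindex,
        residue_ids=residue_ids,
        residue_names=np.array(["RES"] * n_res_a + ["TGT"], dtype=object),
        entities={"groupA": residue_ids[:n_res_a], "groupB": residue_ids[n_res_a:]},
        frames=frames,
        boxes=np.tile(box, (n_frames, 1)) if periodic else None,
        time_per_frame=0.1,
    )


def brute_min_distances(system: MolecularSystem, group_atoms, target_atoms,
                        frame: int) -> dict[int, float]:
    """Reference O(N*M) per-residue min distance, plain Python loops."""
    xyz = system.frames[frame]
    box = system.boxes[frame] if system.boxes is not None else None
    rids = system.residue_id_of_atoms()
    best: dict[int, float] = {}
    for ai in group_atoms:
        for aj in target_atoms:
            d = xyz[ai] - xyz[aj]
            if box is not None:
                d = d - box * np.round(d / box)
            dist = float(np.sqrt((d * d).sum()))
            rid = int(rids[ai])
            if rid not in best or dist < best[rid]:
                best[rid] = dist
    return best


def simple_system(positions, residue_split=None, box=None,
                  radii=0.15, names=None, dt=0.1) -> MolecularSystem:
    """A hand-built system: positions (n_frames, n_atoms, 3) or (n_atoms, 3).

    ``residue_split`` gives the number of atoms in entity "a"; the rest go
    to entity "b" (one residue each).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    n_atoms = positions.shape[1]
    split = residue_split if residue_split is not None else n_atoms // 2
    resindex = np.array([0] * split + [1] * (n_atoms - split))
    n_frames = positions.shape[0]
    return MolecularSystem(
        atom_names=np.array(
            names if names is not None else [f"X{i}" for i in range(n_atoms)],
            dtype=object,
        ),
        elements=np.array(["C"] * n_atoms, dtype=object),
        vdw_radii=np.full(n_atoms, radii) if np.isscalar(radii) else np.asarray(radii),
        atom_resindex=resindex,
        residue_ids=np.array([1, 2]),
        residue_names=np.array(["AAA", "BBB"], dtype=object),
        entities={"a": [1], "b": [2]},
        frames=positions,
        boxes=np.tile(box, (n_frames, 1)) if box is not None else None,
        time_per_frame=dt,
    )


TINY_PDB = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A  41       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  O   ALA A  41       4.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p
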