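"""Synthetic fixture generators with exact, machine-checkable ground truth.

Real glycoprotein trajectories are multi-gigabyte downloads; every stage
of this package is instead testable against toy systems whose answers are
known by construction:

* :func:`gen_shielded_trajectory` builds a rigid toy receptor (residues on
  a planar lattice), grafts bead-chain "glycans" whose occlusion of chosen
  residues is planted at exact contact fractions (a seeded frame subset of
  size ``round(p * n_frames)`` per residue), and moves a bead-chain ligand
  through scripted bound/unbound episodes.  The planted fractions and the
  episode schedule ARE the expected analysis output, exactly.
* :func:`gen_titration_peaks` fabricates HSQC peak lists across titration
  points with planted per-residue response categories and perturbation
  vectors.

The geometry is deliberately coarse: occluder beads toggle between a
parked pose far above the receptor plane and a contact pose 0.25 nm above
one residue centre, so that at the 0.3 nm coverage cutoff a contact
touches exactly one residue and nothing else.  No polymer physics is
emulated — see the methods note for what this does and does not test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError
from .nmr import PeakList
from .system import MolecularSystem, parse_entity_map, write_system
from .tabular import write_tsv

__all__ = [
    "GlycanChainSpec",
    "ShieldScenario",
    "TitrationScenario",
    "gen_shielded_trajectory",
    "gen_shielded_replicas",
    "gen_titration_peaks",
    "toy_habd_scenario",
    "TOY_PLANTED_OCCLUSION",
    "TOY_FOOTPRINT_RESIDUES",
]

#: contact pose offset (nm): strictly inside the 0.3 nm coverage cutoff
CONTACT_OFFSET = 0.25
#: parked occluder height above the receptor plane (nm): well outside 0.6 nm
REST_HEIGHT = 0.9
#: unbound ligand depth below the receptor plane (nm): beyond 1.5 nm
UNBOUND_DEPTH = 3.0
LATTICE_SPACING = 1.2
MARGIN = 2.0


@dataclass(frozen=True)
class GlycanChainSpec:
    attachment_residue: int
    n_beads: int = 8
    bead_radius: float = 0.15        # nm, used as vdw radius


# Default planted occlusions for the toy receptor: crystallographic-groove
# residues most occluded, flanking (parallel) residues intermediate, the
# upright patch least — the shielding hierarchy the analyses should recover.
TOY_PLANTED_OCCLUSION: dict[int, float] = {
    41: 0.80, 78: 0.70,                      # crystallographic groove
    150: 0.50, 154: 0.45,                    # parallel-mode flanking arginines
    38: 0.20, 43: 0.25, 44: 0.30, 79: 0.15, 80: 0.25,
    105: 0.20, 113: 0.30, 114: 0.25, 162: 0.10, 166: 0.15,  # upright patch
}

TOY_FOOTPRINT_RESIDUES: dict[str, list[int]] = {
    "crystallographic": [41, 78],
    "parallel": [41, 150, 154],
    "upright": [38, 43, 44, 79, 80, 105, 113, 114, 162, 166],
}


@dataclass
class ShieldScenario:
    """Parameters of one synthetic shielded-receptor trajectory."""

    n_receptor_residues: int = 150
    first_residue_id: int = 20
    atoms_per_residue: int = 3
    glycans: list[GlycanChainSpec] = field(
        default_factory=lambda: [GlycanChainSpec(r) for r in (25, 57, 100, 110, 120)]
    )
    planted_occlusion: dict[int, float] = field(
        default_factory=lambda: dict(TOY_PLANTED_OCCLUSION)
    )
    ligand_n_beads: int = 6
    #: bound episodes as (start_ns, end_ns) half-open intervals
    binding_schedule: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 30.0), (45.0, 60.0), (75.0, 90.0)]
    )
    epitope_residues: list[int] = field(
        default_factory=lambda: [38, 41, 78, 150, 154, 162]
    )
    n_frames: int = 1000
    dt: float = 0.1                  # ns per frame
    seed: int = 0

    def validate(self) -> None:
        rid_lo = self.first_residue_id
        rid_hi = rid_lo + self.n_receptor_residues - 1
        for rid, p in self.planted_occlusion.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"planted occlusion {p} for residue {rid} not in [0,1]")
            if not rid_lo <= rid <= rid_hi:
                raise GenerationError(f"planted residue {rid} outside receptor {rid_lo}-{rid_hi}")
        for g in self.glycans:
            if not rid_lo <= g.attachment_residue <= rid_hi:
                raise GenerationError(f"glycan attachment {g.attachment_residue} off-receptor")
        total_beads = sum(g.n_beads for g in self.glycans)
        n_planted = sum(1 for p in self.planted_occlusion.values() if p > 0)
        if n_planted > total_beads:
            raise GenerationError(
                f"{n_planted} occluded residues need dedicated beads but the "
                f"glycan chains supply only {total_beads}"
            )
        span = self.n_frames * self.dt
        for t0, t1 in self.binding_schedule:
            if not (0 <= t0 < t1 <= span + 1e-9):
                raise GenerationError(
                    f"binding episode ({t0}, {t1}) ns outside trajectory span {span} ns"
                )
        for rid in self.epitope_residues:
            if not rid_lo <= rid <= rid_hi:
                raise GenerationError(f"epitope residue {rid} off-receptor")

    @classmethod
    def from_yaml(cls, path) -> "ShieldScenario":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise GenerationError("scenario YAML must state a seed")
        if "glycans" in raw:
            raw["glycans"] = [GlycanChainSpec(**g) for g in raw["glycans"]]
        if "binding_schedule" in raw:
            raw["binding_schedule"] = [tuple(ep) for ep in raw["binding_schedule"]]
        if "planted_occlusion" in raw:
            raw["planted_occlusion"] = {int(k): float(v)
                                        for k, v in raw["planted_occlusion"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the analyses must recover from a generated trajectory."""

    planted_occlusion: pd.DataFrame   # residue_id, planted_p, n_contact_frames
    schedule: pd.DataFrame            # start_ns, end_ns, duration_ns
    entity_map: dict[str, object]


# ---------------------------------------------------------------------------
# shielded trajectory
# ---------------------------------------------------------------------------


def _receptor_lattice(scn: ShieldScenario) -> tuple[np.ndarray, np.ndarray]:
    """Residue-centre lattice (z=0 plane) and per-residue atom offsets."""
    n = scn.n_receptor_residues
    ncols = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), ncols)
    centers = np.column_stack(
        [cols * LATTICE_SPACING, rows * LATTICE_SPACING, np.zeros(n)]
    )
    offsets = np.zeros((scn.atoms_per_residue, 3))
    for k in range(1, scn.atoms_per_residue):
        ang = 2 * np.pi * k / max(scn.atoms_per_residue - 1, 1)
        offsets[k] = [0.04 * np.cos(ang), 0.04 * np.sin(ang), 0.0]
    return centers, offsets


def gen_shielded_trajectory(scenario: ShieldScenario,
                            out_dir: str | Path | None = None
                            ) -> tuple[MolecularSystem, GroundTruth]:
    """Build one synthetic shielded-receptor trajectory.

    Returns the in-memory system plus its ground truth.  With ``out_dir``
    the system is also written as ``toy.gro`` + ``toy.xtc`` together with
    ``entity_map.yaml`` and ground-truth TSVs.
    """
    scn = scenario
    scn.validate()
    rng = np.random.default_rng(scn.seed)

    centers, offsets = _receptor_lattice(scn)
    rid_lo = scn.first_residue_id
    receptor_rids = np.arange(rid_lo, rid_lo + scn.n_receptor_residues)

    # ---- topology -------------------------------------------------------
    atom_names, elements, resindex = [], [], []
    residue_ids, residue_names = [], []
    positions0 = []

    for i, rid in enumerate(receptor_rids):
        residue_ids.append(rid)
        residue_names.append("RES")
        for k in range(scn.atoms_per_residue):
            atom_names.append(f"A{k}")
            elements.append("C")
            resindex.append(len(residue_ids) - 1)
            positions0.append(centers[i] + offsets[k])

    # glycan chains: one residue per chain, parked stacked above attachment
    entity_map: dict[str, object] = {"receptor": f"{receptor_rids[0]}-{receptor_rids[-1]}"}
    glycan_rest: list[np.ndarray] = []
    glycan_atom_start: list[int] = []
    next_rid = 1001
    for g in scn.glycans:
        rid = next_rid
        next_rid += 1
        residue_ids.append(rid)
        residue_names.append("GLC")
        entity_map[f"glycan_N{g.attachment_residue}"] = [rid]
        attach = centers[g.attachment_residue - rid_lo]
        glycan_atom_start.append(len(atom_names))
        rest = np.array(
            [attach + [0.0, 0.0, REST_HEIGHT + 0.3 * k] for k in range(g.n_beads)]
        )
        glycan_rest.append(rest)
        for k in range(g.n_beads):
            atom_names.append(f"G{k}")
            elements.append("C")
            resindex.append(len(residue_ids) - 1)
            positions0.append(rest[k])

    # ligand chain
    lig_rid = 2001
    residue_ids.append(lig_rid)
    residue_names.append("LIG")
    entity_map["ligand_HA6_1"] = [lig_rid]
    lig_atom_start = len(atom_names)
    epitope_centers = np.array(
        [centers[r - rid_lo] for r in scn.epitope_residues]
    )
    lig_bound = np.array(
        [
            epitope_centers[k % len(epitope_centers)] + [0.0, 0.0, -CONTACT_OFFSET]
            for k in range(scn.ligand_n_beads)
        ]
    )
    lig_unbound = np.array(
        [[0.4 * k, -1.0, -UNBOUND_DEPTH] for k in range(scn.ligand_n_beads)]
    )
    for k in range(scn.ligand_n_beads):
        atom_names.append(f"L{k}")
        elements.append("C")
        resindex.append(len(residue_ids) - 1)
        positions0.append(lig_unbound[k])

    positions0 = np.array(positions0)
    shift = MARGIN - positions0.min(axis=0)
    positions0 += shift
    centers_s = centers + shift
    box = positions0.max(axis=0) + MARGIN

    n_atoms = len(atom_names)
    radii = np.full(n_atoms, 0.15)

    # ---- frame-by-frame placement ---------------------------------------
    frames = np.tile(positions0, (scn.n_frames, 1, 1))

    # assign each occluded residue a dedicated glycan bead, nearest chain first
    planted = {r: p for r, p in scn.planted_occlusion.items() if p > 0}
    bead_budget = [g.n_beads for g in scn.glycans]
    attach_xy = np.array([centers[g.attachment_residue - rid_lo][:2] for g in scn.glycans])
    assignment: dict[int, tuple[int, int]] = {}  # residue -> (chain, bead)
    for rid in sorted(planted):
        xy = centers[rid - rid_lo][:2]
        order = np.argsort(((attach_xy - xy) ** 2).sum(axis=1), kind="stable")
        chain = next((int(c) for c in order if bead_budget[c] > 0), None)
        if chain is None:
            raise GenerationError("ran out of glycan beads for planted residues")
        bead_budget[chain] -= 1
        assignment[rid] = (chain, scn.glycans[chain].n_beads - 1 - bead_budget[chain])

    gt_rows = []
    for rid, p in sorted(scn.planted_occlusion.items()):
        n_contact = int(round(p * scn.n_frames))
        if p > 0:
            chain, bead = assignment[rid]
            contact_frames = rng.permutation(scn.n_frames)[:n_contact]
            atom = glycan_atom_start[chain] + bead
            pose = centers_s[rid - rid_lo] + [0.0, 0.0, CONTACT_OFFSET]
            frames[contact_frames, atom, :] = pose
        gt_rows.append({"residue_id": rid, "planted_p": p, "n_contact_frames": n_contact})

    # ligand schedule
    bound_mask = np.zeros(scn.n_frames, dtype=bool)
    sched_rows = []
    for t0, t1 in scn.binding_schedule:
        f0 = int(round(t0 / scn.dt))
        f1 = int(round(t1 / scn.dt))  # exclusive
        bound_mask[f0:f1] = True
        sched_rows.append({"start_ns": t0, "end_ns": t1, "duration_ns": t1 - t0})
    lig_slice = slice(lig_atom_start, lig_atom_start + scn.ligand_n_beads)
    frames[bound_mask, lig_slice, :] = lig_bound + shift
    frames[~bound_mask, lig_slice, :] = lig_unbound + shift

    system = MolecularSystem(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        vdw_radii=radii,
        atom_resindex=np.array(resindex),
        residue_ids=np.array(residue_ids),
        residue_names=np.array(residue_names, dtype=object),
        entities=parse_entity_map(entity_map),
        frames=frames,
        boxes=np.tile(box, (scn.n_frames, 1)),
        time_per_frame=scn.dt,
    )
    truth = GroundTruth(
        planted_occlusion=pd.DataFrame(gt_rows),
        schedule=pd.DataFrame(sched_rows),
        entity_map=entity_map,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_system(system, out_dir / "toy.gro", out_dir / "toy.xtc")
        (out_dir / "entity_map.yaml").write_text(yaml.safe_dump(entity_map))
        write_tsv(truth.planted_occlusion, out_dir / "ground_truth_occlusion.tsv",
                  params={"seed": scn.seed, "n_frames": scn.n_frames})
        write_tsv(truth.schedule, out_dir / "ground_truth_schedule.tsv",
                  params={"seed": scn.seed, "dt_ns": scn.dt})
    return system, truth


def gen_shielded_replicas(scenario: ShieldScenario, n_replicas: int
                          ) -> tuple[list[MolecularSystem], GroundTruth]:
    """Independent replicas of one scenario (seed offset per replica).

    Each replica plants the same occlusion fractions through a different
    seeded frame subset, so per-replica contact fractions are identical by
    construction and the replica SE of any planted quantity is exactly 0.
    """
    systems = []
    truth = None
    for r in range(n_replicas):
        scn_r = ShieldScenario(**{**scenario.__dict__,
                                  "glycans": list(scenario.glycans),
                                  "planted_occlusion": dict(scenario.planted_occlusion),
                                  "binding_schedule": list(scenario.binding_schedule),
                                  "epitope_residues": list(scenario.epitope_residues),
                                  "seed": scenario.seed + 7919 * r})
        sysm, truth = gen_shielded_trajectory(scn_r)
        systems.append(sysm)
    return systems, truth


def toy_habd_scenario(seed: int = 0, n_frames: int = 1000) -> ShieldScenario:
    """The default toy receptor: 150 residues (20-169), five glycan chains
    at the glycosylation-site positions, key binding residues as epitope."""
    return ShieldScenario(seed=seed, n_frames=n_frames)


# ---------------------------------------------------------------------------
# titration peak lists
# ---------------------------------------------------------------------------


@dataclass
class TitrationScenario:
    """Parameters of a synthetic HSQC titration."""

    residues: list[int] = field(default_factory=lambda: list(range(20, 170)))
    #: residue -> category (classifier codomain); unlisted residues are unperturbed
    planted_categories: dict[int, str] = field(
        default_factory=lambda: {
            38: "instant_disappearance", 40: "instant_disappearance",
            80: "instant_disappearance", 114: "instant_disappearance",
            43: "instant_shift", 44: "instant_shift", 79: "instant_shift",
            23: "gradual_shift", 105: "gradual_shift", 162: "gradual_shift",
        }
    )
    #: residue -> (dH, dN) perturbation at the final titration point, ppm
    perturbations: dict[int, tuple[float, float]] = field(default_factory=dict)
    doubled: list[int] = field(default_factory=lambda: [150, 154])
    noise_sigma: float = 0.0         # ppm, added to every shift
    ratios: tuple = (1.0, 2.0, 3.0)  # ligand:protein molar ratios
    seed: int = 0

    def validate(self) -> None:
        from .nmr import CATEGORIES

        for rid, cat in self.planted_categories.items():
            if cat not in CATEGORIES:
                raise GenerationError(f"unknown planted category {cat!r} for residue {rid}")
            if rid not in self.residues:
                raise GenerationError(f"planted residue {rid} not in residue list")
        for rid in self.doubled:
            if self.planted_categories.get(rid, "unperturbed") == "instant_disappearance":
                raise GenerationError("a disappeared signal cannot be doubled")


def gen_titration_peaks(scenario: TitrationScenario
                        ) -> tuple[dict[str, PeakList], pd.DataFrame]:
    """Fabricate free + titration peak lists with planted responses.

    Returns ``{"free": ..., "1:1": ..., ...}`` plus a ground-truth table
    (residue_id, category, doubled, dH, dN).  Instant responses apply the
    full perturbation from the first point; gradual responses scale it by
    ratio/max(ratio); disappearances zero the intensity from the first
    point.  Gaussian noise of ``noise_sigma`` ppm is added to every shift.
    """
    scn = scenario
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    rids = np.array(sorted(scn.residues), dtype=np.int64)
    n = rids.size
    base_dH = rng.uniform(7.0, 9.5, n)
    base_dN = rng.uniform(105.0, 130.0, n)

    default_delta = {"instant_disappearance": (0.0, 0.0),
                     "instant_shift": (0.10, 0.50),
                     "gradual_shift": (0.12, 0.45),
                     "unperturbed": (0.0, 0.0)}
    deltas = np.zeros((n, 2))
    cats = []
    for i, rid in enumerate(rids):
        cat = scn.planted_categories.get(int(rid), "unperturbed")
        cats.append(cat)
        d = scn.perturbations.get(int(rid), default_delta[cat])
        deltas[i] = d

    max_ratio = max(scn.ratios)
    doubled_set = set(scn.doubled)
    out: dict[str, PeakList] = {}

    def noisy(x):
        return x + (rng.normal(0.0, scn.noise_sigma, x.shape) if scn.noise_sigma > 0 else 0.0)

    out["free"] = PeakList(rids, noisy(base_dH.copy()), noisy(base_dN.copy()),
                           np.ones(n), np.ones(n, dtype=bool), condition="free")

    truth_rows = []
    for i, rid in enumerate(rids):
        truth_rows.append({"residue_id": int(rid), "category": cats[i],
                           "doubled": int(rid) in doubled_set,
                           "dH": deltas[i, 0], "dN": deltas[i, 1]})

    for ratio in scn.ratios:
        scale_gradual = ratio / max_ratio
        dH = base_dH.copy()
        dN = base_dN.copy()
        intensity = np.ones(n)
        present = np.ones(n, dtype=bool)
        sec_dH = np.full(n, np.nan)
        sec_dN = np.full(n, np.nan)
        for i, rid in enumerate(rids):
            cat = cats[i]
            if cat == "instant_disappearance":
                intensity[i] = 0.0
                present[i] = False
            elif cat == "instant_shift":
                dH[i] += deltas[i, 0]
                dN[i] += deltas[i, 1]
            elif cat == "gradual_shift":
                dH[i] += deltas[i, 0] * scale_gradual
                dN[i] += deltas[i, 1] * scale_gradual
            if int(rid) in doubled_set and cat != "instant_disappearance":
                # the split partner: the unshifted (or original-mode) position
                sec_dH[i] = base_dH[i] + 0.05
                sec_dN[i] = base_dN[i] + 0.25
        label = f"{ratio:g}:1"
        out[label] = PeakList(rids, noisy(dH), noisy(dN), intensity, present,
                              noisy(sec_dH), noisy(sec_dN), condition=label)
    return out, pd.DataFrame(truth_rows)
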