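"""Per-binding-mode glycan coverage with replica statistics.

The statistic answers: *how much of the receptor surface that a ligand
binding mode relies on is occluded by N-glycans?*  Given a binding-mode
*footprint* — per-residue weights describing how strongly the ligand
contacts each receptor residue in that mode — and per-replica glycan
contact fractions C_res, the mode coverage of replica ``r`` is the
footprint-weighted mean

    C_mode(r) = sum_res w_res * C_res(r) / sum_res w_res,

reported as a replica mean with the sample standard error.  The result is
invariant to uniform scaling of the weights and is a convex combination of
the per-residue coverages.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ResidueCoverage
from .errors import AnalysisError, ConfigurationError
from .tabular import write_tsv

__all__ = [
    "ModeFootprint",
    "CoverageReport",
    "load_footprints",
    "bundled_footprints",
    "mode_coverage",
    "key_residue_coverage",
    "compare_modes",
    "coverage_table",
]


@dataclass
class ModeFootprint:
    """Per-residue ligand-contact weights for one named binding mode."""

    mode: str
    residue_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.residue_ids.size != self.weights.size:
            raise ConfigurationError("footprint residue/weight length mismatch")
        if len(np.unique(self.residue_ids)) != self.residue_ids.size:
            raise ConfigurationError(f"duplicate residues in footprint {self.mode!r}")
        if self.weights.size == 0 or np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ConfigurationError(
                f"footprint {self.mode!r} weights must lie in [0, 1]"
            )
        if not np.any(self.weights > 0):
            raise ConfigurationError(
                f"footprint {self.mode!r} is degenerate: all weights are zero"
            )


@dataclass
class CoverageReport:
    """Replica-resolved mode coverage (one cell of a coverage table)."""

    mode: str
    per_replica: np.ndarray          # coverage fractions in [0, 1], one per replica
    mean: float                      # fraction
    se: float | None                 # fraction; None when n_replicas == 1
    n_replicas: int

    @property
    def mean_pct(self) -> float:
        return 100.0 * self.mean

    @property
    def se_pct(self) -> float | None:
        return None if self.se is None else 100.0 * self.se

    def __str__(self) -> str:
        se = "n/a" if self.se is None else f"{self.se_pct:.0f}"
        return f"{self.mode}: {self.mean_pct:.0f} ± {se} %"


# ---------------------------------------------------------------------------
# footprint I/O
# ---------------------------------------------------------------------------


def load_footprints(path) -> dict[str, ModeFootprint]:
    """Read a footprint TSV (columns: mode, residue_id, weight) into footprints."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"mode", "residue_id", "weight"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"footprint table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = {}
    for mode, grp in df.groupby("mode", sort=False):
        out[str(mode)] = ModeFootprint(
            str(mode),
            grp["residue_id"].to_numpy(),
            grp["weight"].to_numpy(),
        )
    if not out:
        raise ConfigurationError("footprint table is empty")
    return out


def bundled_footprints() -> dict[str, ModeFootprint]:
    """The example CD44 binding-mode membership footprints shipped with the package."""
    with resources.as_file(
        resources.files("glycocover").joinpath("data/footprints_cd44.tsv")
    ) as p:
        return load_footprints(p)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _replica_stats(values: np.ndarray) -> tuple[float, float | None]:
    n = values.size
    mean = float(values.mean())
    if n < 2:
        return mean, None
    if np.ptp(values) == 0.0:  # identical replicas: exactly zero spread
        return float(values[0]), 0.0
    return mean, float(values.std(ddof=1) / np.sqrt(n))


def _coverage_lookup(cov: ResidueCoverage, residue_ids: np.ndarray,
                     context: str) -> np.ndarray:
    table = cov.as_dict()
    missing = [int(r) for r in residue_ids if int(r) not in table]
    if missing:
        raise AnalysisError(f"{context}: residues missing from replica coverage: {missing}")
    return np.array([table[int(r)] for r in residue_ids])


def mode_coverage(glycan_coverage_per_replica: list[ResidueCoverage],
                  footprint: ModeFootprint) -> CoverageReport:
    """Footprint-weighted glycan coverage of a binding mode, per replica.

    Every footprint residue with a positive weight must be present in every
    replica's coverage; a missing residue is an error rather than a silent
    zero, because it usually means the group selection was wrong.
    """
    if not glycan_coverage_per_replica:
        raise AnalysisError("at least one replica coverage is required")
    pos = footprint.weights > 0
    rids = footprint.residue_ids[pos]
    w = footprint.weights[pos]
    per_replica = np.array(
        [
            float((w * _coverage_lookup(cov, rids, f"mode {footprint.mode!r}")).sum()
                  / w.sum())
            for cov in glycan_coverage_per_replica
        ]
    )
    mean, se = _replica_stats(per_replica)
    return CoverageReport(footprint.mode, per_replica, mean, se,
                          len(per_replica))


def key_residue_coverage(glycan_coverage_per_replica: list[ResidueCoverage],
                         residues) -> pd.DataFrame:
    """Replica mean ± SE of the glycan contact fraction of individual residues.

    Used for the key ligand-binding residues (e.g. the binding arginines):
    a residue with low glycan coverage remains accessible to the ligand.
    """
    if not glycan_coverage_per_replica:
        raise AnalysisError("at least one replica coverage is required")
    rids = np.asarray(residues, dtype=np.int64)
    values = np.array(
        [
            _coverage_lookup(cov, rids, "key residues")
            for cov in glycan_coverage_per_replica
        ]
    )  # (n_replicas, n_res)
    n = values.shape[0]
    mean = values.mean(axis=0)
    se = values.std(ddof=1, axis=0) / np.sqrt(n) if n > 1 else np.full(rids.size, np.nan)
    return pd.DataFrame(
        {"residue_id": rids, "mean_coverage": mean, "se": se, "n_replicas": n}
    )


def compare_modes(reports: list[CoverageReport]) -> pd.DataFrame:
    """Rank binding modes by mean coverage and tabulate pairwise differences.

    Returns a long-form DataFrame: one ``rank`` row per mode (sorted by mean
    coverage, most shielded first) followed by one ``difference`` row per
    mode pair with the difference of means and its pooled standard error.
    """
    if len(reports) < 2:
        raise AnalysisError("need at least two mode reports to compare")
    ns = {r.n_replicas for r in reports}
    if len(ns) > 1:
        raise AnalysisError(f"reports come from different replica counts: {sorted(ns)}")
    ranked = sorted(reports, key=lambda r: r.mean, reverse=True)
    rows = [
        {
            "kind": "rank",
            "mode": r.mode,
            "other": "",
            "mean_pct": r.mean_pct,
            "se_pct": r.se_pct,
            "difference_pct": np.nan,
            "pooled_se_pct": np.nan,
        }
        for r in ranked
    ]
    for i, a in enumerate(ranked):
        for b in ranked[i + 1:]:
            pooled = (
                np.sqrt(a.se ** 2 + b.se ** 2)
                if a.se is not None and b.se is not None
                else np.nan
            )
            rows.append(
                {
                    "kind": "difference",
                    "mode": a.mode,
                    "other": b.mode,
                    "mean_pct": np.nan,
                    "se_pct": np.nan,
                    "difference_pct": a.mean_pct - b.mean_pct,
                    "pooled_se_pct": 100.0 * pooled if np.isfinite(pooled) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def coverage_table(reports_by_glycoform: dict[str, list[CoverageReport]],
                   path=None) -> pd.DataFrame:
    """Mode × glycoform table of "mean ± SE" coverage percentages.

    Mirrors the layout of a per-glycoform coverage summary; optionally
    written as TSV with a provenance header.
    """
    modes: list[str] = []
    for reports in reports_by_glycoform.values():
        for r in reports:
            if r.mode not in modes:
                modes.append(r.mode)
    data = {}
    for glycoform, reports in reports_by_glycoform.items():
        by_mode = {r.mode: r for r in reports}
        col = []
        for m in modes:
            r = by_mode.get(m)
            if r is None:
                col.append("")
            else:
                se = "n/a" if r.se_pct is None else f"{r.se_pct:.0f}"
                col.append(f"{r.mean_pct:.0f} ± {se}")
        data[glycoform] = col
    df = pd.DataFrame(data, index=pd.Index(modes, name="mode")).reset_index()
    if path is not None:
        write_tsv(df, path, params={"units": "percent", "se": "sample std (ddof=1)/sqrt(n)"})
    return df
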