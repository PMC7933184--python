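"""TSV output with provenance header comments.

All tabular artifacts written by the package carry `# key = value` header
lines recording the parameters (cutoffs, seeds, versions) that produced
them, so a table can always be traced back to its settings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV, prefixed with commented parameter lines."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# glycocover = {__version__}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key} = {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
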