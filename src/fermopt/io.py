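"""CSV and flat-text I/O for run records, designs and configuration.

Run CSVs use the column layout
``run_id,pH,agitation_rpm,aeration_vvm,productivity,productivity_sd,
concentration,concentration_sd,yield,yield_sd`` (comma separated, dot
decimal); design-only files omit the response columns.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable
from .factors import Region
from .records import Response, RunRecord

__all__ = [
    "read_runs_csv",
    "write_runs_csv",
    "write_design_csv",
    "read_config",
    "parse_region",
]

_FACTOR_COLUMNS = {"pH": "pH", "agitation": "agitation_rpm", "aeration": "aeration_vvm"}
_RESPONSES = ("productivity", "concentration", "yield")


def write_design_csv(design: DesignTable, path) -> None:
    """Write a design's physical settings (no response columns)."""
    phys = design.physical_matrix
    cols = {"run_id": np.arange(1, design.n_runs + 1)}
    for j, f in enumerate(design.space.factors):
        cols[_FACTOR_COLUMNS.get(f.name, f.name)] = phys[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_runs_csv(records: Sequence[RunRecord], path) -> None:
    rows = []
    for r in records:
        row: dict[str, float] = {"run_id": r.run_id}
        for name, col in _FACTOR_COLUMNS.items():
            if name in r.settings:
                row[col] = r.settings[name]
        for resp in _RESPONSES:
            if resp in r.responses:
                row[resp] = r.responses[resp].mean
                row[f"{resp}_sd"] = r.responses[resp].sd
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_runs_csv(path) -> list[RunRecord]:
    """Read run records; response columns are optional (design-only files
    yield records with empty responses)."""
    df = pd.read_csv(path)
    inverse = {v: k for k, v in _FACTOR_COLUMNS.items()}
    records = []
    for _, row in df.iterrows():
        settings = {
            inverse[c]: float(row[c]) for c in df.columns if c in inverse and pd.notna(row[c])
        }
        responses = {}
        for resp in _RESPONSES:
            if resp in df.columns and pd.notna(row[resp]):
                sd_col = f"{resp}_sd"
                sd = float(row[sd_col]) if sd_col in df.columns and pd.notna(row.get(sd_col)) else 0.0
                responses[resp] = Response(float(row[resp]), sd)
        records.append(
            RunRecord(run_id=int(row["run_id"]), settings=settings, responses=responses)
        )
    return records


def read_config(path) -> dict[str, str]:
    """Flat ``key=value`` text configuration; '#' starts a comment line."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            k, v = line.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg


def parse_region(text: str) -> Region:
    """Parse ``name:low:high`` triples separated by commas, e.g.
    ``pH:4:7.5,agitation:200:550,aeration:0.6:2.0``."""
    bounds: dict[str, tuple[float, float]] = {}
    for part in text.split(","):
        name, lo, hi = part.split(":")
        bounds[name.strip()] = (float(lo), float(hi))
    return Region(bounds)
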