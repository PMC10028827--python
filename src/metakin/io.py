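"""Readers and writers: COLVAR-dialect tables, energy/ligand CSVs, results.

The COLVAR dialect is the PLUMED time-series format: a ``#! FIELDS ...``
header line naming the columns, further ``#``-prefixed comment lines, and
whitespace-separated numeric rows. The bias column name is configurable
because dialects differ (``metad.bias`` vs ``bias``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE
from .exceptions import FormatError, ValidationError
from .features import validate_energy_table
from .ligands import LigandRecord
from .trajectory import BiasedTrajectory

__all__ = [
    "ColvarFile",
    "read_colvar",
    "write_colvar",
    "colvar_to_trajectory",
    "trajectory_to_colvar",
    "read_energy_table",
    "write_energy_table",
    "read_ligand_table",
    "write_ligand_table",
    "write_results",
]

DEFAULT_BIAS_COLUMN = "metad.bias"

LIGAND_TABLE_COLUMNS = (
    "ligand_id", "smiles", "substituent_class",
    "tau_cal", "tau_exp", "k_d", "k_i_nlx",
)

#: Units of the emitted table columns (sidecar schema content).
COLUMN_UNITS = {
    "time": "ps", "z": "angstrom", "contacts": "count", "metad.bias": "kcal/mol",
    "frame_time": "ps", "energy": "kcal/mol", "frame_bias": "kcal/mol",
    "tau_cal": "s", "tau_exp": "s", "k_d": "nM", "k_i_nlx": "nM",
    "tau_hat_s": "s", "mean_tau_s": "s", "sem_tau_s": "s",
    "free_energy": "kcal/mol", "pearson_r": "dimensionless",
    "max_abs_mean": "kcal/mol", "spread": "kcal/mol",
    "log10_tau": "log10 s", "rmse": "log10 s", "r2": "dimensionless",
}


@dataclass
class ColvarFile:
    """Parsed COLVAR table: ordered field names plus a numeric row matrix."""

    fields: List[str]
    data: np.ndarray  # (n_rows, n_fields)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.data[:, self.fields.index(name)]
        except ValueError:
            raise FormatError(f"COLVAR has no field {name!r}; fields: {self.fields}")


def read_colvar(path: Union[str, Path], check_monotone_time: bool = True) -> ColvarFile:
    """Parse a COLVAR-dialect file.

    The first ``#! FIELDS`` line defines the columns; comment lines are
    skipped; every row must carry exactly one value per field. The time
    column (when present and ``check_monotone_time``) must be strictly
    increasing.
    """
    path = Path(path)
    fields: Optional[List[str]] = None
    rows: List[List[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if stripped.startswith("#!") and "FIELDS" in stripped and fields is None:
                    fields = stripped.split()[2:]
                continue
            if fields is None:
                raise FormatError(f"{path}: data before '#! FIELDS' header")
            parts = stripped.split()
            if len(parts) != len(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(fields)} values, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})")
    if fields is None:
        raise FormatError(f"{path}: missing '#! FIELDS' header")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    cf = ColvarFile(fields=fields, data=data)
    if check_monotone_time and "time" in fields and len(rows) > 1:
        if not np.all(np.diff(cf.column("time")) > 0):
            raise ValidationError(f"{path}: time column is not strictly increasing")
    return cf


def write_colvar(path: Union[str, Path], colvar: ColvarFile) -> None:
    """Write a COLVAR file; floats are printed with full precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#! FIELDS " + " ".join(colvar.fields) + "\n")
        for row in colvar.data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def colvar_to_trajectory(
    colvar: ColvarFile,
    ligand_id: str,
    bias_column: str = DEFAULT_BIAS_COLUMN,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BiasedTrajectory:
    """Interpret a COLVAR table as a biased unbinding trajectory."""
    return BiasedTrajectory(
        ligand_id=ligand_id,
        time=colvar.column("time"),
        z=colvar.column("z"),
        contacts=colvar.column("contacts"),
        bias=colvar.column(bias_column),
        temperature=temperature,
    )


def trajectory_to_colvar(
    traj: BiasedTrajectory, bias_column: str = DEFAULT_BIAS_COLUMN
) -> ColvarFile:
    return ColvarFile(
        fields=["time", "z", "contacts", bias_column],
        data=np.column_stack([traj.time, traj.z, traj.contacts, traj.bias]),
    )


def read_energy_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and schema-validate a frame-level energy CSV."""
    df = pd.read_csv(path)
    return validate_energy_table(df)


def write_energy_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    validate_energy_table(table).to_csv(path, index=False)


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_ligand_table(path: Union[str, Path]) -> List[LigandRecord]:
    """Read a ligand metadata CSV; blank optional cells become None."""
    df = pd.read_csv(path)
    missing = set(LIGAND_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ligand table missing columns: {sorted(missing)}")
    if df["ligand_id"].duplicated().any():
        dupes = df.loc[df["ligand_id"].duplicated(), "ligand_id"].tolist()
        raise ValidationError(f"duplicate ligand ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                LigandRecord(
                    ligand_id=str(row["ligand_id"]),
                    smiles=str(row["smiles"]),
                    substituent_class=str(row["substituent_class"]),
                    tau_cal=_opt(row["tau_cal"]),
                    tau_exp=_opt(row["tau_exp"]),
                    k_d=_opt(row["k_d"]),
                    k_i_nlx=_opt(row["k_i_nlx"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(str(exc))
    return records


def write_ligand_table(path: Union[str, Path], records: Sequence[LigandRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "ligand_id": r.ligand_id,
                "smiles": r.smiles,
                "substituent_class": r.substituent_class,
                "tau_cal": r.tau_cal,
                "tau_exp": r.tau_exp,
                "k_d": r.k_d,
                "k_i_nlx": r.k_i_nlx,
            }
        )
    pd.DataFrame(rows, columns=list(LIGAND_TABLE_COLUMNS)).to_csv(path, index=False)


def write_results(tables: Mapping[str, pd.DataFrame], outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write result tables as ``<name>.csv`` plus a units sidecar.

    Output is reproducible byte-for-byte for fixed inputs: stable column
    order, no index column, default pandas float formatting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    schema: Dict[str, Dict[str, str]] = {}
    for name, table in tables.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        written[name] = p
        schema[name] = {
            col: COLUMN_UNITS.get(col, "dimensionless") for col in table.columns
        }
    with (outdir / "schema.json").open("w") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return written
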