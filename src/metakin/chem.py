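"""Log-scale kinetics correlations and ligand similarity.

Calculated residence times are compared with experimental residence
times, dissociation constants (K_d = k_off/k_on) and naloxone inhibitory
constants (K_i,NLX) by Pearson correlation of the log10-transformed
values, with pairwise exclusion of unmeasured compounds and an optional
subset rule that separates out the R2-modified analogs (which are nearly
indistinguishable from the parent compound and dilute the correlation).
Chemical similarity between ligands is summarised as a Tanimoto matrix on
binary fingerprints.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator
from rdkit.DataStructs import TanimotoSimilarity
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError, ValidationError
from .ligands import LigandRecord, ligand_fixture

__all__ = [
    "CorrelationResult",
    "pearson_log",
    "subset_exclude_R2",
    "tanimoto_matrix",
    "correlation_table",
]


@dataclass
class CorrelationResult:
    """Pearson correlation between two log10-transformed quantities."""

    x_field: str
    y_field: str
    subset: str
    n: int
    pearson_r: float
    slope: float  # regression of log10(y) on log10(x)
    intercept: float
    excluded: Tuple[str, ...] = ()  # ligands dropped for missing values


def subset_exclude_R2(records: Sequence[LigandRecord]) -> List[LigandRecord]:
    """Drop the R2-modified compounds; keep parent, R1/R4-modified, morphinans."""
    return [r for r in records if r.substituent_class != "R2_modified"]


def pearson_log(
    records: Sequence[LigandRecord],
    x_field: str,
    y_field: str,
    subset: Optional[Callable[[Sequence[LigandRecord]], Sequence[LigandRecord]]] = None,
    subset_name: str = "all",
) -> CorrelationResult:
    """Pearson r between log10(x) and log10(y) over qualifying records.

    Records failing the subset rule or missing either field are excluded
    (the excluded ids are reported); at least 3 qualifying records are
    required.
    """
    pool = list(records) if subset is None else list(subset(records))
    xs, ys, excluded = [], [], []
    for r in pool:
        x, y = getattr(r, x_field), getattr(r, y_field)
        if x is None or y is None:
            excluded.append(r.ligand_id)
            continue
        xs.append(np.log10(x))
        ys.append(np.log10(y))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"only {len(xs)} records have both {x_field!r} and {y_field!r}"
        )
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    r = stats.pearsonr(xs_a, ys_a)
    reg = stats.linregress(xs_a, ys_a)
    return CorrelationResult(
        x_field=x_field,
        y_field=y_field,
        subset=subset_name,
        n=len(xs),
        pearson_r=float(r.statistic),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        excluded=tuple(excluded),
    )


def correlation_table(records: Sequence[LigandRecord]) -> pd.DataFrame:
    """The standard set of kinetics correlations as one table.

    Rows: tau_cal vs tau_exp (all measured), tau_cal vs tau_exp excluding
    the R2-modified analogs, tau_cal vs K_d, tau_cal vs K_i,NLX.
    """
    rows = []
    specs = [
        ("tau_cal", "tau_exp", None, "all"),
        ("tau_cal", "tau_exp", subset_exclude_R2, "no_R2"),
        ("tau_cal", "k_d", None, "all"),
        ("tau_cal", "k_i_nlx", None, "all"),
    ]
    for x, y, sub, name in specs:
        res = pearson_log(records, x, y, subset=sub, subset_name=name)
        rows.append(
            {
                "x": res.x_field, "y": res.y_field, "subset": res.subset,
                "n": res.n, "pearson_r": res.pearson_r,
                "slope": res.slope, "intercept": res.intercept,
            }
        )
    return pd.DataFrame(rows)


def _fingerprint(mol, kind: str, radius: int, n_bits: int):
    if kind == "morgan":
        return GetMorganGenerator(radius=radius, fpSize=n_bits).GetFingerprint(mol)
    if kind == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    raise InvalidParameterError(f"unknown fingerprint kind {kind!r}")


def tanimoto_matrix(
    records: Sequence[LigandRecord],
    kind: str = "morgan",
    radius: int = 2,
    n_bits: int = 2048,
) -> pd.DataFrame:
    """Symmetric Tanimoto similarity matrix over the ligand panel.

    Default fingerprint: circular (Morgan), radius 2, 2048 bits; MACCS
    keys available via ``kind="maccs"``. Diagonal is 1 by construction.
    """
    fps, ids = [], []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            raise ValidationError(f"SMILES of ligand {r.ligand_id!r} does not parse")
        fps.append(_fingerprint(mol, kind, radius, n_bits))
        ids.append(r.ligand_id)
    n = len(fps)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = TanimotoSimilarity(fps[i], fps[j])
    return pd.DataFrame(mat, index=ids, columns=ids)
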