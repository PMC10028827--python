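"""Ligand records for the 19-compound opioid panel.

The panel comprises fentanyl (FEN), six analogs modified mainly at the R2
position of the 4-anilidopiperidine scaffold (BUF, FBUF, FIBUF, IBUF, VAF,
FUR), eight analogs modified at R1 and/or R4 (MNFEN, MNCAR, CAR, LOF, METM,
SUF, ALF, REMI), and four morphinans (MOP, BUP, NLX, NTX).

Kinetic and affinity values attached by :func:`ligand_fixture` are a
SYNTHETIC stand-in table: plausible numbers encoding only the qualitative
ordering of the compounds (e.g. BUP and CAR slowest to dissociate, ALF
fastest with the weakest affinity), intended for exercising the correlation
machinery. They are not measurements.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["LigandRecord", "ligand_fixture", "SUBSTITUENT_CLASSES"]


@dataclass
class LigandRecord:
    """Identity, chemistry and kinetic/affinity constants of one ligand.

    ``tau_cal`` / ``tau_exp`` are residence times in seconds; ``k_d`` is the
    equilibrium dissociation constant in nM; ``k_i_nlx`` is the naloxone
    inhibitory constant in nM. Optional fields are ``None`` when unmeasured.
    """

    ligand_id: str
    smiles: str
    substituent_class: str  # parent | R2_modified | R1_R4_modified | morphinan
    tau_cal: Optional[float] = None
    tau_exp: Optional[float] = None
    k_d: Optional[float] = None
    k_i_nlx: Optional[float] = None

    def __post_init__(self) -> None:
        allowed = {"parent", "R2_modified", "R1_R4_modified", "morphinan"}
        if self.substituent_class not in allowed:
            raise ValueError(
                f"unknown substituent class {self.substituent_class!r} "
                f"for {self.ligand_id!r}"
            )
        for name in ("tau_cal", "tau_exp", "k_d", "k_i_nlx"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive for {self.ligand_id!r}")


SUBSTITUENT_CLASSES = {
    "FEN": "parent",
    "BUF": "R2_modified",
    "FBUF": "R2_modified",
    "FIBUF": "R2_modified",
    "IBUF": "R2_modified",
    "VAF": "R2_modified",
    "FUR": "R2_modified",
    "MNFEN": "R1_R4_modified",
    "MNCAR": "R1_R4_modified",
    "CAR": "R1_R4_modified",
    "LOF": "R1_R4_modified",
    "METM": "R1_R4_modified",
    "SUF": "R1_R4_modified",
    "ALF": "R1_R4_modified",
    "REMI": "R1_R4_modified",
    "MOP": "morphinan",
    "BUP": "morphinan",
    "NLX": "morphinan",
    "NTX": "morphinan",
}

_SMILES = {
    "FEN": "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "BUF": "CCCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "FBUF": "CCCC(=O)N(c1ccc(F)cc1)C1CCN(CCc2ccccc2)CC1",
    "FIBUF": "CC(C)C(=O)N(c1ccc(F)cc1)C1CCN(CCc2ccccc2)CC1",
    "IBUF": "CC(C)C(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "VAF": "CCCCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "FUR": "O=C(c1ccco1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1",
    "MNFEN": "CCC(=O)N(c1ccccc1)C1CCN(C)CC1",
    "MNCAR": "CCC(=O)N(c1ccccc1)C1(C(=O)OC)CCN(C)CC1",
    "CAR": "CCC(=O)N(c1ccccc1)C1(C(=O)OC)CCN(CCc2ccccc2)CC1",
    "LOF": "CCC(=O)N(c1ccccc1)C1(C(=O)OC)CC(C)N(CCc2ccccc2)CC1",
    "METM": "CCC(=O)N(c1ccccc1)C1(COC)CCN(CCc2ccccc2)CC1",
    "SUF": "CCC(=O)N(c1ccccc1)C1(COC)CCN(CCc2cccs2)CC1",
    "ALF": "CCN1N=NN(CCN2CCC(COC)(N(C(=O)CC)c3ccccc3)CC2)C1=O",
    "REMI": "COC(=O)CCN1CCC(C(=O)OC)(N(C(=O)CC)c2ccccc2)CC1",
    "MOP": "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5",
    "BUP": "COC12CCC3(CC1C(C)(O)C(C)(C)C)C1Cc4ccc(O)c5c4C3(CCN1CC1CC1)C2O5",
    "NLX": "C=CCN1CCC23c4c5ccc(O)c4OC2C(=O)CCC3(O)C1C5",
    "NTX": "O=C1CCC2(O)C3Cc4ccc(O)c5c4C2(CCN3CC2CC2)C1O5",
}

# SYNTHETIC stand-in kinetics (seconds / nM). Chosen once to respect the
# qualitative ordering described above; None = not measured.
# columns: tau_cal, tau_exp, k_d, k_i_nlx
_KINETICS = {
    "FEN": (38.0, 240.0, 1.0, 8.0),
    "BUF": (25.0, 300.0, 1.5, 6.0),
    "FBUF": (15.0, 150.0, 2.5, 4.0),
    "FIBUF": (20.0, 100.0, 2.0, 5.0),
    "IBUF": (50.0, 250.0, 0.8, 10.0),
    "VAF": (40.0, None, None, None),
    "FUR": (30.0, 350.0, 1.2, 7.0),
    "MNFEN": (2.0, None, None, None),
    "MNCAR": (1.5, None, None, None),
    "CAR": (300.0, 3000.0, 0.02, 50.0),
    "LOF": (150.0, None, None, None),
    "METM": (60.0, None, None, None),
    "SUF": (80.0, 500.0, 0.15, 20.0),
    "ALF": (0.2, 60.0, 600.0, None),
    "REMI": (6.0, 600.0, 100.0, None),
    "MOP": (20.0, None, None, None),
    "BUP": (500.0, 5000.0, 0.08, 80.0),
    "NLX": (12.0, 30.0, 2.0, 3.0),
    "NTX": (15.0, None, None, None),
}


def ligand_fixture() -> list[LigandRecord]:
    """The 19-ligand panel with synthetic stand-in kinetic constants.

    Returns one :class:`LigandRecord` per compound, in a fixed order
    (fentanyl, R2-modified analogs, R1/R4-modified analogs, morphinans).
    """
    records = []
    for lid in SUBSTITUENT_CLASSES:
        tau_cal, tau_exp, k_d, k_i = _KINETICS[lid]
        records.append(
            LigandRecord(
                ligand_id=lid,
                smiles=_SMILES[lid],
                substituent_class=SUBSTITUENT_CLASSES[lid],
                tau_cal=tau_cal,
                tau_exp=tau_exp,
                k_d=k_d,
                k_i_nlx=k_i,
            )
        )
    return records
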