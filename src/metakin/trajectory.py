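"""Per-trajectory container for biased unbinding runs.

A :class:`BiasedTrajectory` holds the per-frame record of one infrequent
metadynamics unbinding simulation: the frame time (ps), the ligand z
position relative to the orthosteric site (angstrom), the ligand-receptor
contact count, and the instantaneous metadynamics bias evaluated at the
frame's collective-variable values (kcal/mol).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .exceptions import InvalidInputError

__all__ = ["BiasedTrajectory"]


@dataclass
class BiasedTrajectory:
    """Frame record of one biased unbinding trajectory.

    Parameters
    ----------
    ligand_id
        Token identifying the ligand this trajectory belongs to.
    time
        Frame times in ps, strictly increasing.
    z
        Ligand z position per frame, angstrom.
    contacts
        Ligand-receptor contact count per frame (dimensionless).
    bias
        Instantaneous deposited bias per frame, kcal/mol. Finite.
    temperature
        Simulation temperature in kelvin.
    """

    ligand_id: str
    time: np.ndarray
    z: np.ndarray
    contacts: np.ndarray
    bias: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        n = self.time.size
        if n < 2:
            raise InvalidInputError(
                f"trajectory {self.ligand_id!r} needs at least 2 frames, got {n}"
            )
        for name, arr in (("z", self.z), ("contacts", self.contacts), ("bias", self.bias)):
            if arr.size != n:
                raise InvalidInputError(
                    f"trajectory {self.ligand_id!r}: column {name!r} has length "
                    f"{arr.size}, expected {n}"
                )
        if not np.all(np.diff(self.time) > 0):
            raise InvalidInputError(
                f"trajectory {self.ligand_id!r}: frame times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.bias)):
            raise InvalidInputError(
                f"trajectory {self.ligand_id!r}: bias values must be finite"
            )
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    def __len__(self) -> int:
        return self.n_frames
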