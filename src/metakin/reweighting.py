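"""Unbiased distributions and free-energy surfaces from biased frames.

Frames generated under a metadynamics bias V are reweighted with
``w_i ∝ exp(+V_i/kT)`` (static reweighting by the recorded instantaneous
bias). Weighted histograms give unbiased probability densities; the
free-energy surface over a collective variable x is
``F(x) = -kT ln p(x)``, shifted so its occupied minimum is zero. Basins of
the surface are found by a watershed with persistence-based merging of
shallow saddles, and binding modes are assigned by testing basin minima
against named distance windows (salt-bridge, hydrogen-bond, loosely-bound
boxes on the amine-D147 / amine-H297 distance plane).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .constants import DEFAULT_TEMPERATURE, beta, kt
from .exceptions import EmptyDensityError, InvalidInputError

__all__ = [
    "WeightedEnsemble",
    "FreeEnergySurface",
    "Basin",
    "frame_weights",
    "reweighted_histogram",
    "fes",
    "locate_basins",
    "classify_binding_mode",
    "default_binding_mode_boxes",
]

#: Default bin widths by observable kind (angstrom, kcal/mol, degrees).
DEFAULT_BIN_WIDTHS = {"distance": 0.25, "energy": 0.5, "angle": 5.0}


def frame_weights(bias_series: np.ndarray, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Normalised unbiasing weights w_i = exp(V_i/kT) / sum_j exp(V_j/kT).

    Computed with a max-shift for numerical stability; invariant to adding
    a constant to all biases.
    """
    v = np.asarray(bias_series, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty bias series")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("bias series must be finite")
    bv = beta(temperature) * v
    bv -= bv.max()
    w = np.exp(bv)
    return w / w.sum()


@dataclass
class WeightedEnsemble:
    """Frame observables with normalised unbiasing weights.

    ``values`` is (n,) for one observable or (n, d) for d observables per
    frame; ``weights`` must be non-negative and sum to 1.
    """

    values: np.ndarray
    weights: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.values.shape[0]
        if self.weights.shape != (n,):
            raise InvalidInputError("weights must be one per frame")
        if np.any(self.weights < 0):
            raise InvalidInputError("weights must be non-negative")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise InvalidInputError("weights must sum to 1")

    @classmethod
    def from_bias(
        cls,
        values: np.ndarray,
        bias: np.ndarray,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "WeightedEnsemble":
        """Build an ensemble by reweighting frames with their recorded bias."""
        return cls(values=np.asarray(values, dtype=float),
                   weights=frame_weights(bias, temperature),
                   temperature=temperature)

    @property
    def ndim(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]


BinsSpec = Union[int, np.ndarray, Sequence]


def reweighted_histogram(
    ensemble: WeightedEnsemble, bins: BinsSpec
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Weighted probability density over ``bins``.

    Returns ``(density, edges)``; the density integrates to 1 over the
    occupied bins. Raises :class:`EmptyDensityError` when no weight falls
    inside the binning.
    """
    if ensemble.ndim == 1:
        hist, edges = np.histogram(ensemble.values, bins=bins, weights=ensemble.weights)
        edges_list = [edges]
        widths = np.diff(edges)
        volume = widths
    elif ensemble.ndim == 2:
        hist, ex, ey = np.histogram2d(
            ensemble.values[:, 0], ensemble.values[:, 1],
            bins=bins, weights=ensemble.weights,
        )
        edges_list = [ex, ey]
        volume = np.outer(np.diff(ex), np.diff(ey))
    else:
        raise InvalidInputError("only 1D and 2D observables are supported")
    total = hist.sum()
    if total <= 0:
        raise EmptyDensityError("no probability mass inside the requested bins")
    density = hist / (total * volume)
    return density, edges_list


@dataclass
class FreeEnergySurface:
    """Free energy (kcal/mol) per bin over a 1D or 2D grid.

    Unoccupied bins are flagged in ``occupied`` and hold NaN; the minimum
    over occupied bins is zero.
    """

    edges: List[np.ndarray]
    free_energy: np.ndarray
    occupied: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])


def fes(ensemble: WeightedEnsemble, bins: BinsSpec) -> FreeEnergySurface:
    """Free-energy surface F = -kT ln(density), shifted to min 0."""
    density, edges = reweighted_histogram(ensemble, bins)
    occupied = density > 0
    f = np.full(density.shape, np.nan)
    f[occupied] = -kt(ensemble.temperature) * np.log(density[occupied])
    f[occupied] -= np.nanmin(f[occupied])
    return FreeEnergySurface(
        edges=edges, free_energy=f, occupied=occupied,
        temperature=ensemble.temperature,
    )


@dataclass
class Basin:
    """One free-energy basin: its minimum and member bins."""

    min_value: float  # kcal/mol, on the FES scale (global min = 0)
    min_location: Tuple[float, ...]  # bin centers of the minimum
    min_index: Tuple[int, ...]
    bins: List[Tuple[int, ...]] = field(default_factory=list)


def _neighbors(idx: Tuple[int, ...], shape: Tuple[int, ...]):
    for axis in range(len(shape)):
        for step in (-1, 1):
            j = list(idx)
            j[axis] += step
            if 0 <= j[axis] < shape[axis]:
                yield tuple(j)


def locate_basins(surface: FreeEnergySurface, depth_cutoff: float = 1.0) -> List[Basin]:
    """Find FES basins, merging minima separated by shallow saddles.

    Occupied bins are visited in order of increasing free energy
    (watershed). A bin adjacent to no existing basin seeds a new one; a bin
    bridging several basins merges any basin whose persistence (saddle
    height above its own minimum) is below ``depth_cutoff`` into the
    deepest neighbour. Reported basin membership is restricted to bins
    within ``depth_cutoff`` of the basin minimum.
    """
    occ_idx = np.argwhere(surface.occupied)
    if occ_idx.size == 0:
        raise EmptyDensityError("free-energy surface has no occupied bins")
    f = surface.free_energy
    order = np.argsort(f[tuple(occ_idx.T)], kind="stable")
    shape = f.shape

    label: Dict[Tuple[int, ...], int] = {}
    parent: List[int] = []
    min_val: List[float] = []
    min_idx: List[Tuple[int, ...]] = []

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for flat in order:
        idx = tuple(occ_idx[flat])
        fv = f[idx]
        roots = sorted(
            {find(label[nb]) for nb in _neighbors(idx, shape) if nb in label},
            key=lambda r: min_val[r],
        )
        if not roots:
            label[idx] = len(parent)
            parent.append(len(parent))
            min_val.append(float(fv))
            min_idx.append(idx)
            continue
        deepest = roots[0]
        label[idx] = deepest
        for r in roots[1:]:
            # saddle at fv: merge r if its persistence is below the cutoff
            if fv - min_val[r] < depth_cutoff:
                parent[r] = deepest
    # collect members
    basins: Dict[int, Basin] = {}
    for idx, lab in label.items():
        root = find(lab)
        if root not in basins:
            loc = tuple(
                float(surface.centers(ax)[min_idx[root][ax]])
                for ax in range(surface.ndim)
            )
            basins[root] = Basin(
                min_value=min_val[root], min_location=loc, min_index=min_idx[root]
            )
        if f[idx] <= min_val[root] + depth_cutoff:
            basins[root].bins.append(idx)
    return sorted(basins.values(), key=lambda b: b.min_value)


def default_binding_mode_boxes(
    d147_max: float = 4.0,
    h297_max: float = 4.0,
    loose_box: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = (
        (7.0, 9.0),
        (13.0, 15.0),
    ),
) -> Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]]:
    """Named distance windows on the (amine-D147, amine-H297) plane.

    Salt-bridge / hydrogen-bond windows default to a minimum distance of
    4 angstrom on their respective axis; the loosely-bound window follows
    the 7-9 / 13-15 angstrom box observed for partial agonists.
    """
    boxes = {
        "D147 salt bridge": ((0.0, d147_max), (0.0, np.inf)),
        "H297 h-bond": ((0.0, np.inf), (0.0, h297_max)),
    }
    if loose_box is not None:
        boxes["loosely bound"] = loose_box
    return boxes


def classify_binding_mode(
    basins: Sequence[Basin],
    boxes: Optional[Dict[str, Tuple[Tuple[float, float], Tuple[float, float]]]] = None,
) -> set:
    """Binding modes whose window contains at least one basin minimum."""
    if boxes is None:
        boxes = default_binding_mode_boxes()
    modes = set()
    for name, box in boxes.items():
        for basin in basins:
            inside = all(
                lo <= basin.min_location[ax] <= hi
                for ax, (lo, hi) in enumerate(box)
            )
            if inside:
                modes.add(name)
                break
    return modes
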