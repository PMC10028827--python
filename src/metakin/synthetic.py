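"""Synthetic biased unbinding trajectories and feature datasets.

Every downstream stage of the pipeline can be validated against ground
truth without any simulation data:

* :func:`gen_unbinding_trajectories` draws true rescaled dissociation times
  from an exponential distribution (the homogeneous-Poisson assumption the
  residence-time estimator relies on) and converts each into a biased
  trajectory by integrating the acceleration factor exp(beta*V(t)) along a
  deterministic bias schedule until the drawn rescaled time is consumed.
  The kinetics stage, run on the emitted frames, must recover the drawn
  times exactly (up to one frame's rescaled increment) and hence the true
  residence time statistically.
* :func:`gen_feature_dataset` emits per-ligand frame-level
  residue-substituent interaction-energy tables in which log10 of the
  residence time depends linearly on a small set of planted pair means, so
  feature-importance machinery has a known answer to recover.

The bias schedule is deliberately a scalar deterministic profile rather
than a two-dimensional well-tempered potential: only the accumulated
acceleration exp(beta*V) along the escape path enters the rescaling, so a
scalar schedule preserves exactly the statistical structure the estimator
assumes while remaining analytically checkable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, PS_PER_S, beta
from .exceptions import InvalidParameterError
from .ligands import LigandRecord, ligand_fixture  # re-exported fixture
from .trajectory import BiasedTrajectory

__all__ = [
    "BiasSchedule",
    "SyntheticTruth",
    "gen_unbinding_trajectories",
    "gen_feature_dataset",
    "ligand_fixture",
    "DEFAULT_RESIDUES",
    "default_planted_weights",
]

#: Binding-site residue tokens used for synthetic pair names.
DEFAULT_RESIDUES = (
    "D147", "H297", "W293", "M151", "S154", "W318", "Y148", "I296",
    "V300", "N150", "K233", "V236", "I322", "Y326", "Q124", "W133",
    "C217", "T218", "L219", "E229", "A240", "F241", "L232", "N127",
)


@dataclass
class BiasSchedule:
    """Deterministic scalar metadynamics-like bias profile V(t).

    Parameters
    ----------
    deposition_stride
        Time between bias depositions (and between emitted frames), ps.
    hill_height
        Bias increment scale per deposition, kcal/mol.
    growth_model
        ``"step_ramp"``: V after k depositions is ``hill_height * k``
        (linear growth, exponential acceleration).
        ``"saturating"``: ``bias_scale * ln(1 + hill_height*k/bias_scale)``
        (logarithmic growth, power-law acceleration — the long-time
        behaviour of a well-tempered bias).
    bias_cap
        Hard upper bound on the bias, kcal/mol.
    bias_scale
        Tempering scale of the saturating model, kcal/mol.
    temperature
        Temperature in kelvin used for beta.
    """

    deposition_stride: float = 10.0
    hill_height: float = 0.5
    growth_model: str = "saturating"
    bias_cap: float = 25.0
    bias_scale: float = 2.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.deposition_stride <= 0:
            raise InvalidParameterError("deposition_stride must be positive")
        if self.hill_height < 0:
            raise InvalidParameterError("hill_height must be non-negative")
        if self.bias_cap < 0:
            raise InvalidParameterError("bias_cap must be non-negative")
        if self.growth_model not in ("step_ramp", "saturating"):
            raise InvalidParameterError(
                f"unknown growth_model {self.growth_model!r}"
            )
        if self.growth_model == "saturating" and self.bias_scale <= 0:
            raise InvalidParameterError("bias_scale must be positive")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")

    def bias_at(self, k: np.ndarray) -> np.ndarray:
        """Bias (kcal/mol) after ``k`` depositions (k >= 0, vectorised)."""
        k = np.asarray(k, dtype=float)
        if self.growth_model == "step_ramp":
            v = self.hill_height * k
        else:
            v = self.bias_scale * np.log1p(self.hill_height * k / self.bias_scale)
        return np.minimum(v, self.bias_cap)


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic dataset."""

    tau_true: float  # seconds
    rescaled_times_true: np.ndarray  # seconds, i.i.d. Exp(tau_true)
    planted_weights: Dict[Tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0  # log10 s
    seed: int = 0


def _rescaled_increments(schedule: BiasSchedule, n: int) -> np.ndarray:
    """Rescaled-time increment (ps) contributed by frames 1..n.

    Overflow to inf is harmless: it only means the event lands before the
    overflowing frame for any drawn target.
    """
    k = np.arange(1, n + 1)
    b = beta(schedule.temperature)
    with np.errstate(over="ignore"):
        return schedule.deposition_stride * np.exp(b * schedule.bias_at(k))


def gen_unbinding_trajectories(
    tau_true: float,
    schedule: Optional[BiasSchedule] = None,
    n_traj: int = 15,
    seed: int = 0,
    ligand_id: str = "LIG",
    n_post_frames: int = 5,
    max_frames: int = 20_000_000,
) -> Tuple[List[BiasedTrajectory], SyntheticTruth]:
    """Draw exponential unbinding times and emit matching biased trajectories.

    For each trajectory a target rescaled time ``T* = -tau_true*ln(u)`` is
    drawn (seconds); frames are emitted every ``deposition_stride`` ps and
    the accumulated rescaled time ``sum dt*exp(beta*V)`` is integrated along
    the schedule until it reaches ``T*``. The z trace rises from the bound
    state (~2 A) and crosses the 15 A unbinding threshold exactly at the
    event frame; the contact count is anti-correlated with z.

    Returns the trajectories and a :class:`SyntheticTruth` carrying
    ``tau_true`` and the drawn rescaled times.
    """
    if tau_true <= 0:
        raise InvalidParameterError(f"tau_true must be positive, got {tau_true}")
    if n_traj < 1:
        raise InvalidParameterError("n_traj must be >= 1")
    schedule = schedule if schedule is not None else BiasSchedule()

    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_traj)
    t_star_s = -tau_true * np.log(u)
    t_star_ps = t_star_s * PS_PER_S

    # Shared deterministic cumulative rescaled time; grow until it covers
    # the largest drawn target.
    n_grid = 4096
    with np.errstate(over="ignore"):
        cum = np.cumsum(_rescaled_increments(schedule, n_grid))
        while cum[-1] < t_star_ps.max():
            if 2 * n_grid > max_frames:
                raise InvalidParameterError(
                    "bias schedule too weak to reach the drawn unbinding times "
                    f"within {max_frames} frames; increase hill_height/bias_cap"
                )
            n_grid *= 2
            cum = np.cumsum(_rescaled_increments(schedule, n_grid))

    event_idx = np.searchsorted(cum, t_star_ps, side="left")  # 0-based frame
    dt = schedule.deposition_stride
    trajectories: List[BiasedTrajectory] = []
    for i in range(n_traj):
        ev = int(event_idx[i])  # frames 1..ev are pre-event, frame ev+1 is the event
        n_pre = ev  # number of bound frames before the crossing frame
        n_tot = n_pre + 1 + n_post_frames
        kk = np.arange(1, n_tot + 1)
        time = dt * kk
        bias_v = schedule.bias_at(kk)

        z = np.empty(n_tot)
        if n_pre > 0:
            frac = np.arange(1, n_pre + 1) / (n_pre + 1)
            z_pre = 2.0 + 12.5 * frac + rng.normal(0.0, 0.4, size=n_pre)
            z[:n_pre] = np.clip(z_pre, 0.5, 14.8)
        z[n_pre] = 15.2 + abs(rng.normal(0.3, 0.1))
        z[n_pre + 1:] = (
            z[n_pre]
            + 1.5 * np.arange(1, n_post_frames + 1)
            + rng.normal(0.0, 0.2, size=n_post_frames)
        )
        z[n_pre + 1:] = np.maximum(z[n_pre + 1:], 15.05)

        contacts = np.clip(
            np.round(40.0 * (1.0 - z / 15.0) + rng.normal(0.0, 1.0, size=n_tot)),
            0.0,
            None,
        )
        contacts[n_pre:] = 0.0

        trajectories.append(
            BiasedTrajectory(
                ligand_id=ligand_id,
                time=time,
                z=z,
                contacts=contacts,
                bias=bias_v,
                temperature=schedule.temperature,
            )
        )

    truth = SyntheticTruth(
        tau_true=float(tau_true),
        rescaled_times_true=t_star_s,
        seed=seed,
    )
    return trajectories, truth


def default_planted_weights() -> Dict[Tuple[str, str], float]:
    """Three planted kinetic modulators (log10 s per kcal/mol).

    Negative weights encode "stronger (more negative) interaction energy
    lengthens the residence time", mirroring the H297/W293/M151-type
    modulators the feature ranking is expected to surface.
    """
    return {
        ("H297", "R4"): -0.5,
        ("W293", "R1"): -0.4,
        ("M151", "R1"): -0.35,
    }


def gen_feature_dataset(
    n_ligands: int = 19,
    n_pairs: int = 24,
    planted_weights: Optional[Dict[Tuple[str, str], float]] = None,
    noise_sd: float = 0.05,
    frames_per_ligand: int = 2000,
    seed: int = 0,
    sigma_frame: float = 2.0,
    exit_fraction: float = 0.1,
    strong_null_pair: Tuple[str, str] = ("D147", "R1"),
) -> Tuple[Dict[str, pd.DataFrame], pd.Series, SyntheticTruth]:
    """Per-ligand frame-level interaction-energy tables with planted kinetics.

    Per-ligand pair means ``mu_ij`` are drawn around per-pair base levels;
    frame energies scatter around the means with ``sigma_frame``; the target
    is ``log10 tau_i = sum_j w_j * mu_ij + eps_i`` with
    ``eps ~ Normal(0, noise_sd)`` and ``w_j = 0`` for non-planted pairs.

    The ``strong_null_pair`` is given the largest-magnitude base level
    (~ -15 kcal/mol) but zero weight: a maximally strong yet kinetically
    uninformative interaction, the synthetic analogue of a dominant
    anchoring salt bridge shared by all ligands.

    Returns ``(tables, log10_tau, truth)`` where ``tables`` maps ligand id
    to an energy table (one row per frame x pair) and ``log10_tau`` is the
    noiseless-plus-eps target per ligand.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if frames_per_ligand < 1:
        raise InvalidParameterError("frames_per_ligand must be >= 1")
    weights = (
        dict(planted_weights) if planted_weights is not None
        else default_planted_weights()
    )
    # build the pair list: planted pairs + strong null pair + filler pairs
    pairs: List[Tuple[str, str]] = list(weights)
    if strong_null_pair not in pairs:
        pairs.append(strong_null_pair)
    subs = ("R1", "R2", "R4")
    for res in DEFAULT_RESIDUES:
        for sub in subs:
            if len(pairs) >= n_pairs:
                break
            if (res, sub) not in pairs:
                pairs.append((res, sub))
        if len(pairs) >= n_pairs:
            break
    if n_pairs < len(weights):
        raise InvalidParameterError(
            f"n_pairs={n_pairs} is smaller than the number of planted pairs "
            f"({len(weights)})"
        )
    if len(pairs) < n_pairs:
        raise InvalidParameterError("not enough residue tokens for n_pairs")
    pairs = pairs[:n_pairs]

    rng = np.random.default_rng(seed)
    base = rng.normal(-3.0, 2.0, size=n_pairs)
    if strong_null_pair in pairs:
        base[pairs.index(strong_null_pair)] = -15.0
    spread = rng.uniform(0.6, 1.4, size=n_pairs)
    # a kinetic modulator must differ between ligands to modulate kinetics:
    # planted pairs carry a strong fixed cross-ligand spread
    for pair in weights:
        if pair in pairs:
            spread[pairs.index(pair)] = 1.5

    ligand_ids = [f"L{i + 1:02d}" for i in range(n_ligands)]
    mu = base[None, :] + rng.normal(size=(n_ligands, n_pairs)) * spread[None, :]

    w = np.array([weights.get(p, 0.0) for p in pairs])
    eps = rng.normal(0.0, noise_sd, size=n_ligands) if noise_sd > 0 else np.zeros(n_ligands)
    log10_tau = pd.Series(mu @ w + eps, index=ligand_ids, name="log10_tau")

    n_exit = int(round(exit_fraction * frames_per_ligand))
    tables: Dict[str, pd.DataFrame] = {}
    for i, lid in enumerate(ligand_ids):
        frame_time = 10.0 * np.arange(1, frames_per_ligand + 1)
        traj_id = np.array([f"t{j % 15:02d}" for j in range(frames_per_ligand)])
        z = rng.uniform(2.0, 12.0, size=frames_per_ligand)
        if n_exit > 0:
            exit_rows = rng.choice(frames_per_ligand, size=n_exit, replace=False)
            z[exit_rows] = rng.uniform(15.5, 25.0, size=n_exit)
        bias_f = rng.uniform(0.0, 1.5, size=frames_per_ligand)
        energies = mu[i][None, :] + rng.normal(
            size=(frames_per_ligand, n_pairs)
        ) * sigma_frame
        tables[lid] = pd.DataFrame(
            {
                "ligand_id": np.repeat(lid, frames_per_ligand * n_pairs),
                "trajectory_id": np.repeat(traj_id, n_pairs),
                "frame_time": np.repeat(frame_time, n_pairs),
                "residue_id": np.tile([p[0] for p in pairs], frames_per_ligand),
                "substituent": np.tile([p[1] for p in pairs], frames_per_ligand),
                "energy": energies.ravel(),
                "frame_bias": np.repeat(bias_f, n_pairs),
                "z": np.repeat(z, n_pairs),
            }
        )

    truth = SyntheticTruth(
        tau_true=float("nan"),
        rescaled_times_true=np.array([]),
        planted_weights=weights,
        noise_sd=noise_sd,
        seed=seed,
    )
    return tables, log10_tau, truth
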