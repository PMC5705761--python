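"""Three-state coarse-graining of the period-averaged velocity.

In the deterministic limit the ratchet has three coexisting attractors of the
period-averaged velocity: two running states v± ≈ ±0.4 and a locked state
v₀ ≈ 0.  At finite temperature, thermal fluctuations induce transitions
between the corresponding velocity bands; this module estimates the
conditional transition probabilities p_ij and the occupation probabilities of
the bands, and identifies the deterministic attractors by clustering.

The coarse-graining assigns a window velocity v to the band
[center − ν, center + ν) of the nearest state center (default centers
−0.4, 0, 0.4 with threshold ν = 0.2); velocities outside every band map to an
auxiliary ``OTHER`` symbol, reported separately from the 3×3 matrix.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError
from .observables import PeriodVelocityRecord


class State(enum.IntEnum):
    MINUS = 0
    ZERO = 1
    PLUS = 2
    OTHER = 3


STATE_LABELS = {State.MINUS: "-", State.ZERO: "0", State.PLUS: "+", State.OTHER: "other"}


@dataclass(frozen=True)
class StateModel:
    """Velocity-band model: state centers, half-width ν, and comparison lag.

    Bands are the half-open intervals [center − ν, center + ν), scanned in
    ascending center order; with the default touching bands a value on a
    shared edge belongs to the band whose lower endpoint it is.  ``lag``
    counts drive periods between compared windows.
    """

    centers: tuple[float, float, float] = (-0.4, 0.0, 0.4)
    nu: float = 0.2
    lag: int = 1

    def __post_init__(self):
        if not self.nu > 0:
            raise InvalidInputError("threshold nu must be strictly positive")
        c = np.asarray(self.centers, dtype=float)
        if len(c) != 3 or not np.all(np.diff(c) > 0):
            raise InvalidInputError("centers must be three strictly increasing values")
        if np.any(np.diff(c) < 2 * self.nu - 1e-12):
            raise InvalidInputError("bands overlap: centers closer than 2*nu")
        if self.lag < 1:
            raise InvalidInputError("lag must be at least one window")


@dataclass
class StateSequence:
    """Per-trajectory symbol sequences (codes from :class:`State`)."""

    codes: np.ndarray  # (n_traj, n_windows), int8
    window_starts: np.ndarray
    model: StateModel


@dataclass
class TransitionMatrix:
    """Conditional probabilities p_ij among {−, 0, +} plus the auxiliary OTHER.

    ``counts`` and ``probs`` are 4×4 in the order (−, 0, +, other); rows of
    ``probs`` are normalized over all four destinations, so every defined row
    sums to 1 (the ``defined`` mask flags rows with nonzero counts).
    ``three_state`` is the 3×3 view the physics discussion uses.
    """

    counts: np.ndarray
    probs: np.ndarray
    defined: np.ndarray
    lag: int

    @property
    def three_state(self) -> np.ndarray:
        return self.probs[:3, :3]

    def named(self) -> dict[str, float]:
        out = {}
        for i in (State.MINUS, State.ZERO, State.PLUS):
            for j in (State.MINUS, State.ZERO, State.PLUS):
                out[f"p_{STATE_LABELS[i]}{STATE_LABELS[j]}"] = float(self.probs[i, j])
        return out

    def to_dict(self) -> dict:
        return {
            "lag": self.lag,
            "probabilities": self.named(),
            "counts": self.counts.tolist(),
            "defined_rows": self.defined.tolist(),
        }


@dataclass
class AttractorSet:
    """Clustered period-averaged-velocity attractors with basin weights.

    ``dispersions`` holds each cluster's diameter (max − min member value);
    a diameter above the merge tolerance indicates the transient was too
    short for the window velocities to settle.
    """

    centers: np.ndarray
    fractions: np.ndarray
    dispersions: np.ndarray
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "fractions": self.fractions.tolist(),
            "dispersions": self.dispersions.tolist(),
            "converged": self.converged,
        }


@dataclass
class OccupationEstimate:
    """Occupation probability of one band with binomial (Wilson) uncertainty."""

    probability: float
    stderr: float
    wilson_low: float
    wilson_high: float
    n_samples: int


def coarse_grain(pv: PeriodVelocityRecord, model: StateModel | None = None
                 ) -> StateSequence:
    """Map every window velocity to its unique band symbol (total mapping)."""
    model = model or StateModel()
    v = pv.velocities
    codes = np.full(v.shape, int(State.OTHER), dtype=np.int8)
    for sym, center in zip((State.MINUS, State.ZERO, State.PLUS), model.centers):
        mask = (v >= center - model.nu) & (v < center + model.nu)
        codes[mask & (codes == int(State.OTHER))] = int(sym)
    return StateSequence(codes=codes, window_starts=pv.window_starts, model=model)


def transition_probabilities(
    seqs: StateSequence,
    lag: int | None = None,
    t_range: tuple[float, float] | None = None,
) -> TransitionMatrix:
    """p_ij = count(i at window k, j at window k+lag) / count(i at window k).

    Counts are pooled over trajectories and over all source windows whose
    start time falls in ``t_range`` (default: all).  Rows with zero counts
    are flagged undefined (NaN probabilities) rather than filled.
    """
    lag = lag if lag is not None else seqs.model.lag
    codes = seqs.codes
    if codes.shape[1] <= lag:
        raise InvalidInputError("sequences must be longer than the lag")
    src = codes[:, :-lag]
    dst = codes[:, lag:]
    if t_range is not None:
        starts = seqs.window_starts[:-lag]
        keep = (starts >= t_range[0]) & (starts <= t_range[1])
        src, dst = src[:, keep], dst[:, keep]
    pair = (src.astype(np.int64) * 4 + dst.astype(np.int64)).ravel()
    counts = np.bincount(pair, minlength=16).reshape(4, 4)
    row = counts.sum(axis=1)
    defined = row > 0
    if not defined.any():
        warnings.warn("empty transition pool: all rows undefined", stacklevel=2)
    probs = np.full((4, 4), np.nan)
    probs[defined] = counts[defined] / row[defined, None]
    return TransitionMatrix(counts=counts, probs=probs, defined=defined, lag=lag)


def occupation_probability(
    seqs: StateSequence,
    state: State,
    t_range: tuple[float, float] | None = None,
) -> OccupationEstimate:
    """Fraction of (trajectory, window) pairs in ``state`` within ``t_range``."""
    codes = seqs.codes
    if t_range is not None:
        keep = (seqs.window_starts >= t_range[0]) & (seqs.window_starts <= t_range[1])
        if not keep.any():
            raise InvalidInputError("no windows inside the requested time range")
        codes = codes[:, keep]
    n = codes.size
    k = int((codes == int(state)).sum())
    p = k / n
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return OccupationEstimate(
        probability=p,
        stderr=float(np.sqrt(p * (1 - p) / n)),
        wilson_low=float(lo),
        wilson_high=float(hi),
        n_samples=n,
    )


def occupation_series(seqs: StateSequence) -> dict[State, np.ndarray]:
    """Per-window occupation probability of every symbol (sums to 1 exactly)."""
    n = seqs.codes.shape[0]
    return {s: (seqs.codes == int(s)).sum(axis=0) / n for s in State}


def identify_attractors(values, merge_tol: float = 0.05) -> AttractorSet:
    """Cluster long-time period-averaged velocities into attractors.

    1-D agglomerative (average-linkage) clustering cut at ``merge_tol``;
    centers are cluster means, fractions the basin weights over the supplied
    initial-condition sample.  A cluster whose internal spread exceeds
    ``merge_tol`` flags non-convergence (transient too short).
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InvalidInputError("no attractor values supplied")
    if v.size == 1:
        return AttractorSet(v.copy(), np.array([1.0]), np.array([0.0]))
    Z = hierarchy.linkage(v.reshape(-1, 1), method="average")
    labels = hierarchy.fcluster(Z, t=merge_tol, criterion="distance")
    centers, fractions, dispersions = [], [], []
    for lab in np.unique(labels):
        grp = v[labels == lab]
        centers.append(grp.mean())
        fractions.append(grp.size / v.size)
        dispersions.append(grp.max() - grp.min())
    order = np.argsort(centers)
    centers = np.asarray(centers)[order]
    fractions = np.asarray(fractions)[order]
    dispersions = np.asarray(dispersions)[order]
    converged = bool(np.all(dispersions <= merge_tol))
    if not converged:
        warnings.warn(
            "attractor cluster dispersion exceeds the merge tolerance; "
            "transient may be too short", stacklevel=2,
        )
    return AttractorSet(centers, fractions, dispersions, converged)
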