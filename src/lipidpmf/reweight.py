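"""Binless reweighting of xi1-biased ensembles to unbiased observables.

Frames collected under a ladder of harmonic biases along xi1 are assigned
unbiased statistical weights with the standard binless-WHAM formula

    w_n  propto  1 / sum_j N_j exp(beta * (f_j - u_j(x_n)))

where u_j is window j's bias at the frame's xi1 and the f_j are the
converged WHAM window offsets.  The weights turn biased trajectories into
estimates of any unbiased expectation — in particular 2D free-energy
surfaces over pairs of (xi1, xi2, xi3), which is how orientation
landscapes are obtained from a single-CV sampling campaign.  This assumes
the xi1-biased run sampled the other variables adequately; the count grid
is reported so thin regions can be masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import rt
from .trajio import AnalysisConfig, CVTrajectory, UmbrellaProtocol
from .wham import PMFProfile

__all__ = ["FrameWeights", "FES2D", "frame_weights", "fes_2d",
           "basin_occupancy", "reweighted_profile_xi1"]

_AXES = ("xi1", "xi2", "xi3")


@dataclass
class FrameWeights:
    """Normalised per-frame unbiased weights with their frame CVs.

    Frames are the concatenation of the input trajectories in order.
    ``ess`` is the Kish effective sample size (sum w)^2 / sum w^2.
    """

    weights: np.ndarray
    xi1: np.ndarray
    xi2: np.ndarray | None
    xi3: np.ndarray | None
    normalization: str = "sum-to-one"

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("weights sum to zero")
        self.weights = self.weights / s

    @property
    def ess(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / np.sum(w ** 2))

    def __len__(self) -> int:
        return len(self.weights)

    def axis(self, name: str) -> np.ndarray:
        if name not in _AXES:
            raise ValueError(f"unknown CV {name!r}; expected one of {_AXES}")
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"CV {name!r} not present in frames")
        return v


@dataclass
class FES2D:
    """Reweighted 2D free-energy surface over a pair of CVs.

    ``free_energy`` is NaN on cells with zero count; under the min-zero
    convention the global minimum over finite cells is 0.
    """

    axes: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), kJ/mol
    counts: np.ndarray  # unweighted frame counts per cell
    zero_convention: str = "min-zero"
    temperature: float = 323.0

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def minimum_location(self) -> tuple[float, float]:
        """(x, y) of the global minimum cell."""
        i, j = np.unravel_index(np.nanargmin(self.free_energy),
                                self.free_energy.shape)
        return float(self.x_centers[i]), float(self.y_centers[j])


def _concat(trajs: list[CVTrajectory], name: str) -> np.ndarray | None:
    vals = [getattr(tr, name) for tr in trajs]
    if any(v is None for v in vals):
        return None
    return np.concatenate(vals)


def frame_weights(trajs: list[CVTrajectory], protocol: UmbrellaProtocol,
                  pmf: PMFProfile, *,
                  allow_unconverged: bool = False) -> FrameWeights:
    """Unbiased weights for every frame of a biased multi-window ensemble.

    Deterministic given its inputs.  Refuses unconverged WHAM offsets
    unless ``allow_unconverged=True`` (the override is recorded in a
    warning).
    """
    if not pmf.converged:
        if not allow_unconverged:
            raise ValueError(
                "WHAM offsets are unconverged; pass allow_unconverged=True "
                "to proceed anyway")
        warnings.warn("reweighting with unconverged WHAM offsets (override)")
    kt = rt(protocol.temperature)
    xi1 = np.concatenate([tr.xi1 for tr in trajs])
    # per-window sample counts from the trajectories themselves
    N = np.zeros(protocol.n_windows)
    for tr in trajs:
        wi = tr.window_index
        if isinstance(wi, np.ndarray):
            for i in range(protocol.n_windows):
                N[i] += int(np.sum(wi == i))
        else:
            N[int(wi)] += len(tr)
    if np.any(N == 0):
        missing = np.nonzero(N == 0)[0]
        raise ValueError(f"windows with no frames: {missing.tolist()}")
    c = np.asarray(protocol.centers)[:, None]
    beta_u = 0.5 * protocol.force_constant * (xi1[None, :] - c) ** 2 / kt
    beta_f = (pmf.window_offsets / kt)[:, None]
    log_w = -logsumexp(np.log(N)[:, None] + beta_f - beta_u, axis=0)
    log_w -= logsumexp(log_w)
    return FrameWeights(
        weights=np.exp(log_w), xi1=xi1,
        xi2=_concat(trajs, "xi2"), xi3=_concat(trajs, "xi3"))


def fes_2d(trajs: list[CVTrajectory], weights: FrameWeights,
           pair: tuple[str, str], config: AnalysisConfig,
           *, pad_fraction: float = 0.02) -> FES2D:
    """Weighted 2D free-energy surface over a CV pair.

    The grid spans the observed data range padded by ``pad_fraction`` on
    each side, with ``config.fes_bins`` bins per axis.  Cells with zero
    frames are undefined (NaN).  If more than half the grid cells are
    empty a sampling-adequacy warning is issued.
    """
    xname, yname = pair
    x = weights.axis(xname)
    y = weights.axis(yname)
    n_frames = sum(len(tr) for tr in trajs)
    if n_frames != len(weights):
        raise ValueError(
            f"weights cover {len(weights)} frames but trajectories "
            f"contain {n_frames}")

    def edges(v):
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo or 1e-9
        return np.linspace(lo - pad_fraction * span, hi + pad_fraction * span,
                           config.fes_bins + 1)

    xe, ye = edges(x), edges(y)
    hist, _, _ = np.histogram2d(x, y, bins=(xe, ye), weights=weights.weights)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    empty_frac = np.mean(counts == 0)
    if empty_frac > 0.5:
        warnings.warn(
            f"{100 * empty_frac:.0f}% of 2D grid cells are empty: the "
            "single-CV bias may not have sampled this variable pair "
            "adequately")
    kt = rt(config.temperature)
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -kt * np.log(hist, where=hist > 0,
                                              out=np.full_like(hist, -np.inf)),
                     np.nan)
    F = F - np.nanmin(F)
    return FES2D(axes=(xname, yname), x_edges=xe, y_edges=ye,
                 free_energy=F, counts=counts,
                 temperature=config.temperature)


def reweighted_profile_xi1(weights: FrameWeights, bin_edges: np.ndarray,
                           temperature: float) -> np.ndarray:
    """xi1 free-energy profile from frame weights (min-zero gauge).

    Marginalisation cross-check: this should agree with the histogram
    WHAM PMF on well-sampled bins.
    """
    hist, _ = np.histogram(weights.xi1, bins=bin_edges,
                           weights=weights.weights)
    kt = rt(temperature)
    with np.errstate(divide="ignore"):
        F = np.where(hist > 0, -kt * np.log(hist, where=hist > 0,
                                            out=np.full_like(hist, -np.inf)),
                     np.nan)
    return F - np.nanmin(F)


def basin_occupancy(weights: FrameWeights, state_definitions,
                    temperature: float) -> dict[str, dict[str, float]]:
    """Per-state probability and free energy from frame weights.

    Each state definition must expose ``name`` and
    ``contains(xi1, xi2, xi3) -> bool mask``.  Probabilities of the
    declared states plus the unassigned complement sum to one; a state
    with zero weight has probability 0 and undefined (NaN) free energy.
    Free energies are -RT ln p, reported relative to the most occupied
    state.
    """
    kt = rt(temperature)
    xi1 = weights.xi1
    xi2 = weights.xi2
    xi3 = weights.xi3
    out: dict[str, dict[str, float]] = {}
    assigned = np.zeros(len(weights), dtype=bool)
    probs = {}
    for sd in state_definitions:
        m = sd.contains(xi1, xi2, xi3)
        probs[sd.name] = float(weights.weights[m].sum())
        assigned |= m
    probs["(unassigned)"] = float(weights.weights[~assigned].sum())
    pmax = max(probs.values())
    for name, p in probs.items():
        F = float(-kt * (np.log(p) - np.log(pmax))) if p > 0 else float("nan")
        out[name] = {"probability": p, "free_energy": F}
    return out
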