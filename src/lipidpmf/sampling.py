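"""Synthetic biased sampling: umbrella windows and replica exchange.

Stands in for the biased coarse-grained MD engine.  Each umbrella window
runs a Metropolis Monte Carlo chain along the biased reaction coordinate
xi1 (target density exp(-beta * [F(xi1) + 0.5*k*(xi1 - c_i)^2])); the
orientation coordinates (xi2, xi3) are then drawn exactly from the model's
conditional density given xi1.  Because that conditional is sampled
exactly, the chain is a collapsed Gibbs sampler for the full
three-variable Boltzmann distribution — the target is hit exactly (up to
Monte Carlo error in the xi1 chain), which makes quadrature oracles on the
model potential directly usable in tests.

Replica exchange follows the standard neighbour-swap scheme: every
``exchange_interval`` steps, alternating even/odd pairs of adjacent
windows attempt a configuration swap accepted with the Boltzmann
criterion min(1, exp(-beta * Delta)), Delta being the change in total
bias energy on swapping the two configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import rt
from .potential import XI1_DOMAIN, XI3_DOMAIN, ModelPotential
from .trajio import CVTrajectory, UmbrellaProtocol

__all__ = ["ExchangeRecord", "REUSResult", "sample_window", "run_reus",
           "demux_replicas"]

#: Default Metropolis proposal width along xi1 (nm).
DEFAULT_STEP = 0.025


@dataclass(frozen=True)
class ExchangeRecord:
    """One attempted neighbour swap: windows (i, i+1) at a given step."""

    step: int
    window_i: int
    window_j: int
    accepted: bool


@dataclass
class REUSResult:
    """Output of a replica-exchange umbrella-sampling run.

    ``trajectories[i]`` is the time series recorded *in window i* (the
    usual per-window view consumed by WHAM); its ``replica_index`` column
    tracks which walker occupied the window at each frame, enabling
    demultiplexing into continuous replica paths.
    """

    trajectories: list[CVTrajectory]
    exchange_log: list[ExchangeRecord]
    protocol: UmbrellaProtocol

    @property
    def n_attempted(self) -> int:
        return len(self.exchange_log)

    @property
    def acceptance_rate(self) -> float:
        if not self.exchange_log:
            return float("nan")
        return sum(r.accepted for r in self.exchange_log) / len(self.exchange_log)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (single reflection; steps << range)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def _sample_orientation(potential: ModelPotential, xi1: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Exact draw of (xi2, xi3) from the conditional density at each xi1."""
    comps = potential.components
    gates = np.stack([c.gate(xi1) for c in comps])  # (K, N)
    w = gates / gates.sum(axis=0)
    u = rng.random(xi1.shape)
    k = (np.cumsum(w, axis=0) < u).sum(axis=0)
    k = np.minimum(k, len(comps) - 1)
    mu2 = np.array([c.mu2 for c in comps])[k]
    s2 = np.array([c.sigma2 for c in comps])[k]
    mu3 = np.array([c.mu3 for c in comps])[k]
    s3 = np.array([c.sigma3 for c in comps])[k]
    xi2 = rng.normal(mu2, s2)
    # truncated normal on [-1, 1] by vectorised rejection
    xi3 = rng.normal(mu3, s3)
    bad = (xi3 < XI3_DOMAIN[0]) | (xi3 > XI3_DOMAIN[1])
    while np.any(bad):
        xi3[bad] = rng.normal(mu3[bad], s3[bad])
        bad = (xi3 < XI3_DOMAIN[0]) | (xi3 > XI3_DOMAIN[1])
    return xi2, xi3


def _check_start(potential: ModelPotential, x0: np.ndarray) -> None:
    lo, hi = XI1_DOMAIN
    for x in np.atleast_1d(x0):
        if not np.isfinite(x) or x < lo or x > hi:
            raise ValueError(
                f"non-finite potential at start point: xi1={x} lies outside "
                f"the domain [{lo}, {hi}] nm")


def _mc_xi1(potential: ModelPotential, centers: np.ndarray, k: float,
            temperature: float, n_steps: int, rng: np.random.Generator,
            step: float = DEFAULT_STEP,
            exchange_interval: int | None = None,
            exchange_rng: np.random.Generator | None = None):
    """Metropolis chains along xi1, one per window, optionally with REUS.

    Returns (samples (n_steps, W), replica (n_steps, W) int,
    exchange_log list).
    """
    kt = rt(temperature)
    lo, hi = XI1_DOMAIN
    W = len(centers)
    x = np.clip(centers.astype(float).copy(), lo + 1e-9, hi - 1e-9)
    _check_start(potential, x)
    u_marg = potential.marginal_xi1
    e = u_marg(x) + 0.5 * k * (x - centers) ** 2
    replica = np.arange(W)
    out = np.empty((n_steps, W))
    rep_out = np.empty((n_steps, W), dtype=np.int64)
    log: list[ExchangeRecord] = []
    n_exch_rounds = 0
    for t in range(n_steps):
        prop = _reflect(x + rng.normal(0.0, step, W), lo, hi)
        e_prop = u_marg(prop) + 0.5 * k * (prop - centers) ** 2
        accept = rng.random(W) < np.exp(np.minimum(0.0, -(e_prop - e) / kt))
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        if exchange_interval and (t + 1) % exchange_interval == 0:
            start = n_exch_rounds % 2
            n_exch_rounds += 1
            ex_rng = exchange_rng or rng
            for i in range(start, W - 1, 2):
                j = i + 1
                delta = (0.5 * k * ((x[j] - centers[i]) ** 2
                                    + (x[i] - centers[j]) ** 2
                                    - (x[i] - centers[i]) ** 2
                                    - (x[j] - centers[j]) ** 2))
                acc = ex_rng.random() < np.exp(min(0.0, -delta / kt))
                if acc:
                    x[i], x[j] = x[j], x[i]
                    replica[i], replica[j] = replica[j], replica[i]
                    e[i] = u_marg(x[i]) + 0.5 * k * (x[i] - centers[i]) ** 2
                    e[j] = u_marg(x[j]) + 0.5 * k * (x[j] - centers[j]) ** 2
                log.append(ExchangeRecord(step=t + 1, window_i=i, window_j=j,
                                          accepted=bool(acc)))
        out[t] = x
        rep_out[t] = replica
    return out, rep_out, log


def sample_window(potential: ModelPotential, protocol: UmbrellaProtocol,
                  window_index: int, step: float = DEFAULT_STEP) -> CVTrajectory:
    """Sample one umbrella window (no replica exchange).

    The chain targets exp(-beta*[F(xi1) + bias_i(xi1)]); (xi2, xi3) are
    exact conditional draws.  Deterministic given (inputs, protocol.seed).
    """
    if not 0 <= window_index < protocol.n_windows:
        raise ValueError(
            f"window_index {window_index} out of range 0..{protocol.n_windows - 1}")
    if protocol.n_steps <= 0:
        raise ValueError("protocol.n_steps must be positive")
    rng = np.random.default_rng([protocol.seed, window_index, 0x5eed])
    centers = np.array([protocol.centers[window_index]])
    xs, _, _ = _mc_xi1(potential, centers, protocol.force_constant,
                       protocol.temperature, protocol.n_steps, rng, step=step)
    xi1 = xs[:, 0]
    xi2, xi3 = _sample_orientation(potential, xi1, rng)
    return CVTrajectory(
        time=np.arange(protocol.n_steps, dtype=float),
        xi1=xi1, xi2=xi2, xi3=xi3, window_index=window_index,
        source=f"synthetic window {window_index} "
               f"(c={protocol.centers[window_index]:.3f} nm, seed={protocol.seed})")


def run_reus(potential: ModelPotential, protocol: UmbrellaProtocol,
             step: float = DEFAULT_STEP) -> REUSResult:
    """Run replica-exchange umbrella sampling over all windows.

    Exchange attempts occur every ``protocol.exchange_interval`` steps on
    alternating even/odd neighbour pairs; swaps are accepted with the
    Boltzmann criterion on the bias-energy difference.  Per-window
    marginal distributions coincide with independent-window sampling
    (exchange moves satisfy detailed balance).
    """
    if protocol.n_windows < 2:
        raise ValueError("replica exchange needs at least 2 windows")
    if protocol.exchange_interval <= 0:
        raise ValueError("exchange_interval must be positive")
    rng = np.random.default_rng([protocol.seed, 0xae05])
    centers = np.asarray(protocol.centers, dtype=float)
    xs, reps, log = _mc_xi1(
        potential, centers, protocol.force_constant, protocol.temperature,
        protocol.n_steps, rng, step=step,
        exchange_interval=protocol.exchange_interval)
    time = np.arange(protocol.n_steps, dtype=float)
    trajs = []
    for i in range(protocol.n_windows):
        xi1 = xs[:, i]
        xi2, xi3 = _sample_orientation(potential, xi1, rng)
        trajs.append(CVTrajectory(
            time=time.copy(), xi1=xi1, xi2=xi2, xi3=xi3, window_index=i,
            replica_index=reps[:, i],
            source=f"synthetic REUS window {i} (seed={protocol.seed})"))
    return REUSResult(trajectories=trajs, exchange_log=log, protocol=protocol)


def demux_replicas(reus: REUSResult) -> list[CVTrajectory]:
    """Demultiplex window-view trajectories into continuous replica paths.

    Each returned trajectory follows one walker through window space; its
    ``window_index`` is a per-frame array.  The concatenation of all
    outputs is a permutation of all input frames.
    """
    if reus.exchange_log is None:
        raise ValueError("exchange log missing: cannot demultiplex")
    for i, tr in enumerate(reus.trajectories):
        if tr.replica_index is None:
            raise ValueError(
                f"window {i} lacks a replica_index record: cannot demultiplex")
    n_rep = len(reus.trajectories)
    out = []
    for r in range(n_rep):
        times, xi1, xi2, xi3, widx = [], [], [], [], []
        for i, tr in enumerate(reus.trajectories):
            m = tr.replica_index == r
            times.append(tr.time[m])
            xi1.append(tr.xi1[m])
            xi2.append(tr.xi2[m] if tr.xi2 is not None else np.array([]))
            xi3.append(tr.xi3[m] if tr.xi3 is not None else np.array([]))
            widx.append(np.full(m.sum(), i, dtype=int))
        t = np.concatenate(times)
        order = np.argsort(t, kind="stable")
        has2 = reus.trajectories[0].xi2 is not None
        has3 = reus.trajectories[0].xi3 is not None
        out.append(CVTrajectory(
            time=t[order],
            xi1=np.concatenate(xi1)[order],
            xi2=np.concatenate(xi2)[order] if has2 else None,
            xi3=np.concatenate(xi3)[order] if has3 else None,
            window_index=np.concatenate(widx)[order],
            replica_index=np.full(len(t), r, dtype=int),
            source=f"demuxed replica {r}"))
    return out
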