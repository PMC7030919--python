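"""Weighted histogram analysis method (WHAM) for 1D PMF estimation.

Combines the biased histograms from a ladder of harmonic umbrella windows
into one unbiased potential of mean force F(xi1), solving the standard
self-consistent equations

    p_l  propto  ( sum_i n_il ) / ( sum_i N_i exp(beta*(f_i - w_i(x_l))) )
    exp(-beta*f_i) = sum_l p_l exp(-beta*w_i(x_l))

by direct iteration in log space (numerically safe for deep wells).  The
per-window offsets f_i are reported alongside the profile; they feed the
binless reweighting used for 2D landscapes.

Conventions: bins with zero total count have undefined (NaN) free energy
and are excluded from alignment and minima detection; the profile can be
gauged either to min-zero or to a plateau region (the unbound state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal
from scipy.special import logsumexp

from .constants import rt
from .trajio import AnalysisConfig, CVTrajectory, UmbrellaProtocol

__all__ = ["PMFProfile", "MinimaResult", "wham_1d", "align_pmf",
           "pmf_convergence", "find_minima"]


@dataclass
class PMFProfile:
    """Binned free-energy profile along xi1 with WHAM bookkeeping.

    ``free_energy`` is NaN on bins with no samples.  ``window_offsets``
    are the converged WHAM f_i (kJ/mol, gauge: f_0 = 0); ``counts`` is
    the (n_windows, n_bins) histogram matrix.
    """

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol, NaN where undefined
    zero_convention: str  # "min-zero" | "plateau-zero"
    window_offsets: np.ndarray  # kJ/mol per window
    counts: np.ndarray  # (n_windows, n_bins)
    temperature: float
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        if not np.any(np.isfinite(self.free_energy)):
            raise ValueError("PMF has no finite bins")

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.bin_centers)))

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def well_depth(self) -> float:
        """Minimum finite free energy (kJ/mol) in the current gauge."""
        return float(np.nanmin(self.free_energy))


@dataclass
class MinimaResult:
    """Local minima of a PMF and the barriers separating them."""

    minima: list[tuple[float, float]]  # (position nm, depth kJ/mol)
    barriers: list[float]  # kJ/mol, between consecutive minima
    edge_minima: list[tuple[float, float]]  # boundary minima (monotone tails)
    smoothed: bool


def _bias_matrix(centers, k, bin_centers):
    """(n_windows, n_bins) harmonic bias energies at bin centres."""
    c = np.asarray(centers, float)[:, None]
    return 0.5 * k * (bin_centers[None, :] - c) ** 2


def wham_1d(trajs: list[CVTrajectory], protocol: UmbrellaProtocol,
            config: AnalysisConfig) -> PMFProfile:
    """Estimate the unbiased PMF along xi1 from biased window series.

    ``trajs`` must contain one post-burn-in trajectory per umbrella
    window (window identity from ``traj.window_index``).  Iterates the
    self-consistent equations until the largest change in any window
    offset falls below ``config.wham_tolerance`` (kJ/mol) or
    ``config.max_iterations`` is reached (the profile is then flagged
    unconverged).  The result is gauge-invariant: shifting all offsets by
    a constant leaves the aligned profile unchanged.

    Raises
    ------
    ValueError
        If a window has no samples (named in the message).
    """
    kt = rt(protocol.temperature)
    edges = config.xi1_bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    W = protocol.n_windows
    by_window: dict[int, list[np.ndarray]] = {i: [] for i in range(W)}
    for tr in trajs:
        wi = tr.window_index
        if isinstance(wi, np.ndarray):
            for i in range(W):
                sel = tr.xi1[wi == i]
                if sel.size:
                    by_window[i].append(sel)
        else:
            by_window[int(wi)].append(tr.xi1)

    counts = np.zeros((W, len(centers)))
    for i in range(W):
        if not by_window[i] or sum(len(s) for s in by_window[i]) == 0:
            raise ValueError(
                f"window {i} (center {protocol.centers[i]:.3f} nm) has no samples")
        x = np.concatenate(by_window[i])
        counts[i], _ = np.histogram(x, bins=edges)

    # adjacent-window histogram overlap diagnostic
    occupied = counts > 0
    for i in range(W - 1):
        overlap = int(np.sum(occupied[i] & occupied[i + 1]))
        if overlap == 0:
            warnings.warn(
                f"no histogram overlap between windows {i} and {i + 1} "
                f"(centers {protocol.centers[i]:.3f} / "
                f"{protocol.centers[i + 1]:.3f} nm): PMF may be disconnected")

    n_tot = counts.sum(axis=0)
    N_i = counts.sum(axis=1)
    beta_w = _bias_matrix(protocol.centers, protocol.force_constant,
                          centers) / kt  # (W, L)
    log_N = np.log(N_i)
    with np.errstate(divide="ignore"):
        log_n_tot = np.log(n_tot)

    bf = np.zeros(W)  # beta * f_i
    occupied_bins = n_tot > 0
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # log p_l over occupied bins
        denom = logsumexp(log_N[:, None] + bf[:, None] - beta_w, axis=0)
        log_p = np.where(occupied_bins, log_n_tot - denom, -np.inf)
        log_p -= logsumexp(log_p[occupied_bins])
        bf_new = -logsumexp(log_p[None, :] - beta_w, axis=1,
                            b=occupied_bins[None, :].astype(float))
        bf_new -= bf_new[0]  # gauge: f_0 = 0
        delta = np.max(np.abs(bf_new - bf)) * kt
        bf = bf_new
        if delta < config.wham_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {config.max_iterations} iterations "
            f"(last offset change {delta:.3g} kJ/mol)")

    denom = logsumexp(log_N[:, None] + bf[:, None] - beta_w, axis=0)
    log_p = np.where(occupied_bins, log_n_tot - denom, -np.inf)
    with np.errstate(invalid="ignore"):
        F = np.where(occupied_bins, -kt * log_p, np.nan)
    F = F - np.nanmin(F)  # min-zero gauge
    return PMFProfile(
        bin_centers=centers, free_energy=F, zero_convention="min-zero",
        window_offsets=bf * kt, counts=counts,
        temperature=protocol.temperature, converged=converged,
        n_iterations=it)


def align_pmf(profile: PMFProfile,
              plateau_region: tuple[float, float]) -> PMFProfile:
    """Re-gauge a PMF so its mean over the plateau (unbound) region is zero.

    Pairwise free-energy differences are preserved exactly; only the
    additive constant changes.
    """
    lo, hi = plateau_region
    mask = ((profile.bin_centers >= lo) & (profile.bin_centers <= hi)
            & profile.finite_mask)
    if not np.any(mask):
        raise ValueError(
            f"no finite bins in plateau region [{lo}, {hi}] nm")
    shift = float(np.mean(profile.free_energy[mask]))
    return _dc_replace(profile, free_energy=profile.free_energy - shift,
                       zero_convention="plateau-zero")


def pmf_convergence(trajs: list[CVTrajectory], protocol: UmbrellaProtocol,
                    config: AnalysisConfig, n_blocks: int
                    ) -> tuple[list[PMFProfile | None], np.ndarray]:
    """Block-wise convergence diagnostic.

    Splits each window's (post-burn-in) time range into ``n_blocks``
    contiguous blocks, runs WHAM per block, and returns the per-block
    profiles plus the symmetric matrix of pairwise RMS discrepancies
    (computed over bins finite in both blocks, after removing the mean
    difference so only shape mismatch counts).  A block in which some
    window is empty yields ``None`` and NaN rows rather than aborting.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    profiles: list[PMFProfile | None] = []
    for b in range(n_blocks):
        block_trajs = []
        for tr in trajs:
            t0, t1 = tr.time[0], tr.time[-1]
            lo = t0 + (t1 - t0) * b / n_blocks
            hi = t0 + (t1 - t0) * (b + 1) / n_blocks
            mask = (tr.time >= lo) & (tr.time <= hi if b == n_blocks - 1
                                      else tr.time < hi)
            block_trajs.append(tr.slice(mask))
        try:
            profiles.append(wham_1d(block_trajs, protocol, config))
        except ValueError as exc:
            warnings.warn(f"block {b}: {exc}")
            profiles.append(None)

    D = np.full((n_blocks, n_blocks), np.nan)
    np.fill_diagonal(D, 0.0)
    for a in range(n_blocks):
        for b in range(a + 1, n_blocks):
            pa, pb = profiles[a], profiles[b]
            if pa is None or pb is None:
                continue
            m = pa.finite_mask & pb.finite_mask
            if not np.any(m):
                continue
            diff = pa.free_energy[m] - pb.free_energy[m]
            diff -= diff.mean()
            D[a, b] = D[b, a] = float(np.sqrt(np.mean(diff ** 2)))
    return profiles, D


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average, NaN aware, ends kept as-is."""
    out = y.copy()
    for i in range(1, len(y) - 1):
        window = y[i - 1:i + 2]
        if np.all(np.isfinite(window)):
            out[i] = window.mean()
    return out


def find_minima(profile: PMFProfile, smooth: bool = True,
                prominence: float = 0.5) -> MinimaResult:
    """Locate strict local minima of the binned PMF and their barriers.

    Operates on the longest contiguous run of finite bins.  With
    ``smooth=True`` a 3-bin moving average is applied first (recorded in
    the result).  ``prominence`` (kJ/mol) suppresses statistical wiggles:
    a minimum must sit at least that far below the lower of the two
    ridges enclosing it (set 0 to report every strict minimum).  Monotone
    profiles yield no interior minima; boundary minima are reported under
    ``edge_minima``.  Barrier k is the highest point between minima k and
    k+1, relative to the shallower of the two.
    """
    F = profile.free_energy
    x = profile.bin_centers
    finite = np.isfinite(F)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite bins")
    # longest contiguous finite run
    best, cur, start, bstart = 0, 0, 0, 0
    for i, ok in enumerate(finite):
        if ok:
            if cur == 0:
                start = i
            cur += 1
            if cur > best:
                best, bstart = cur, start
        else:
            cur = 0
    sl = slice(bstart, bstart + best)
    y = _smooth3(F[sl].copy()) if smooth else F[sl].copy()
    xs = x[sl]

    if prominence > 0:
        idx_min, _ = signal.find_peaks(-y, prominence=prominence)
    else:
        idx_min, _ = signal.find_peaks(-y)
    minima = [(float(xs[i]), float(y[i])) for i in idx_min]
    edge: list[tuple[float, float]] = []
    if len(y) >= 2:
        if y[0] < y[1] and not any(abs(p - xs[0]) < 1e-12 for p, _ in minima):
            edge.append((float(xs[0]), float(y[0])))
        if y[-1] < y[-2]:
            edge.append((float(xs[-1]), float(y[-1])))

    barriers: list[float] = []
    idx = [int(np.argmin(np.abs(xs - p))) for p, _ in minima]
    for a, b in zip(idx, idx[1:]):
        seg = y[a:b + 1]
        barriers.append(float(seg.max() - max(y[a], y[b])))
    return MinimaResult(minima=minima, barriers=barriers, edge_minima=edge,
                        smoothed=smooth)
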