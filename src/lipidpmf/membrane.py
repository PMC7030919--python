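"""Synthetic in-plane membrane snapshots for density-map analysis.

Emulates the per-frame data needed to map lipid head-group clustering
under a membrane-bound protein: 2D positions of anionic-lipid (PIP3)
phosphate head groups in the bilayer plane, a coarse protein bead
footprint, and a per-frame statistical weight.  Head groups are drawn
from a mixture of Gaussian hotspots (the protein's lipid-binding sites —
canonical, noncanonical, and a third site) over a uniform background, in
a periodic box.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["MembraneSnapshot", "generate_membrane_frames"]


def wrap_xy(pos: np.ndarray, box_xy: tuple[float, float]) -> np.ndarray:
    """Wrap (x, y) positions into the primary periodic cell [0, L)."""
    box = np.asarray(box_xy, dtype=float)
    return np.mod(pos, box)


@dataclass
class MembraneSnapshot:
    """One frame of in-plane head-group and protein bead coordinates (nm)."""

    headgroup_xy: np.ndarray  # (n_lipids, 2)
    protein_bead_xyz: np.ndarray  # (n_beads, 3)
    box_xy: tuple[float, float]
    frame_weight: float = 1.0

    def __post_init__(self):
        self.headgroup_xy = np.atleast_2d(np.asarray(self.headgroup_xy, float))
        self.protein_bead_xyz = np.atleast_2d(
            np.asarray(self.protein_bead_xyz, float))
        if self.frame_weight < 0:
            raise ValueError("frame_weight must be nonnegative")
        if self.headgroup_xy.size and self.headgroup_xy.shape[1] != 2:
            raise ValueError("headgroup_xy must be (n, 2)")
        if self.protein_bead_xyz.size and self.protein_bead_xyz.shape[1] != 3:
            raise ValueError("protein_bead_xyz must be (n, 3)")
        self.headgroup_xy = wrap_xy(self.headgroup_xy, self.box_xy)
        xyz = self.protein_bead_xyz.copy()
        if xyz.size:
            xyz[:, :2] = wrap_xy(xyz[:, :2], self.box_xy)
        self.protein_bead_xyz = xyz


def _default_protein_beads(center: np.ndarray, z: float = 0.45) -> np.ndarray:
    """A coarse protein footprint just above the membrane plane (z = 0):
    two concentric bead rings plus a centre bead, dense enough that any
    lipid under the footprint is within the contact cutoff of a bead."""
    rows = [[center[0], center[1], z]]
    for radius, n in ((0.55, 8), (1.1, 16)):
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        rows.extend(np.column_stack([
            center[0] + radius * np.cos(ang),
            center[1] + radius * np.sin(ang),
            np.full(n, z),
        ]))
    return np.asarray(rows)


def generate_membrane_frames(
    state_label: str,
    n_pip3: int,
    hotspots: list[tuple[float, float, float]],
    n_frames: int,
    seed: int,
    *,
    box_xy: tuple[float, float] = (12.0, 12.0),
    hotspot_width: float = 0.25,
    weights: np.ndarray | None = None,
) -> list[MembraneSnapshot]:
    """Generate snapshots with head groups clustered at declared hotspots.

    Parameters
    ----------
    state_label : str
        Label recorded in no field but used to seed independently per
        state (frames for different states are independent streams).
    n_pip3 : int
        Head groups per frame (one phosphate bead per lipid).
    hotspots : list of (x, y, weight)
        Hotspot centres (nm, relative to the protein centre, which sits
        at the middle of the box) and their mixture weights; weights must
        be nonnegative and sum to at most 1 — the remainder is a uniform
        background over the box.
    n_frames, seed : int
        Number of frames and RNG seed.
    hotspot_width : float
        Isotropic Gaussian width (nm) of each hotspot.
    weights : array, optional
        Per-frame statistical weights (default: all 1).

    Each particle independently picks a hotspot with its weight (else the
    uniform background) and is placed with Gaussian scatter, wrapped into
    the periodic box.
    """
    if n_pip3 <= 0:
        raise ValueError(f"n_pip3 must be positive, got {n_pip3}")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    hs = [(float(x), float(y), float(w)) for x, y, w in hotspots]
    wsum = sum(w for _, _, w in hs)
    if any(w < 0 for _, _, w in hs) or wsum > 1 + 1e-12:
        raise ValueError("hotspot weights must be >= 0 and sum to <= 1")
    if weights is not None and len(weights) != n_frames:
        raise ValueError("weights must have one entry per frame")

    rng = np.random.default_rng(
        [seed, zlib.crc32(state_label.encode())])
    box = np.asarray(box_xy, dtype=float)
    center = box / 2.0
    beads = _default_protein_beads(center)
    cum = np.cumsum([w for _, _, w in hs])
    centers = (center + np.array([[x, y] for x, y, _ in hs])
               if hs else np.empty((0, 2)))

    frames = []
    for f in range(n_frames):
        u = rng.random(n_pip3)
        pos = np.empty((n_pip3, 2))
        choice = np.searchsorted(cum, u)  # == len(hs) -> background
        bg = choice >= len(hs)
        pos[bg] = rng.random((bg.sum(), 2)) * box
        if (~bg).any():
            mu = centers[choice[~bg]]
            pos[~bg] = mu + rng.normal(0.0, hotspot_width, (int((~bg).sum()), 2))
        frames.append(MembraneSnapshot(
            headgroup_xy=wrap_xy(pos, box_xy),
            protein_bead_xyz=beads,
            box_xy=tuple(box),
            frame_weight=1.0 if weights is None else float(weights[f])))
    return frames
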