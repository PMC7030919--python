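"""Bound-state classification, lipid contacts, and in-plane density maps.

The membrane-associated states of the protein are defined as closed boxes
in CV space (protein-lipid minimum distance, protein-membrane COM
distance, cos of the helix tilt).  The two tightly bound orientations:

* ``B_A`` — min distance [0.46, 0.52] nm, COM [3.91, 3.97] nm,
  cos(theta) [0.36, 0.46];
* ``B_B`` — min distance [0.45, 0.51] nm, COM [3.45, 3.51] nm,
  cos(theta) [0.89, 0.99] (deeper insertion, helix nearly upright).

The encounter state ``E`` has no published box; the repository default is
the xi1 slab [0.70, 0.76] nm around the encounter minimum with xi2 and
xi3 unconstrained.

Lipid contacts use a 0.7 nm protein-lipid cutoff (strict inequality)
under the minimum-image convention in the periodic membrane plane.
Density maps are weighted 2D histograms of head-group positions for
frames in a given state, normalised by the maximum cell value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .membrane import MembraneSnapshot

__all__ = ["StateDefinition", "DensityMap", "ContactPDF", "classify_state",
           "contact_count", "contact_pdf", "density_map",
           "default_state_definitions", "check_state_disjointness",
           "CONTACT_CUTOFF"]

#: Protein-lipid contact cutoff (nm); comparison is strict (<).
CONTACT_CUTOFF = 0.7

_UNBOUNDED = (-np.inf, np.inf)


@dataclass(frozen=True)
class StateDefinition:
    """A named closed box in (xi1, xi2, xi3) CV space.

    Interval endpoints are included; unconstrained axes use infinite
    bounds.
    """

    name: str
    xi1: tuple[float, float] = _UNBOUNDED
    xi2: tuple[float, float] = _UNBOUNDED
    xi3: tuple[float, float] = _UNBOUNDED

    def __post_init__(self):
        for axis in ("xi1", "xi2", "xi3"):
            lo, hi = getattr(self, axis)
            if np.isnan(lo) or np.isnan(hi) or lo > hi:
                raise ValueError(
                    f"state {self.name!r}: invalid {axis} interval "
                    f"[{lo}, {hi}]")

    def contains(self, xi1, xi2=None, xi3=None) -> np.ndarray:
        """Boolean mask of frames inside the box (closed intervals)."""
        xi1 = np.asarray(xi1, dtype=float)
        m = (xi1 >= self.xi1[0]) & (xi1 <= self.xi1[1])
        for axis, v in (("xi2", xi2), ("xi3", xi3)):
            lo, hi = getattr(self, axis)
            if np.isinf(lo) and np.isinf(hi):
                continue
            if v is None:
                raise ValueError(
                    f"state {self.name!r} constrains {axis} but the frame "
                    f"lacks it")
            v = np.asarray(v, dtype=float)
            m = m & (v >= lo) & (v <= hi)
        return m


def default_state_definitions(include_encounter: bool = True
                              ) -> list[StateDefinition]:
    """The published B_A/B_B boxes, optionally with the default E slab."""
    defs = [
        StateDefinition("B_A", xi1=(0.46, 0.52), xi2=(3.91, 3.97),
                        xi3=(0.36, 0.46)),
        StateDefinition("B_B", xi1=(0.45, 0.51), xi2=(3.45, 3.51),
                        xi3=(0.89, 0.99)),
    ]
    if include_encounter:
        defs.append(StateDefinition("E", xi1=(0.70, 0.76)))
    return defs


def check_state_disjointness(definitions: list[StateDefinition]) -> list[str]:
    """Report pairs of states whose boxes overlap on every axis.

    Overlapping definitions make classification order-dependent; the
    report is issued as warnings and returned.
    """
    msgs = []
    for i, a in enumerate(definitions):
        for b in definitions[i + 1:]:
            overlap_all = True
            for axis in ("xi1", "xi2", "xi3"):
                alo, ahi = getattr(a, axis)
                blo, bhi = getattr(b, axis)
                if ahi < blo or bhi < alo:
                    overlap_all = False
                    break
            if overlap_all:
                msg = (f"states {a.name!r} and {b.name!r} overlap on all "
                       "axes; classification will be order-dependent")
                warnings.warn(msg)
                msgs.append(msg)
    return msgs


def classify_state(frame, definitions: list[StateDefinition]) -> str | None:
    """Label a frame (xi1, xi2, xi3) with the first matching state box.

    Returns ``None`` when no box contains the frame.  A state that
    constrains a CV the frame lacks raises, naming the CV.
    """
    xi1, xi2, xi3 = frame
    if xi1 is None:
        raise ValueError("frame lacks xi1")
    for sd in definitions:
        if bool(sd.contains(np.atleast_1d(float(xi1)),
                            None if xi2 is None else np.atleast_1d(float(xi2)),
                            None if xi3 is None else np.atleast_1d(float(xi3))
                            )[0]):
            return sd.name
    return None


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _min_image_dist2(head_xy: np.ndarray, beads: np.ndarray,
                     box_xy: tuple[float, float]) -> np.ndarray:
    """(n_lipids, n_beads) squared distances, minimum image in x-y.

    Head groups sit in the membrane plane (z = 0); protein beads carry
    their z offset, which enters the distance unperiodically.
    """
    box = np.asarray(box_xy, dtype=float)
    d = head_xy[:, None, :] - beads[None, :, :2]
    d -= box * np.round(d / box)
    dz = beads[None, :, 2]
    return (d ** 2).sum(axis=-1) + dz ** 2


def contact_count(snapshot: MembraneSnapshot,
                  cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of lipids with any head-group bead within ``cutoff`` of any
    protein bead (strict inequality, minimum-image in the periodic
    plane)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if snapshot.protein_bead_xyz.size == 0:
        raise ValueError("snapshot has no protein beads")
    if snapshot.headgroup_xy.size == 0:
        return 0
    d2 = _min_image_dist2(snapshot.headgroup_xy, snapshot.protein_bead_xyz,
                          snapshot.box_xy)
    return int(np.sum(d2.min(axis=1) < cutoff ** 2))


# ---------------------------------------------------------------------------
# contact-number PDF and density maps
# ---------------------------------------------------------------------------

@dataclass
class ContactPDF:
    """Probability of each integer lipid-contact count within one state."""

    counts: np.ndarray  # integer support, 0..max
    probabilities: np.ndarray
    state: str
    cutoff: float

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p

    @property
    def mode(self) -> int:
        return int(self.counts[int(np.argmax(self.probabilities))])

    def mean(self) -> float:
        return float(np.sum(self.counts * self.probabilities))


def contact_pdf(snapshots: list[MembraneSnapshot], weights: np.ndarray,
                state_mask: np.ndarray, state: str,
                cutoff: float = CONTACT_CUTOFF) -> ContactPDF:
    """Weighted PDF of lipid-contact counts over frames in one state.

    ``weights`` are per-frame unbiased weights; ``state_mask`` selects
    frames classified in ``state``.  Raises if the selected frames carry
    zero total weight.
    """
    weights = np.asarray(weights, dtype=float)
    state_mask = np.asarray(state_mask, dtype=bool)
    if len(weights) != len(snapshots) or len(state_mask) != len(snapshots):
        raise ValueError("weights and state_mask must align with snapshots")
    w = weights[state_mask]
    if w.sum() <= 0:
        raise ValueError(f"zero total weight in state {state!r}")
    counts = np.array([contact_count(s, cutoff)
                       for s, m in zip(snapshots, state_mask) if m])
    support = np.arange(counts.max() + 1)
    p = np.zeros(len(support))
    np.add.at(p, counts, w)
    return ContactPDF(counts=support, probabilities=p / p.sum(),
                      state=state, cutoff=cutoff)


@dataclass
class DensityMap:
    """Max-normalised in-plane head-group density for one bound state."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (nx, ny), max = 1 where any weight present
    state: str
    n_frames: int
    total_weight: float

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        if self.total_weight > 0 and not np.isclose(self.density.max(), 1.0):
            raise ValueError("density must be normalised to max 1")

    def peak_positions(self, threshold: float = 0.5) -> list[tuple[float, float]]:
        """Centres of local maxima above ``threshold`` (4-neighbour rule)."""
        d = self.density
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        peaks = []
        padded = np.pad(d, 1, constant_values=-1.0)
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                v = d[i, j]
                if v < threshold:
                    continue
                nb = [padded[i, j + 1], padded[i + 2, j + 1],
                      padded[i + 1, j], padded[i + 1, j + 2]]
                if all(v >= n for n in nb):
                    peaks.append((float(xc[i]), float(yc[j])))
        return peaks


def _align_frame(snapshot: MembraneSnapshot) -> np.ndarray:
    """Head-group positions in the protein-fixed frame.

    Frames are translated so the protein's in-plane centroid sits at the
    origin; positions use minimum-image displacements from the centroid
    so the map is periodic-safe.
    """
    beads = snapshot.protein_bead_xyz
    box = np.asarray(snapshot.box_xy, dtype=float)
    centroid = beads[:, :2].mean(axis=0)
    d = snapshot.headgroup_xy - centroid
    d -= box * np.round(d / box)
    return d


def density_map(snapshots: list[MembraneSnapshot], weights: np.ndarray,
                state_mask: np.ndarray, state: str, *,
                cell: float = 0.2, extent: float = 4.0) -> DensityMap:
    """Reweighted, max-normalised head-group density map for one state.

    Frames are re-centred on the protein's in-plane centroid before
    accumulation (protein-relative map).  ``cell`` is the grid spacing
    (nm) and ``extent`` the half-width of the map (nm).  Empty cells are
    zero (the map is a density, not a free energy).  The map is invariant
    under global rescaling of the weights.
    """
    weights = np.asarray(weights, dtype=float)
    state_mask = np.asarray(state_mask, dtype=bool)
    if not np.any(state_mask):
        raise ValueError(f"no frames classified in state {state!r}")
    n = int(round(2 * extent / cell))
    edges = np.linspace(-extent, extent, n + 1)
    H = np.zeros((n, n))
    total_w = 0.0
    n_frames = 0
    for snap, w, m in zip(snapshots, weights, state_mask):
        if not m or w == 0:
            continue
        pos = _align_frame(snap)
        h, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=(edges, edges))
        H += w * h
        total_w += w
        n_frames += 1
    if H.max() > 0:
        H = H / H.max()
    return DensityMap(x_edges=edges, y_edges=edges, density=H, state=state,
                      n_frames=n_frames, total_weight=total_w)
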