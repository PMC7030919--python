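"""PMF to dissociation constant and standard-state binding free energy.

For a protein binding a membrane spanning the x-y plane of a periodic box,
the dissociation constant follows from the PMF F(r) along the
protein-lipid minimum distance r:

    Kd = (1 - b/L_z) / ( N_A * A * I ),      I = integral_0^b exp(-beta F(r)) dr

with A the membrane x-y area, b the bound-state cutoff (F(r) = 0 above
b), L_z the box height; in the L_z -> infinity limit the prefactor is 1.
The standard-state binding free energy is Delta G = RT ln(Kd / 1 M).

Unit chain: A [nm^2] * I [nm] = nm^3; 1 nm^3 = 1e-24 L, so
N_A * A * I carries units L/mol and Kd comes out in mol/L.

The integral runs over the binned PMF by a composite midpoint rule on
the bins' full extents; the region below the smallest sampled distance
contributes zero (steric wall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import L_PER_NM3, N_AVOGADRO, rt
from .wham import PMFProfile

__all__ = ["BindingParams", "BindingResult", "kd_from_pmf", "dg_from_kd",
           "aggregate_well_depths"]


@dataclass(frozen=True)
class BindingParams:
    """Geometric and thermodynamic inputs of the Kd formula.

    ``area_A`` has no default: it is a property of the simulated box that
    must be supplied.  ``box_Lz = inf`` selects the infinite-height limit.
    """

    area_A: float  # membrane x-y area, nm^2
    b: float = 1.0  # bound-state cutoff, nm
    box_Lz: float = np.inf  # box height, nm
    temperature: float = 323.0  # K

    def __post_init__(self):
        if self.area_A <= 0:
            raise ValueError("membrane area must be positive")
        if self.b <= 0:
            raise ValueError("bound cutoff b must be positive")
        if np.isfinite(self.box_Lz) and not self.b < self.box_Lz:
            raise ValueError("need 0 < b < L_z for a finite box")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class BindingResult:
    """Kd (mol/L), Delta G (kJ/mol), and the inputs that produced them."""

    kd: float
    delta_g: float
    integral_nm: float  # I = integral_0^b exp(-beta F) dr
    params: BindingParams
    formula: str  # "finite-box" | "infinite-Lz"

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("Kd must be positive")


def dg_from_kd(kd: float, temperature: float) -> float:
    """Standard-state binding free energy Delta G = RT ln(Kd / 1 M).

    ``kd`` in mol/L, ``temperature`` in K; result in kJ/mol (negative for
    sub-molar Kd, i.e. favourable binding).
    """
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    return rt(temperature) * float(np.log(kd))


def _boltzmann_integral(profile: PMFProfile, b: float,
                        temperature: float) -> float:
    """I = integral_0^b exp(-beta F) dr over the binned profile.

    Composite midpoint rule: each finite bin contributes its Boltzmann
    factor times the overlap of its extent with [0, b]; the partial bin
    straddling b is clipped exactly.  Distances below the first finite
    bin's lower edge contribute zero (hard wall); a gap between the last
    finite bin and b contributes at the plateau value (F = 0)."""
    w = profile.bin_width
    m = profile.finite_mask & (profile.bin_centers - 0.5 * w < b)
    if m.sum() < 2:
        raise ValueError(
            f"fewer than 2 finite PMF bins at or below b = {b} nm")
    r = profile.bin_centers[m]
    g = np.exp(-profile.free_energy[m] / rt(temperature))
    lo = r - 0.5 * w
    hi = np.minimum(r + 0.5 * w, b)
    I = float(np.sum(g * np.maximum(hi - lo, 0.0)))
    if hi[-1] < b:  # plateau continuation, F = 0
        I += b - float(hi[-1])
    return I


def kd_from_pmf(profile: PMFProfile, params: BindingParams) -> BindingResult:
    """Dissociation constant from a plateau-aligned PMF.

    The profile must be in the plateau-zero gauge (F -> 0 in the unbound
    region) — the formula's derivation assumes F(r) = 0 above b.  I is
    the composite-midpoint integral over the finite bins' extents clipped
    to [0, b]; distances below the first finite bin's lower edge
    contribute zero (hard wall).
    """
    if profile.zero_convention != "plateau-zero":
        raise ValueError(
            "PMF must be plateau-aligned (zero in the unbound region) "
            "before converting to Kd; call align_pmf first")
    if params.b > profile.bin_centers[-1] + profile.bin_width:
        raise ValueError(
            f"bound cutoff b = {params.b} nm lies beyond the binned range "
            f"(max bin centre {profile.bin_centers[-1]:.3f} nm)")
    I = _boltzmann_integral(profile, params.b, params.temperature)
    vol_l_per_mol = N_AVOGADRO * params.area_A * I * L_PER_NM3  # L/mol
    if np.isfinite(params.box_Lz):
        kd = (1.0 - params.b / params.box_Lz) / vol_l_per_mol
        formula = "finite-box"
    else:
        kd = 1.0 / vol_l_per_mol
        formula = "infinite-Lz"
    return BindingResult(kd=kd, delta_g=dg_from_kd(kd, params.temperature),
                         integral_nm=I, params=params, formula=formula)


def aggregate_well_depths(profiles: dict[int, PMFProfile],
                          params: BindingParams) -> pd.DataFrame:
    """Well depth, Kd and Delta G across systems with varying lipid count.

    ``profiles`` maps PIP3-per-leaflet count to an aligned PMF.  Returns
    a DataFrame sorted by ``n_pip3`` with columns ``depth_kj_mol``,
    ``kd_mol_l``, ``dg_kj_mol``, plus two attrs: ``monotone`` (depth
    non-increasing with n) and ``saturation_n`` (first n beyond which the
    depth deepens by less than 1 kJ/mol).
    """
    keys = list(profiles)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate n_pip3 keys")
    rows = []
    for n in sorted(keys):
        prof = profiles[n]
        res = kd_from_pmf(prof, params)
        rows.append({"n_pip3": int(n), "depth_kj_mol": prof.well_depth(),
                     "kd_mol_l": res.kd, "dg_kj_mol": res.delta_g})
    df = pd.DataFrame(rows).sort_values("n_pip3").reset_index(drop=True)
    depths = df["depth_kj_mol"].to_numpy()
    monotone = bool(np.all(np.diff(depths) <= 1e-9))
    sat = int(df["n_pip3"].iloc[0])
    for i in range(1, len(depths)):
        if depths[i] < depths[i - 1] - 1.0:
            sat = int(df["n_pip3"].iloc[i])
    df.attrs["monotone"] = monotone
    df.attrs["saturation_n"] = sat
    return df
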