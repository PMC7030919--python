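"""Ground-truth model free-energy surface for the synthetic sampler.

The surface lives on three collective variables (CVs):

* ``xi1`` — protein-lipid minimum distance (nm),
* ``xi2`` — protein-membrane centre-of-mass (COM) distance (nm),
* ``xi3`` — cosine of the tilt angle of the protein's alpha helix.

The construction is deliberately factorised so that the 1D marginal free
energy along ``xi1`` is known in closed form.  The total energy is

    U(xi1, xi2, xi3) = U1(xi1) - RT0 * ln rho(xi2, xi3 | xi1)

where ``U1`` is a sum of Gaussian wells plus a flat plateau, and ``rho`` is
a *normalised* conditional density over (xi2, xi3): a mixture of fixed
bound/encounter/unbound orientation components whose mixture weights vary
smoothly with xi1.  Because ``rho`` integrates to one at every xi1, the
Boltzmann marginal of U along xi1 at the reference temperature equals U1
exactly — every downstream estimator can be checked against an analytic
oracle.

Topology of the default surface: a tightly bound minimum near xi1 = 0.48 nm
(split into two orientation basins, B_A and B_B, that differ in COM
distance and tilt), a shallower encounter minimum near 0.73 nm, and a flat
unbound plateau beyond 1.5 nm.  Increasing the number of anionic lipids
(PIP3) per leaflet deepens the bound well by a fixed per-lipid increment
that saturates at five lipids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate
from scipy.stats import truncnorm

from .constants import DEFAULT_TEMPERATURE, rt

__all__ = [
    "GaussianWell",
    "OrientationComponent",
    "ModelPotential",
    "make_model_potential",
    "DEFAULT_ORIENTATION_COMPONENTS",
]

#: Domain of validity of the surface.
XI1_DOMAIN = (0.3, 2.0)
XI3_DOMAIN = (-1.0, 1.0)

#: Number of lipids at which bound-well deepening saturates.
SATURATION_N_PIP3 = 5

#: Default per-lipid deepening of the bound well (kJ/mol per PIP3).
DEFAULT_DEPTH_INCREMENT = 4.0


@dataclass(frozen=True)
class GaussianWell:
    """A Gaussian well along xi1: depth * exp(-(xi1-center)^2 / 2 width^2)."""

    center: float  # nm
    depth: float  # kJ/mol, <= 0
    width: float = 0.04  # nm (standard deviation)

    def __post_init__(self):
        if self.depth > 0:
            raise ValueError(f"well depth must be <= 0, got {self.depth}")
        if self.width <= 0:
            raise ValueError(f"well width must be positive, got {self.width}")


@dataclass(frozen=True)
class OrientationComponent:
    """One fixed (xi2, xi3) component of the conditional orientation density.

    The component is a product of a normal density in xi2 and a truncated
    normal in xi3 (support [-1, 1]); its mixture weight is a Gaussian gate
    in xi1 (``gate_width = None`` means an xi1-independent background
    weight).
    """

    name: str
    mu2: float
    sigma2: float
    mu3: float
    sigma3: float
    weight: float = 1.0
    gate_center: float | None = None
    gate_width: float | None = None

    def gate(self, xi1: np.ndarray) -> np.ndarray:
        """Unnormalised mixture weight as a function of xi1."""
        if self.gate_center is None or self.gate_width is None:
            return np.full_like(np.asarray(xi1, dtype=float), self.weight)
        z = (np.asarray(xi1, dtype=float) - self.gate_center) / self.gate_width
        return self.weight * np.exp(-0.5 * z * z)

    def log_density(self, xi2: np.ndarray, xi3: np.ndarray) -> np.ndarray:
        """Log of the normalised component density over (xi2, xi3)."""
        xi2 = np.asarray(xi2, dtype=float)
        xi3 = np.asarray(xi3, dtype=float)
        z2 = (xi2 - self.mu2) / self.sigma2
        logp2 = -0.5 * z2 * z2 - np.log(self.sigma2 * np.sqrt(2.0 * np.pi))
        a = (XI3_DOMAIN[0] - self.mu3) / self.sigma3
        b = (XI3_DOMAIN[1] - self.mu3) / self.sigma3
        logp3 = truncnorm.logpdf(xi3, a, b, loc=self.mu3, scale=self.sigma3)
        return logp2 + logp3


def _default_components(basin_split: float = 0.5) -> tuple[OrientationComponent, ...]:
    """Bound (B_A, B_B), encounter (E) and unbound (U) orientation components.

    Component centres sit inside the bound-state classification boxes used
    for state assignment (B_A at COM 3.94 nm / cos-theta 0.41; B_B at
    3.48 nm / 0.94) and at the encounter basin (COM 4.3 nm).
    ``basin_split`` is the fraction of bound-state weight in B_A.
    """
    if not 0.0 <= basin_split <= 1.0:
        raise ValueError("basin_split must lie in [0, 1]")
    return (
        OrientationComponent("B_A", mu2=3.94, sigma2=0.018, mu3=0.41, sigma3=0.028,
                             weight=basin_split, gate_center=0.48, gate_width=0.05),
        OrientationComponent("B_B", mu2=3.48, sigma2=0.018, mu3=0.94, sigma3=0.028,
                             weight=1.0 - basin_split, gate_center=0.48, gate_width=0.05),
        OrientationComponent("E", mu2=4.30, sigma2=0.10, mu3=0.30, sigma3=0.22,
                             weight=1.0, gate_center=0.73, gate_width=0.06),
        OrientationComponent("U", mu2=5.20, sigma2=0.45, mu3=0.0, sigma3=0.55,
                             weight=0.05),
    )


DEFAULT_ORIENTATION_COMPONENTS = _default_components()


@dataclass(frozen=True)
class ModelPotential:
    """Analytic ground-truth free-energy surface over (xi1, xi2, xi3).

    The xi1 marginal at ``reference_temperature`` is exactly
    ``marginal_xi1`` (plateau plus Gaussian wells); orientation structure
    is carried by a normalised conditional density and therefore does not
    distort the marginal.
    """

    wells: tuple[GaussianWell, ...]
    components: tuple[OrientationComponent, ...] = DEFAULT_ORIENTATION_COMPONENTS
    plateau_value: float = 0.0
    n_pip3: int = 1
    reference_temperature: float = DEFAULT_TEMPERATURE

    # -- 1D part ----------------------------------------------------------
    def marginal_xi1(self, xi1) -> np.ndarray:
        """Exact 1D marginal free energy F(xi1) in kJ/mol (plateau gauge)."""
        xi1 = np.asarray(xi1, dtype=float)
        u = np.full(xi1.shape, self.plateau_value)
        for w in self.wells:
            z = (xi1 - w.center) / w.width
            u = u + w.depth * np.exp(-0.5 * z * z)
        return u

    # -- full surface ------------------------------------------------------
    def _log_conditional(self, xi1, xi2, xi3) -> np.ndarray:
        gates = np.stack([c.gate(xi1) for c in self.components])
        total = gates.sum(axis=0)
        logps = np.stack([c.log_density(xi2, xi3) for c in self.components])
        # log sum_k w_k(xi1) p_k(xi2, xi3), with weights normalised per frame
        m = logps.max(axis=0)
        mix = (gates / total) * np.exp(logps - m)
        return m + np.log(mix.sum(axis=0))

    def energy(self, xi1, xi2, xi3) -> np.ndarray:
        """Total energy U (kJ/mol); +inf outside the declared domain."""
        xi1 = np.asarray(xi1, dtype=float)
        xi2 = np.asarray(xi2, dtype=float)
        xi3 = np.asarray(xi3, dtype=float)
        kt = rt(self.reference_temperature)
        with np.errstate(invalid="ignore"):
            u = self.marginal_xi1(xi1) - kt * self._log_conditional(xi1, xi2, xi3)
        bad = (
            (xi1 < XI1_DOMAIN[0]) | (xi1 > XI1_DOMAIN[1])
            | (xi3 < XI3_DOMAIN[0]) | (xi3 > XI3_DOMAIN[1])
            | ~np.isfinite(u)
        )
        return np.where(bad, np.inf, u)

    # -- quadrature oracles --------------------------------------------------
    def marginal_by_quadrature(self, xi1_grid, temperature: float | None = None,
                               n2: int = 201, n3: int = 201) -> np.ndarray:
        """xi1 marginal via numerical integration over (xi2, xi3).

        Independent of ``marginal_xi1``; used to validate the factorised
        construction.  Returned in the plateau-zero gauge.
        """
        T = temperature or self.reference_temperature
        kt = rt(T)
        xi2 = np.linspace(2.5, 7.5, n2)
        xi3 = np.linspace(XI3_DOMAIN[0], XI3_DOMAIN[1], n3)
        X2, X3 = np.meshgrid(xi2, xi3, indexing="ij")
        out = np.empty(len(xi1_grid))
        for i, x1 in enumerate(np.asarray(xi1_grid, dtype=float)):
            u = self.energy(np.full(X2.shape, x1), X2, X3)
            z = integrate.trapezoid(
                integrate.trapezoid(np.exp(-u / kt), xi3, axis=1), xi2)
            out[i] = -kt * np.log(z)
        # plateau gauge: reference at the largest xi1 supplied
        ref_u = self.marginal_xi1(np.max(xi1_grid))
        return out - out[np.argmax(xi1_grid)] + ref_u

    def biased_moments(self, center: float, force_constant: float,
                       temperature: float | None = None) -> tuple[float, float]:
        """Mean and variance of xi1 under the biased Boltzmann density.

        The bias is the harmonic window potential 0.5*k*(xi1-center)^2.
        Quadrature on the exact xi1 marginal (valid at the reference
        temperature, where orientation integrates out exactly).
        """
        T = temperature or self.reference_temperature
        kt = rt(T)
        x = np.linspace(XI1_DOMAIN[0], XI1_DOMAIN[1], 4001)
        u = self.marginal_xi1(x) + 0.5 * force_constant * (x - center) ** 2
        w = np.exp(-(u - u.min()) / kt)
        z = integrate.trapezoid(w, x)
        mean = integrate.trapezoid(x * w, x) / z
        var = integrate.trapezoid((x - mean) ** 2 * w, x) / z
        return float(mean), float(var)


def make_model_potential(
    minima_xi1,
    depths,
    orientation_basins=None,
    n_pip3: int = 1,
    *,
    well_width: float = 0.04,
    depth_increment: float = DEFAULT_DEPTH_INCREMENT,
    basin_split: float = 0.5,
) -> ModelPotential:
    """Build a ground-truth surface from declared xi1 minima and depths.

    Parameters
    ----------
    minima_xi1 : sequence of float
        Positions (nm) of the xi1 wells, each within [0.35, 1.5].
    depths : sequence of float
        Well depths (kJ/mol, <= 0) at ``n_pip3 = 1``.
    orientation_basins : sequence of (mu2, mu3, depth), optional
        Override the default orientation components with explicit bound
        basins at the given (COM distance, cos-theta) centres; relative
        depths set the mixture weights.
    n_pip3 : int
        Lipid count per leaflet.  The deepest (bound) well deepens by
        ``depth_increment`` kJ/mol per additional lipid, saturating at
        five.
    basin_split : float
        Fraction of bound-orientation weight assigned to the B_A basin.

    Raises
    ------
    ValueError
        For positive depths, minima outside [0.35, 1.5] nm, or two minima
        closer than 0.05 nm (the marginal oracle becomes ill conditioned).
    """
    minima = [float(m) for m in minima_xi1]
    depths = [float(d) for d in depths]
    if len(minima) != len(depths):
        raise ValueError("minima_xi1 and depths must have equal length")
    if n_pip3 < 1:
        raise ValueError(f"n_pip3 must be >= 1, got {n_pip3}")
    for m in minima:
        if not 0.35 <= m <= 1.5:
            raise ValueError(f"well position {m} nm outside [0.35, 1.5] nm")
    for d in depths:
        if d > 0:
            raise ValueError(f"well depth must be <= 0, got {d}")
    srt = sorted(minima)
    for a, b in zip(srt, srt[1:]):
        if b - a < 0.05:
            raise ValueError(
                f"wells at {a} and {b} nm are closer than 0.05 nm: "
                "ground-truth marginal would be ill conditioned")

    # bound = deepest declared well; deepen with lipid count, saturating
    depths = list(depths)
    if any(d < 0 for d in depths):
        i_bound = int(np.argmin(depths))
        extra = depth_increment * (min(n_pip3, SATURATION_N_PIP3) - 1)
        depths[i_bound] -= extra

    wells = tuple(
        GaussianWell(center=m, depth=d, width=well_width)
        for m, d in zip(minima, depths)
    )

    if orientation_basins is None:
        components = _default_components(basin_split)
    else:
        gate_center = min(minima) if minima else 0.48
        bound = []
        weights = np.array([np.exp(-float(d) / 4.0) for _, _, d in orientation_basins])
        weights = weights / weights.sum()
        for (mu2, mu3, _d), w in zip(orientation_basins, weights):
            bound.append(OrientationComponent(
                f"basin@{mu2:.2f}", mu2=float(mu2), sigma2=0.018, mu3=float(mu3),
                sigma3=0.028, weight=float(w), gate_center=gate_center,
                gate_width=0.05))
        components = tuple(bound) + _default_components()[2:]

    return ModelPotential(wells=wells, components=components, n_pip3=n_pip3)


def family_over_pip3(minima_xi1, depths, n_values, **kwargs) -> dict[int, ModelPotential]:
    """A family of potentials sharing geometry, varying only the lipid count."""
    return {int(n): make_model_potential(minima_xi1, depths, n_pip3=int(n), **kwargs)
            for n in n_values}
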