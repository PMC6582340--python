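"""Closed-form kinetics of the two-state facilitated-diffusion model.

A DNA-binding protein locates its target by alternating rounds of 1D
sliding along the DNA (in a non-specific *search* conformation, S) with 3D
excursions, and must then *recognize* the site by switching to its specific
binding conformation (R) across a free-energy barrier.  This module chains
the full analytic model from the microscopic hopping time ``tau0`` up to the
total mean recognition time ``tau_R``:

* ``tau0`` — time to hop one base pair for translation-rotation-coupled
  sliding (Stokes friction plus the rotational penalty of tracking the
  helical groove).
* ``D_1D = exp(-sigma^2) / tau0`` — sliding diffusion coefficient on a
  rugged landscape with Gaussian disorder of standard deviation ``sigma``
  (all energies in units of k_B*T; D_1D is carried in bp^2/s with the base
  pair as the lattice unit).
* ``tau_1D = tau0 * exp(E_ns + sigma^2/2)`` — mean dwell per 1D round, set
  by the non-specific binding energy ``E_ns``.
* ``<n> = 2 sqrt(D_1D tau_1D)`` — mean number of base pairs scanned per
  round, so a genome of M sites takes ``M/<n>`` rounds.
* ``k_SR = exp(-dG_barrier)/tau0`` — Arrhenius rate of the S->R switch,
  competing with the per-base residence rate ``k_res = 4 D_1D`` to give the
  per-visit recognition probability ``P_f`` and the per-round probability
  ``P_loc = min(1, <n> P_f)``.
* ``tau_R = tau_S / P_loc`` with ``tau_S = (M/<n>) (tau_1D + tau_3D)``.

The coupling between search speed and recognition speed enters through the
similarity index ``chi`` (the overlap between the S and R binding patches,
computed from structures by :mod:`searchkin.frustration`):

    sigma      = chi * sigma_max
    dG_barrier = dG_max * (1 - chi)

so smooth-sliding, fast-search proteins (low chi, high frustration) pay
with a high recognition barrier and vice versa.  ``chi_scan`` and
``optimal_chi`` explore this trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import InvalidParameterError, ParameterRangeError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ModelParameters",
    "LandscapeParameters",
    "KineticsBreakdown",
    "base_timescale",
    "diffusion_coefficient_1d",
    "d1d_to_si",
    "d1d_from_si",
    "residence_rate",
    "sliding_round_time",
    "mean_scan_length",
    "transition_rate",
    "recognition_probability",
    "localization_probability",
    "search_time",
    "total_recognition_time",
    "chi_scan",
    "optimal_chi",
    "roughness_from_experimental_d1d",
]

#: Boltzmann constant, J/K (CODATA exact value).
BOLTZMANN_J_PER_K = 1.380649e-23

#: largest exponent magnitude accepted before a ParameterRangeError is
#: raised instead of silently returning inf/0.
EXPONENT_GUARD = 700.0


def _guarded_exp(x: float) -> float:
    if abs(x) > EXPONENT_GUARD:
        raise ParameterRangeError(
            f"exponent {x:g} exceeds the guard |x| <= {EXPONENT_GUARD:g}; "
            "the requested parameters are outside the model's numeric range"
        )
    return math.exp(x)


@dataclass(frozen=True)
class ModelParameters:
    """Physical and geometric constants of the searcher and the DNA.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    viscosity : float
        Solvent viscosity, Pa*s.
    protein_radius : float
        Hydrodynamic radius R of the protein, m.
    center_offset : float
        Distance R_OC between the protein's center of mass and the DNA
        axis, m.  Taken equal to R by default.
    bp_rise : float
        Rise per base pair along the DNA axis, m.
    genome_length : float
        Number of base pairs M being searched (dimensionless count).
    tau_3d : float
        Mean duration of one 3D excursion, s.  The model never fixes this
        value; the default 0 gives the pure-sliding bound, and
        ``tau_3d=base_timescale(p)`` is a documented alternative preset.
    """

    temperature: float = 298.0
    viscosity: float = 1.0e-3
    protein_radius: float = 3.0e-9
    center_offset: float = 3.0e-9
    bp_rise: float = 0.34e-9
    genome_length: float = 5.0e6
    tau_3d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "protein_radius",
                     "center_offset", "bp_rise"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {v!r}")
        if not (np.isfinite(self.genome_length) and self.genome_length >= 1):
            raise InvalidParameterError(
                f"genome_length must be >= 1, got {self.genome_length!r}")
        if not (np.isfinite(self.tau_3d) and self.tau_3d >= 0):
            raise InvalidParameterError(
                f"tau_3d must be >= 0, got {self.tau_3d!r}")

    @property
    def kbt_joule(self) -> float:
        """Thermal energy k_B*T in joules."""
        return BOLTZMANN_J_PER_K * self.temperature


@dataclass(frozen=True)
class LandscapeParameters:
    """Energetic inputs of the two-state landscape, in units of k_B*T.

    ``sigma`` (sliding roughness) and ``dg_barrier`` (S->R transition
    barrier) are derived from the similarity index ``chi``::

        sigma      = chi * sigma_max
        dg_barrier = dg_max * (1 - chi)

    ``chi`` must lie in [0, 1] for the kinetic model: negative values
    (possible for structure-derived similarity indices) are rejected with
    an explicit error, values above 1 are clamped to 1.

    Notes
    -----
    ``sigma_max`` defaults to 5 k_B*T, the roughness that makes the
    specific complex thermodynamically stable; ``dg_max`` and ``e_ns``
    depend strongly on the protein and have no defensible default, so they
    are required.
    """

    chi: float
    dg_max: float
    e_ns: float
    sigma_max: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.chi):
            raise InvalidParameterError(f"chi must be finite, got {self.chi!r}")
        if self.chi < 0:
            raise InvalidParameterError(
                f"chi = {self.chi:g} is negative; the kinetic model is "
                "defined on chi in [0, 1] (structure-derived chi < 0 means "
                "a net-negative patch and cannot be mapped to sigma/dG)")
        if self.chi > 1:
            object.__setattr__(self, "chi", 1.0)
        for name in ("sigma_max", "dg_max", "e_ns"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")

    @property
    def sigma(self) -> float:
        """Sliding roughness sigma = chi * sigma_max, k_B*T."""
        return self.chi * self.sigma_max

    @property
    def dg_barrier(self) -> float:
        """S->R barrier dG = dg_max * (1 - chi), k_B*T."""
        return self.dg_max * (1.0 - self.chi)

    def with_chi(self, chi: float) -> "LandscapeParameters":
        """Copy of these parameters at a different similarity index."""
        return replace(self, chi=chi)


@dataclass(frozen=True)
class KineticsBreakdown:
    """Every intermediate kinetic quantity for one parameter point.

    Times in seconds, rates in 1/s, ``d1d`` in bp^2/s; probabilities
    dimensionless.  ``tau_r = tau_s / p_loc`` always holds, as do the
    identities ``n_mean**2 == 4 * d1d * tau_1d`` and
    ``tau_1d * k_off == 1`` (``k_off = 1/tau_1d``).
    """

    chi: float
    sigma: float
    dg_barrier: float
    tau0: float
    d1d: float
    k_res: float
    tau_1d: float
    n_mean: float
    k_sr: float
    p_f: float
    p_loc: float
    tau_s: float
    tau_r: float

    @property
    def k_off(self) -> float:
        """Dissociation rate from non-specific DNA, 1/tau_1d."""
        return 1.0 / self.tau_1d

    @property
    def tau_res(self) -> float:
        """Mean residence time on one base pair, 1/k_res."""
        return 1.0 / self.k_res

    @property
    def tau_sr(self) -> float:
        """Mean S->R transition time, 1/k_sr."""
        return 1.0 / self.k_sr

    def as_dict(self) -> dict:
        """Plain-float dict (JSON-friendly)."""
        return {
            "chi": self.chi, "sigma_kT": self.sigma,
            "dg_kT": self.dg_barrier, "tau0_s": self.tau0,
            "d1d_bp2_per_s": self.d1d, "k_res_per_s": self.k_res,
            "tau1d_s": self.tau_1d, "n_mean_bp": self.n_mean,
            "k_sr_per_s": self.k_sr, "tau_sr_s": self.tau_sr,
            "p_f": self.p_f, "p_loc": self.p_loc,
            "tau_s_s": self.tau_s, "tau_r_s": self.tau_r,
        }


def base_timescale(params: ModelParameters, *,
                   include_rotation: bool = True) -> float:
    """Time tau0 to hop one base pair during rotation-coupled sliding.

    The protein tracks the helical groove, so advancing one base pair
    costs both translational Stokes friction (6 pi eta R) and rotational
    friction about the DNA axis; one full turn per 10 bp gives the
    (2 pi / (10 BP))^2 geometric factor multiplying the rotational drag
    8 pi eta R^3 + 6 pi eta R R_OC^2::

        tau0 = [6 pi eta R
                + (2 pi / (10 BP))^2 (8 pi eta R^3 + 6 pi eta R R_OC^2)]
               * BP^2 / (k_B T)

    With ``include_rotation=False`` (diagnostic) only the translational
    term is kept, giving the pure Stokes time 6 pi eta R BP^2 / (k_B T).
    """
    eta = params.viscosity
    r = params.protein_radius
    bp = params.bp_rise
    translational = 6.0 * math.pi * eta * r
    friction = translational
    if include_rotation:
        rotational = (8.0 * math.pi * eta * r ** 3
                      + translational * params.center_offset ** 2)
        friction = friction + (2.0 * math.pi / (10.0 * bp)) ** 2 * rotational
    return friction * bp ** 2 / params.kbt_joule


def diffusion_coefficient_1d(sigma: float, tau0: float) -> float:
    """Sliding diffusion coefficient D_1D on a rugged landscape, bp^2/s.

    Gaussian energetic disorder of standard deviation ``sigma`` (k_B*T)
    suppresses diffusion as ``D_1D = exp(-sigma^2) / tau0`` (with the base
    pair as the unit of length).  Use :func:`d1d_to_si` for m^2/s.
    """
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma!r}")
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be > 0, got {tau0!r}")
    return _guarded_exp(-(sigma ** 2)) / tau0


def d1d_to_si(d1d_bp2: float, bp_rise: float = 0.34e-9) -> float:
    """Convert D_1D from bp^2/s to m^2/s (multiply by BP^2)."""
    return d1d_bp2 * bp_rise ** 2


def d1d_from_si(d1d_si: float, bp_rise: float = 0.34e-9) -> float:
    """Convert D_1D from m^2/s to bp^2/s (divide by BP^2)."""
    return d1d_si / bp_rise ** 2


def residence_rate(d1d: float) -> float:
    """Rate k_res = 4 D_1D to step off a base pair (D_1D in bp^2/s).

    Its inverse is the mean residence time per base pair during sliding;
    it is the rate the S->R switch must beat at the target site.
    """
    if d1d <= 0:
        raise InvalidParameterError(f"d1d must be > 0, got {d1d!r}")
    return 4.0 * d1d


def sliding_round_time(e_ns: float, sigma: float, tau0: float) -> float:
    """Mean duration tau_1D of one 1D round (= 1/k_off), seconds.

    ``tau_1D = tau0 * exp(E_ns + sigma^2/2)``: the dwell grows with the
    non-specific binding energy and, more weakly, with the roughness
    (deep wells of the disorder retard escape as well as sliding).
    """
    if e_ns < 0:
        raise InvalidParameterError(f"e_ns must be >= 0, got {e_ns!r}")
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma!r}")
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be > 0, got {tau0!r}")
    return tau0 * _guarded_exp(e_ns + 0.5 * sigma ** 2)


def mean_scan_length(d1d: float, tau_1d: float) -> float:
    """Mean number of base pairs scanned per 1D round, <n> = 2 sqrt(D tau).

    Kept real-valued: it enters the round count M/<n> and P_loc as a mean,
    not as an integer number of sites.
    """
    if d1d <= 0 or tau_1d <= 0:
        raise InvalidParameterError("d1d and tau_1d must be > 0")
    return 2.0 * math.sqrt(d1d * tau_1d)


def transition_rate(dg_barrier: float, tau0: float) -> float:
    """Arrhenius rate of the S->R switch, k_SR = exp(-dG)/tau0."""
    if dg_barrier < 0:
        raise InvalidParameterError(
            f"dg_barrier must be >= 0, got {dg_barrier!r}")
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be > 0, got {tau0!r}")
    return _guarded_exp(-dg_barrier) / tau0


def recognition_probability(k_sr: float, k_res: float) -> float:
    """Per-visit probability P_f = k_SR / (k_SR + k_res) of switching S->R.

    Each arrival at the target is a race between recognizing (k_SR) and
    stepping away (k_res).
    """
    if k_sr < 0 or k_res < 0:
        raise InvalidParameterError("rates must be >= 0")
    if k_sr == 0 and k_res == 0:
        raise InvalidParameterError(
            "P_f is undefined for k_sr = k_res = 0")
    return k_sr / (k_sr + k_res)


def localization_probability(n_mean: float, p_f: float) -> float:
    """Per-round recognition probability P_loc = min(1, <n> P_f).

    During a round of <n> scanned sites the walk makes ~<n>^2 steps, so
    each covered site is revisited ~<n> times; <n> independent attempts at
    probability P_f give <n> P_f, clamped at certainty.
    """
    if n_mean <= 0:
        raise InvalidParameterError(f"n_mean must be > 0, got {n_mean!r}")
    if not (0 < p_f <= 1):
        raise InvalidParameterError(f"p_f must be in (0, 1], got {p_f!r}")
    return min(1.0, n_mean * p_f)


def search_time(params: ModelParameters, tau_1d: float,
                n_mean: float) -> float:
    """Mean time tau_S = (M/<n>) (tau_1D + tau_3D) to first reach the target."""
    if tau_1d <= 0 or n_mean <= 0:
        raise InvalidParameterError("tau_1d and n_mean must be > 0")
    return params.genome_length / n_mean * (tau_1d + params.tau_3d)


def total_recognition_time(landscape: LandscapeParameters,
                           params: ModelParameters) -> KineticsBreakdown:
    """Chain the whole model and return every intermediate quantity.

    ``tau_R = tau_S / P_loc`` is the total mean time to find *and* bind
    the target; the returned :class:`KineticsBreakdown` exposes each link
    of the chain for inspection and testing.
    """
    tau0 = base_timescale(params)
    sigma = landscape.sigma
    dg = landscape.dg_barrier
    d1d = diffusion_coefficient_1d(sigma, tau0)
    k_res = residence_rate(d1d)
    tau_1d = sliding_round_time(landscape.e_ns, sigma, tau0)
    n_mean = mean_scan_length(d1d, tau_1d)
    k_sr = transition_rate(dg, tau0)
    p_f = recognition_probability(k_sr, k_res)
    p_loc = localization_probability(n_mean, p_f)
    tau_s = search_time(params, tau_1d, n_mean)
    tau_r = tau_s / p_loc
    return KineticsBreakdown(
        chi=landscape.chi, sigma=sigma, dg_barrier=dg, tau0=tau0, d1d=d1d,
        k_res=k_res, tau_1d=tau_1d, n_mean=n_mean, k_sr=k_sr, p_f=p_f,
        p_loc=p_loc, tau_s=tau_s, tau_r=tau_r)


def chi_scan(chi_grid, landscape_template: LandscapeParameters,
             params: ModelParameters) -> pd.DataFrame:
    """Evaluate the model on a grid of similarity indices.

    Parameters
    ----------
    chi_grid : array-like
        Strictly increasing values in [0, 1].
    landscape_template : LandscapeParameters
        Template whose ``chi`` is replaced at every grid point.
    params : ModelParameters

    Returns
    -------
    pandas.DataFrame
        One row per chi with columns ``chi, sigma_kT, dg_kT, tau1d_s,
        tau_sr_s, tau_r_s`` plus the remaining breakdown fields
        (``d1d_bp2_per_s, n_mean_bp, p_f, p_loc, tau_s_s``), enough to
        re-plot every trade-off curve and the (sigma, dG) surface.
    """
    grid = np.asarray(chi_grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("chi_grid must not be empty")
    if grid.min() < 0 or grid.max() > 1:
        raise InvalidParameterError("chi_grid values must lie in [0, 1]")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("chi_grid must be strictly increasing")
    rows = []
    for chi in grid:
        b = total_recognition_time(landscape_template.with_chi(chi), params)
        rows.append({
            "chi": chi, "sigma_kT": b.sigma, "dg_kT": b.dg_barrier,
            "tau1d_s": b.tau_1d, "tau_sr_s": b.tau_sr, "tau_r_s": b.tau_r,
            "d1d_bp2_per_s": b.d1d, "n_mean_bp": b.n_mean,
            "p_f": b.p_f, "p_loc": b.p_loc, "tau_s_s": b.tau_s,
        })
    return pd.DataFrame(rows)


def optimal_chi(landscape_template: LandscapeParameters,
                params: ModelParameters,
                resolution: float = 1e-3) -> tuple[float, float]:
    """Similarity index chi* minimizing the total recognition time.

    Grid search over [0, 1] at ``resolution`` followed by bounded local
    refinement (golden-section via scipy) around the best grid point.
    Exact ties are broken toward *larger* chi, so the result is
    deterministic; the choice matters only where tau_R is flat because
    P_loc has clamped at 1, and there the whole plateau extends to
    chi = 1 (the low-frustration regime), which the largest tied value
    represents.

    Returns
    -------
    (chi_star, tau_r_star)
    """
    if not (np.isfinite(resolution) and resolution > 0):
        raise InvalidParameterError(
            f"resolution must be > 0, got {resolution!r}")

    def objective(chi: float) -> float:
        return total_recognition_time(
            landscape_template.with_chi(float(chi)), params).tau_r

    grid = np.arange(0.0, 1.0 + 0.5 * resolution, resolution)
    grid = np.clip(grid, 0.0, 1.0)
    values = np.array([objective(c) for c in grid])
    i = grid.size - 1 - int(np.argmin(values[::-1]))  # last exact tie wins
    best_chi, best_val = float(grid[i]), float(values[i])
    lo = float(grid[max(i - 1, 0)])
    hi = float(grid[min(i + 1, grid.size - 1)])
    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": min(resolution * 1e-6, 1e-10)})
        if np.isfinite(res.fun) and res.fun < best_val:
            best_chi, best_val = float(res.x), float(res.fun)
    return best_chi, best_val


def roughness_from_experimental_d1d(d_exp_si: float,
                                    params: ModelParameters) -> float:
    """Invert the diffusion law: sigma (k_B*T) from a measured D_1D (m^2/s).

    ``sigma = sqrt(ln((BP^2/tau0) / D_exp))``.  A measurement above the
    zero-roughness ceiling ``BP^2/tau0`` is inconsistent with the sliding
    model (the protein would diffuse faster than on a flat landscape) and
    raises an error naming the ceiling.
    """
    if not (np.isfinite(d_exp_si) and d_exp_si > 0):
        raise InvalidParameterError(f"d_exp must be > 0, got {d_exp_si!r}")
    tau0 = base_timescale(params)
    ceiling = params.bp_rise ** 2 / tau0
    if d_exp_si > ceiling:
        raise InvalidParameterError(
            f"D_1D = {d_exp_si:.3e} m^2/s exceeds the zero-roughness "
            f"ceiling BP^2/tau0 = {ceiling:.3e} m^2/s; the measurement is "
            "inconsistent with rotation-coupled sliding at these parameters")
    return math.sqrt(math.log(ceiling / d_exp_si))
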