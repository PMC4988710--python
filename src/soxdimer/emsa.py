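"""EMSA titration analysis: four-parameter logistic fits and binding kinetics.

The binding isotherm measured by a gel-shift titration is modelled with the
four-parameter logistic (4PL) curve

    AB = d + (a - d) / (1 + (B / Kd)^b)

where ``B`` is the protein concentration, ``AB`` the normalized bound-band
intensity, ``a``/``d`` the lower/upper asymptotes, ``Kd`` the midpoint
concentration and ``b`` the steepness (Hill coefficient).  Kinetic rates are
back-calculated from a dissociation half-life via k_off = ln2 / t_half and
k_on = k_off / Kd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "FourPLFit",
    "KineticEstimate",
    "BandPattern",
    "four_pl",
    "fit_4pl",
    "simulate_titration",
    "koff_from_halflife",
    "kon_from_kd_koff",
    "kinetic_estimate",
    "classify_dimerization",
    "normalize_intensities",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """One EMSA titration: protein concentration vs normalized bound fraction.

    ``dna_conc`` (the constant probe concentration) is carried for bookkeeping
    and sanity warnings but does not enter the 4PL model, which is valid when
    the probe is well below the Kd.
    """

    protein_conc: np.ndarray  # nM, strictly increasing
    bound_fraction: np.ndarray  # unitless
    dna_conc: float = 0.0  # nM
    label: str = ""

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.bound_fraction = np.asarray(self.bound_fraction, dtype=float)
        if self.protein_conc.shape != self.bound_fraction.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.protein_conc <= 0):
            raise ValueError("protein concentrations must be strictly positive")
        if np.any(np.diff(self.protein_conc) <= 0):
            raise ValueError("protein concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.bound_fraction)):
            raise ValueError("bound fractions must be finite")

    def __len__(self) -> int:
        return len(self.protein_conc)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters with Gauss-Newton standard errors."""

    a: float
    d: float
    kd: float  # nM
    b: float  # Hill coefficient
    a_se: float = float("nan")
    d_se: float = float("nan")
    kd_se: float = float("nan")
    b_se: float = float("nan")
    converged: bool = True
    rss: float = float("nan")
    message: str = ""

    def predict(self, conc) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float), self.a, self.d, self.kd, self.b)


@dataclass(frozen=True)
class KineticEstimate:
    """Off-rate / on-rate pair back-calculated from a half-life and a Kd."""

    half_life: float  # s
    k_off: float  # 1/s
    k_on: float  # 1/(M s)
    kd_used: float  # M


@dataclass(frozen=True)
class BandPattern:
    """Occupancy-band fractions observed at a sub-stoichiometric titration point."""

    ratio: float  # protein : DNA stoichiometric ratio
    free: float
    single_occupied: float
    double_occupied: float

    def __post_init__(self) -> None:
        total = self.free + self.single_occupied + self.double_occupied
        if min(self.free, self.single_occupied, self.double_occupied) < 0:
            raise ValueError("band fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band fractions must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# 4PL model and fitting
# ---------------------------------------------------------------------------

def four_pl(conc, a: float, d: float, kd: float, b: float):
    """4PL forward model: ``d + (a - d) / (1 + (conc/kd)^b)``."""
    conc = np.asarray(conc, dtype=float)
    return d + (a - d) / (1.0 + (conc / kd) ** b)


def fit_4pl(
    series: TitrationSeries,
    init: Optional[Tuple[float, float, float, float]] = None,
    *,
    xtol: float = 1e-12,
    max_iter: int = 500,
) -> FourPLFit:
    """Least-squares 4PL fit of a titration series.

    Kd is fit on a log scale internally for conditioning and reported on the
    linear scale.  Standard errors come from the Gauss-Newton curvature
    (J'J)^-1 scaled by the residual variance.  Non-convergence is reported via
    the ``converged`` flag, never silently.
    """
    if len(series) < 5:
        raise ValueError("need at least 5 titration points to fit 4 parameters")
    y = series.bound_fraction
    x = series.protein_conc
    if y.max() - y.min() < 1e-6:
        raise ValueError("degenerate flat titration: no dynamic range to fit")

    if init is None:
        a0, d0 = float(y.min()), float(y.max())
        kd0 = float(np.sqrt(x.min() * x.max()))  # geometric mid of the grid
        b0 = 1.0
    else:
        a0, d0, kd0, b0 = init

    def residuals(theta):
        a, d, log_kd, log_b = theta
        return four_pl(x, a, d, np.exp(log_kd), np.exp(log_b)) - y

    theta0 = np.array([a0, d0, np.log(kd0), np.log(b0 if b0 > 0 else 1.0)])
    res = least_squares(
        residuals, theta0, method="lm", xtol=xtol, ftol=xtol, gtol=xtol,
        max_nfev=max_iter * 4,
    )
    a, d, kd, b = res.x[0], res.x[1], float(np.exp(res.x[2])), float(np.exp(res.x[3]))

    # Gauss-Newton covariance on the internal parameterization, then delta
    # method back to the linear scale for kd and b.
    n, p = len(y), 4
    dof = max(n - p, 1)
    rss = float(2.0 * res.cost)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        se_internal = np.sqrt(np.clip(np.diag(cov), 0, None))
        a_se, d_se = float(se_internal[0]), float(se_internal[1])
        kd_se, b_se = float(se_internal[2] * kd), float(se_internal[3] * b)
    except np.linalg.LinAlgError:
        a_se = d_se = kd_se = b_se = float("nan")

    if series.dna_conc > 0 and series.dna_conc > kd / 5.0:
        warnings.warn(
            f"DNA concentration {series.dna_conc} nM is not well below the "
            f"fitted Kd {kd:.3g} nM; the 4PL Kd is then only apparent",
            stacklevel=2,
        )

    return FourPLFit(
        a=float(a), d=float(d), kd=kd, b=b,
        a_se=a_se, d_se=d_se, kd_se=kd_se, b_se=b_se,
        converged=bool(res.success), rss=rss, message=res.message,
    )


def simulate_titration(
    a: float,
    d: float,
    kd: float,
    b: float,
    conc_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    dna_conc: float = 9.0,
    label: str = "",
) -> TitrationSeries:
    """Forward-simulate a titration (optionally with Gaussian read-out noise)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    conc = np.asarray(conc_grid, dtype=float)
    y = four_pl(conc, a, d, kd, b)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return TitrationSeries(conc, y, dna_conc=dna_conc, label=label)


def normalize_intensities(intensities: Sequence[float]) -> np.ndarray:
    """Normalize band intensities to the highest-concentration observation."""
    arr = np.asarray(intensities, dtype=float)
    if arr[-1] == 0:
        raise ValueError("cannot normalize: intensity at highest concentration is 0")
    return arr / arr[-1]


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def koff_from_halflife(half_life_s: float) -> float:
    """Off-rate from a dissociation half-life: k_off = ln2 / t_half (1/s)."""
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    return LN2 / half_life_s


def kon_from_kd_koff(kd_molar: float, k_off: float) -> float:
    """On-rate from Kd and off-rate: k_on = k_off / Kd (1/(M s))."""
    if kd_molar <= 0 or k_off <= 0:
        raise ValueError("kd and k_off must be positive")
    return k_off / kd_molar


def kinetic_estimate(half_life_s: float, kd_molar: float) -> KineticEstimate:
    """Bundle half-life -> (k_off, k_on) back-calculation."""
    k_off = koff_from_halflife(half_life_s)
    return KineticEstimate(
        half_life=half_life_s,
        k_off=k_off,
        k_on=kon_from_kd_koff(kd_molar, k_off),
        kd_used=kd_molar,
    )


# ---------------------------------------------------------------------------
# band-pattern classification
# ---------------------------------------------------------------------------

def classify_dimerization(pattern: BandPattern, threshold: float = 0.05) -> str:
    """Call a mutant dimerizing or not from its sub-stoichiometric band pattern.

    A functional dimerization domain fills tandem sites cooperatively: only
    the double-occupied band appears.  A broken one populates single- and
    double-occupied bands as a mixture.
    """
    if pattern.ratio >= 2.0:
        raise ValueError(
            "band-pattern classification requires a sub-stoichiometric ratio "
            "(< 2 proteins per duplex)"
        )
    bound = pattern.single_occupied + pattern.double_occupied
    if bound <= 0:
        return "indeterminate"
    if pattern.single_occupied < threshold and pattern.double_occupied > 0:
        return "dimerizing"
    return "non_dimerizing"
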