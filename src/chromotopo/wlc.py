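"""Worm-like-chain (WLC) analysis of single-tether force–extension data.

A tethered polymer under tension ``F`` extends according to the Marko–Siggia
interpolation formula

    F(x) = (kB*T / Lp) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ],

where ``Lp`` is the persistence length (nm), ``Lc`` the contour length (nm)
and ``x`` the end-to-end extension (nm).  Magnetic tweezers clamp the tension
and record the extension, so fits here minimise squared *extension* residuals
at fixed tension.  Tensions above an unfolding cutoff (default 10 pN) are
excluded, since nucleosomal fibers unfold beyond that regime and the entropic
WLC description no longer applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "ROOM_TEMPERATURE_K",
    "ForceExtensionRecord",
    "WLCFit",
    "ConditionSummary",
    "kbt",
    "wlc_force",
    "wlc_extension",
    "fit_wlc",
    "spring_constant",
    "contour_from_bp",
    "summarize_condition",
    "compare_conditions",
]

#: Boltzmann constant in pN*nm/K.
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

#: Default assay temperature (K); room-temperature experiments.
ROOM_TEMPERATURE_K = 298.15

#: B-form DNA helical rise, nm per base pair.
BP_RISE_NM = 0.34

#: Default tension cutoff (pN) above which fibers unfold and points are
#: excluded from WLC fits.  Configurable in :func:`fit_wlc`.
DEFAULT_MAX_TENSION_PN = 10.0


def kbt(temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in pN*nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_PN_NM_PER_K * temperature


@dataclass(frozen=True)
class ForceExtensionRecord:
    """One tether's tension–extension series.

    Parameters
    ----------
    tether_id : str
        Identifier of the tethered molecule.
    tensions_pn, extensions_nm : arrays
        Paired tension (pN) and extension (nm) readings, ordered by
        strictly increasing tension.
    temperature_k : float
        Assay temperature in kelvin.
    condition_label : str
        Experimental condition (e.g. ``"DNA"``, ``"dm_octamer"``).
    flags : tuple of str
        Data-quality flags, e.g. ``"tension>10pN"`` when the series enters
        the unfolding regime.
    """

    tether_id: str
    tensions_pn: np.ndarray
    extensions_nm: np.ndarray
    temperature_k: float = ROOM_TEMPERATURE_K
    condition_label: str = ""
    flags: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.tensions_pn, dtype=float)
        x = np.asarray(self.extensions_nm, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("tensions and extensions must be equal-length 1-D arrays")
        if t.size < 6:
            raise ValueError(f"need at least 6 points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("tensions must be strictly increasing")
        object.__setattr__(self, "tensions_pn", t)
        object.__setattr__(self, "extensions_nm", x)

    def __len__(self) -> int:
        return self.tensions_pn.size


@dataclass(frozen=True)
class WLCFit:
    """Result of fitting the Marko–Siggia model to one tether."""

    persistence_length: float
    contour_length: float
    se_persistence: float
    se_contour: float
    rss: float
    n_points_used: int
    max_tension_used: float
    converged: bool = True
    message: str = ""
    tether_id: str = ""
    condition_label: str = ""


@dataclass(frozen=True)
class ConditionSummary:
    """Across-tether summary of persistence lengths for one condition.

    ``sd_lp`` is the across-tether standard deviation; ``mean_se_lp`` the
    mean per-fit standard error — reported side by side because published
    ``±`` values may be either.
    """

    condition_label: str
    n_tethers: int
    mean_lp: float
    sd_lp: float
    mean_lc: float
    sd_lc: float
    mean_se_lp: float
    mean_spring_constant: float


def wlc_force(
    extension: float | np.ndarray,
    lp: float,
    lc: float,
    temperature: float = ROOM_TEMPERATURE_K,
) -> float | np.ndarray:
    """Marko–Siggia tension (pN) at a given extension (nm).

    Strictly increasing and convex in extension on ``[0, lc)``; diverges as
    the extension approaches the contour length.
    """
    if lp <= 0 or lc <= 0:
        raise ValueError("persistence and contour lengths must be positive")
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0) or np.any(x >= lc):
        raise ValueError("extension must lie in [0, contour_length)")
    z = x / lc
    force = (kbt(temperature) / lp) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return force if np.ndim(extension) else float(force)


def wlc_extension(
    tension: float | np.ndarray,
    lp: float,
    lc: float,
    temperature: float = ROOM_TEMPERATURE_K,
) -> float | np.ndarray:
    """Numerically invert :func:`wlc_force`: extension (nm) at a tension (pN).

    Vectorised bisection; the result satisfies ``wlc_force(x) == tension``
    to relative tolerance better than 1e-9 and always lies in ``[0, lc)``.
    """
    if lp <= 0 or lc <= 0:
        raise ValueError("persistence and contour lengths must be positive")
    f = np.asarray(tension, dtype=float)
    if np.any(f < 0):
        raise ValueError("tension must be nonnegative")
    scalar = np.ndim(tension) == 0
    f = np.atleast_1d(f)
    c = kbt(temperature) / lp
    # Bracket in the reduced coordinate z = x/Lc.  F is strictly increasing
    # in z and diverges at z=1, so [0, 1) always brackets the root.
    lo = np.zeros_like(f)
    hi = np.full_like(f, 1.0 - 1e-15)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        fmid = c * (0.25 / (1.0 - mid) ** 2 - 0.25 + mid)
        above = fmid > f
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    z = 0.5 * (lo + hi)
    x = z * lc
    return float(x[0]) if scalar else x


def fit_wlc(
    record: ForceExtensionRecord,
    max_tension: float = DEFAULT_MAX_TENSION_PN,
) -> WLCFit:
    """Least-squares (Lp, Lc) estimates for one tether.

    Minimises squared extension residuals over points with tension at or
    below ``max_tension``.  Standard errors come from the Gauss–Newton
    curvature of the objective at the optimum.

    Raises
    ------
    ValueError
        If fewer than 6 points fall below the tension cutoff.
    """
    keep = record.tensions_pn <= max_tension
    f = record.tensions_pn[keep]
    x = record.extensions_nm[keep]
    if f.size < 6:
        raise ValueError(
            f"need at least 6 points at tension <= {max_tension} pN, got {f.size}"
        )
    temp = record.temperature_k

    def residuals(theta):
        lp_, lc_ = theta
        return wlc_extension(f, lp_, lc_, temp) - x

    x0 = (50.0, 1.05 * float(np.max(x)))
    lower = (0.5, float(np.max(x)) * 1.0 + 1e-9)
    upper = (500.0, float(np.max(x)) * 50.0)
    sol = optimize.least_squares(
        residuals, x0=x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    lp_hat, lc_hat = sol.x
    rss = float(np.sum(sol.fun**2))
    dof = max(f.size - 2, 1)
    sigma2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se_lp, se_lc = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_lp = se_lc = float("nan")
    return WLCFit(
        persistence_length=float(lp_hat),
        contour_length=float(lc_hat),
        se_persistence=float(se_lp),
        se_contour=float(se_lc),
        rss=rss,
        n_points_used=int(f.size),
        max_tension_used=float(np.max(f)),
        converged=bool(sol.success),
        message=str(sol.message),
        tether_id=record.tether_id,
        condition_label=record.condition_label,
    )


def spring_constant(fit: WLCFit, temperature: float = ROOM_TEMPERATURE_K) -> float:
    """Low-force entropic spring constant k = 3*kB*T / (2*Lp*Lc), pN/nm.

    The zero-extension slope dF/dx of the Marko–Siggia relation.  Softer
    fibers (shorter Lp) are *stronger* entropic springs: k grows as either
    length shrinks.
    """
    return 3.0 * kbt(temperature) / (2.0 * fit.persistence_length * fit.contour_length)


def contour_from_bp(n_bp: int, rise: float = BP_RISE_NM) -> float:
    """B-form contour length (nm) of ``n_bp`` base pairs at ``rise`` nm/bp."""
    if n_bp < 0:
        raise ValueError(f"base-pair count must be nonnegative, got {n_bp}")
    return n_bp * rise


def summarize_condition(
    fits: Sequence[WLCFit],
    label: str,
    temperature: float = ROOM_TEMPERATURE_K,
) -> ConditionSummary:
    """Across-tether mean and SD of persistence length for one condition."""
    if len(fits) == 0:
        raise ValueError("need at least one fit to summarise")
    lps = np.array([f.persistence_length for f in fits])
    lcs = np.array([f.contour_length for f in fits])
    ses = np.array([f.se_persistence for f in fits])
    ks = np.array([spring_constant(f, temperature) for f in fits])
    ddof = 1 if len(fits) > 1 else 0
    return ConditionSummary(
        condition_label=label,
        n_tethers=len(fits),
        mean_lp=float(lps.mean()),
        sd_lp=float(lps.std(ddof=ddof)),
        mean_lc=float(lcs.mean()),
        sd_lc=float(lcs.std(ddof=ddof)),
        mean_se_lp=float(np.nanmean(ses)),
        mean_spring_constant=float(ks.mean()),
    )


def compare_conditions(a: ConditionSummary, b: ConditionSummary) -> tuple[float, float]:
    """Welch two-sample t-test on mean persistence length between conditions.

    Returns ``(t_statistic, p_value)``.
    """
    t, p = stats.ttest_ind_from_stats(
        a.mean_lp, a.sd_lp, a.n_tethers, b.mean_lp, b.sd_lp, b.n_tethers,
        equal_var=False,
    )
    return float(t), float(p)
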