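"""Seasonal outdoor PAH concentrations and B[a]P-equivalent arithmetic.

Outdoor levels enter the simulation as per-season, per-congener seasonal
averages.  The measurement literature reports them as medians and standard
deviations; environmental concentrations are strictly positive and strongly
right-skewed (SD typically exceeds the median), so each (median, SD) cell is
fitted with a lognormal law and one seasonal-average field is drawn per
Monte Carlo replicate.

Congeners co-vary with the intensity of regional combustion activity, so by
default a single lognormal quantile per season is shared by all congeners
(perfect rank correlation); fully independent sampling is available as a
switch.

Carcinogenic potency is standardized with toxic equivalency factors (TEFs):
the B[a]P-equivalent (B[a]Peq) concentration is the TEF-weighted sum over
congeners, with TEF(BaP) = 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtri

from .constants import CONGENERS, N_CONGENERS, N_SEASONS, SEASONS

__all__ = [
    "CongenerTable",
    "OutdoorConcField",
    "lognormal_from_median_sd",
    "sample_outdoor_field",
    "baep_equivalent",
]


def lognormal_from_median_sd(median: float, sd: float) -> tuple[float, float]:
    """Fit lognormal parameters (mu, sigma) to a reported median and SD.

    For ``X ~ LogNormal(mu, sigma)`` the median is ``exp(mu)`` and the SD is
    ``median * exp(sigma^2/2) * sqrt(exp(sigma^2) - 1)``.  With
    ``w = exp(sigma^2)`` the SD relation is the quadratic
    ``w^2 - w - (sd/median)^2 = 0``, whose positive root gives sigma in
    closed form.

    Parameters
    ----------
    median, sd:
        Reported distribution median (> 0) and standard deviation (>= 0),
        in the same units.

    Returns
    -------
    (mu, sigma):
        Natural-log-scale parameters; ``sigma == 0`` when ``sd == 0``
        (degenerate point mass at the median).
    """
    if median <= 0:
        raise ValueError(
            f"median must be > 0 to fit a lognormal (got {median!r}); "
            "congeners with zero median must be configured as a point mass at 0"
        )
    if sd < 0:
        raise ValueError(f"sd must be >= 0 (got {sd!r})")
    mu = math.log(median)
    if sd == 0:
        return mu, 0.0
    r2 = (sd / median) ** 2
    w = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * r2))
    return mu, math.sqrt(math.log(w))


@dataclass
class CongenerTable:
    """Seasonal outdoor concentration statistics for the 16 congeners.

    Arrays are shaped ``(n_seasons, n_congeners)`` in the canonical
    season/congener order.  A zero median marks a congener absent in that
    season (sampled as a point mass at zero).
    """

    medians: np.ndarray          # (4, 16) ng/m3
    sds: np.ndarray              # (4, 16) ng/m3
    tefs: np.ndarray             # (16,) dimensionless
    particle_fraction: np.ndarray  # (16,) in [0, 1], season-independent
    congeners: tuple[str, ...] = CONGENERS
    seasons: tuple[str, ...] = SEASONS
    _mu: np.ndarray = field(init=False, repr=False)
    _sigma: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.medians = np.asarray(self.medians, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.tefs = np.asarray(self.tefs, dtype=float)
        self.particle_fraction = np.asarray(self.particle_fraction, dtype=float)
        shape = (len(self.seasons), len(self.congeners))
        if self.medians.shape != shape or self.sds.shape != shape:
            raise ValueError(f"median/sd arrays must have shape {shape}")
        if len(self.congeners) != N_CONGENERS:
            raise ValueError(f"expected exactly {N_CONGENERS} congeners")
        if np.any(self.medians < 0) or np.any(self.sds < 0):
            raise ValueError("medians and sds must be non-negative")
        i_bap = self.congeners.index("BaP")
        if self.tefs[i_bap] != 1.0:
            raise ValueError("TEF(BaP) must equal 1")
        if np.any(self.particle_fraction < 0) or np.any(self.particle_fraction > 1):
            raise ValueError("particle fractions must lie in [0, 1]")
        self._refit()

    def _refit(self) -> None:
        mu = np.zeros_like(self.medians)
        sigma = np.zeros_like(self.medians)
        for s in range(self.medians.shape[0]):
            for c in range(self.medians.shape[1]):
                m, sd = self.medians[s, c], self.sds[s, c]
                if m > 0:
                    mu[s, c], sigma[s, c] = lognormal_from_median_sd(m, sd)
        self._mu, self._sigma = mu, sigma

    @property
    def mu(self) -> np.ndarray:
        return self._mu

    @property
    def sigma(self) -> np.ndarray:
        return self._sigma

    def with_medians(self, medians: np.ndarray) -> "CongenerTable":
        """Copy of the table with a replaced median array (refits lognormals)."""
        return CongenerTable(
            medians=np.asarray(medians, dtype=float),
            sds=self.sds.copy(),
            tefs=self.tefs.copy(),
            particle_fraction=self.particle_fraction.copy(),
            congeners=self.congeners,
            seasons=self.seasons,
        )

    def baepeq(self, conc: np.ndarray) -> np.ndarray:
        """TEF-weighted B[a]Peq of a ``(..., n_congeners)`` concentration array."""
        return np.asarray(conc, dtype=float) @ self.tefs


@dataclass
class OutdoorConcField:
    """One sampled outdoor field: seasonal-average concentration per congener.

    ``conc`` holds totals (gas + particle), ng/m3, shaped (4, 16).  The gas /
    particle split is applied downstream with a per-congener particle-bound
    fraction.
    """

    conc: np.ndarray  # (4, 16) ng/m3

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (N_SEASONS, N_CONGENERS):
            raise ValueError(f"field must have shape {(N_SEASONS, N_CONGENERS)}")
        if np.any(self.conc < 0):
            raise ValueError("outdoor concentrations must be non-negative")

    def gas(self, particle_fraction: np.ndarray) -> np.ndarray:
        return self.conc * (1.0 - particle_fraction)

    def particle(self, particle_fraction: np.ndarray) -> np.ndarray:
        return self.conc * particle_fraction

    def baepeq_by_season(self, tefs: np.ndarray) -> np.ndarray:
        return self.conc @ tefs

    def scaled(self, factor: float) -> "OutdoorConcField":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return OutdoorConcField(conc=self.conc * factor)

    def rescaled_to_baepeq(self, target: float, tefs: np.ndarray) -> "OutdoorConcField":
        """Uniform per-season rescale so each season's B[a]Peq equals ``target``.

        The congener profile within each season is preserved; only the overall
        magnitude is moved, the minimal assumption when a guideline is written
        for BaP as an indicator of the whole mixture.
        """
        if target < 0:
            raise ValueError("target B[a]Peq must be non-negative")
        season_baep = self.baepeq_by_season(tefs)
        if np.any(season_baep <= 0):
            raise ValueError("cannot rescale a season with zero B[a]Peq")
        factors = target / season_baep
        return OutdoorConcField(conc=self.conc * factors[:, None])


def sample_outdoor_field(
    table: CongenerTable,
    rng: np.random.Generator,
    correlated: bool = True,
) -> OutdoorConcField:
    """Draw one seasonal-average outdoor field from the fitted lognormals.

    With ``correlated=True`` (default) a single standard-normal quantile per
    season is shared by all congeners, giving perfect rank correlation within
    a season; otherwise every (season, congener) cell is drawn independently.
    Cells with zero median are point masses at zero; cells with zero SD are
    point masses at the median.  Exactly ``n_seasons`` (or
    ``n_seasons * n_congeners``) uniforms are consumed from ``rng``
    regardless of the table's contents, so common-random-number alignment is
    preserved across parameter shifts.
    """
    if correlated:
        u = rng.random(N_SEASONS)[:, None]
    else:
        u = rng.random((N_SEASONS, N_CONGENERS))
    z = ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
    conc = np.where(table.medians > 0, np.exp(table.mu + table.sigma * z), 0.0)
    return OutdoorConcField(conc=conc)


def baep_equivalent(
    conc_by_congener: Mapping[str, float], tefs: Mapping[str, float]
) -> float:
    """B[a]P-equivalent concentration: sum_i TEF_i * C_i.

    Every congener carrying a TEF must be present in ``conc_by_congener``;
    a missing congener raises ``KeyError`` naming it.
    """
    missing = [c for c in tefs if c not in conc_by_congener]
    if missing:
        raise KeyError(f"missing concentration for congener(s): {', '.join(missing)}")
    return float(sum(tefs[c] * conc_by_congener[c] for c in tefs))
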