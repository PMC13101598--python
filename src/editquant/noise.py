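"""Null model for background channel signal and edit p-values.

Background (non-called) channel signal on the percent scale is modelled
as a zero-adjusted gamma: a point mass nu at exactly zero plus a gamma
distribution parameterised by mean mu and dispersion sigma (variance
sigma^2 * mu^2, i.e. shape 1/sigma^2 and scale mu*sigma^2).  The edit
p-value of an observed percent signal x is the one-sided upper tail

    P(X >= x) = 1                       for x == 0
              = (1 - nu) * S_gamma(x)   for x > 0

where S_gamma is the gamma survival function.  Raw p-values are
reported; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import MotifLocation
from .signal import PERCENT_COLS, SignalTable

__all__ = [
    "NoiseModel",
    "InsufficientNoiseError",
    "collect_noise",
    "fit_noise",
    "edit_pvalue",
    "zaga_rvs",
]

MIN_NOISE_OBS = 50


class InsufficientNoiseError(ValueError):
    """Too few background observations to fit the null model."""


@dataclass
class NoiseModel:
    """Fitted zero-adjusted gamma null for background percent signal.

    ``zero_mass`` (nu) is the probability of exactly-zero signal;
    ``mean`` (mu) and ``dispersion`` (sigma) parameterise the gamma
    component.  ``zero_mass == 1`` is the degenerate sentinel fitted
    when every observation was zero: any positive signal is then deemed
    significant.
    """

    zero_mass: float
    mean: float
    dispersion: float
    n_obs: int
    fit_log: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.zero_mass <= 1):
            raise ValueError("zero_mass must be in [0, 1]")
        if self.zero_mass < 1 and not (self.mean > 0 and self.dispersion > 0):
            raise ValueError("gamma mean and dispersion must be positive")

    @property
    def shape(self) -> float:
        return 1.0 / self.dispersion**2

    @property
    def scale(self) -> float:
        return self.mean * self.dispersion**2

    def survival(self, x) -> np.ndarray:
        """P(gamma component >= x)."""
        return stats.gamma.sf(x, a=self.shape, scale=self.scale)

    def summary(self) -> dict[str, float]:
        return {
            "zero_mass": self.zero_mass,
            "mean": self.mean,
            "dispersion": self.dispersion,
            "n_obs": self.n_obs,
        }


def collect_noise(
    signal_table: SignalTable, motif_location: MotifLocation | None
) -> np.ndarray:
    """Background percent signals outside the motif.

    Takes the three non-called channel percents at every quality-passing,
    valid, non-N position inside the kept range and outside the motif
    interval.  These positions are assumed edit-free, so their
    off-channel signal is pure background fluorescence.
    """
    data = signal_table.data
    mask = (
        data["valid"].to_numpy()
        & data["passes_quality"].to_numpy()
        & data["in_kept_range"].to_numpy()
        & (data["called_base"] != "N").to_numpy()
    )
    if motif_location is not None:
        start, end = motif_location.sample_interval
        pos = data["position"].to_numpy()
        mask &= (pos < start) | (pos >= end)
    rows = data.loc[mask]
    if len(rows) < MIN_NOISE_OBS:
        raise InsufficientNoiseError(
            f"only {len(rows)} quality-passing background positions "
            f"(need >= {MIN_NOISE_OBS}); lower the phred stringency or "
            "provide a longer read"
        )
    percents = rows[PERCENT_COLS].to_numpy()
    called = rows["called_base"].to_numpy()
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    keep = np.ones_like(percents, dtype=bool)
    keep[np.arange(len(rows)), [base_index[b] for b in called]] = False
    obs = percents[keep]
    # Exact zeros are integer peak heights of 0; percents inherit that.
    return np.sort(obs)


def fit_noise(observations: np.ndarray) -> NoiseModel:
    """Maximum-likelihood zero-adjusted gamma fit.

    The zero mass is the fraction of exact zeros (its MLE); the gamma
    component is fitted to the nonzero observations by two-parameter
    maximum likelihood (location fixed at zero).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size < MIN_NOISE_OBS:
        raise InsufficientNoiseError(
            f"need >= {MIN_NOISE_OBS} noise observations, got {obs.size}"
        )
    if np.any(obs < 0):
        raise ValueError("noise observations must be non-negative")
    nonzero = np.sort(obs[obs > 0])
    nu = 1.0 - nonzero.size / obs.size
    if nonzero.size == 0:
        return NoiseModel(
            zero_mass=1.0,
            mean=np.nan,
            dispersion=np.nan,
            n_obs=obs.size,
            fit_log="all observations zero: degenerate noise-free model",
        )
    if nonzero.size < 5 or np.ptp(nonzero) == 0:
        # Too few distinct nonzero values for a stable MLE: fall back to
        # moments (dispersion floored at a weakly informative 0.5).
        mu = float(nonzero.mean())
        sd = float(nonzero.std(ddof=1)) if nonzero.size > 1 else 0.0
        sigma = max(sd / mu if mu > 0 else 0.5, 0.5)
        return NoiseModel(
            zero_mass=nu,
            mean=mu,
            dispersion=sigma,
            n_obs=obs.size,
            fit_log=f"moment fallback fit on {nonzero.size} nonzero observations",
        )
    shape, _, scale = stats.gamma.fit(nonzero, floc=0)
    mu = shape * scale
    sigma = 1.0 / np.sqrt(shape)
    return NoiseModel(
        zero_mass=nu,
        mean=float(mu),
        dispersion=float(sigma),
        n_obs=obs.size,
        fit_log=f"gamma MLE on {nonzero.size} nonzero of {obs.size} observations",
    )


def edit_pvalue(observed, model: NoiseModel):
    """One-sided upper-tail probability of the observed percent signal.

    Scalar in, scalar out; array in, array out.  Zero observations get
    p = 1 (the point mass at zero is part of the tail).
    """
    x = np.asarray(observed, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("observed percent signal must be in [0, 1]")
    if model.zero_mass >= 1.0:
        p = np.where(x > 0, 0.0, 1.0)
    else:
        p = np.where(x > 0, (1.0 - model.zero_mass) * model.survival(x), 1.0)
    return float(p) if p.ndim == 0 else p


def zaga_rvs(
    rng: np.random.Generator,
    size: int,
    zero_mass: float,
    mean: float,
    dispersion: float,
) -> np.ndarray:
    """Draws from the zero-adjusted gamma (simulation and testing aid)."""
    shape = 1.0 / dispersion**2
    scale = mean * dispersion**2
    draws = rng.gamma(shape, scale, size=size)
    draws[rng.random(size) < zero_mass] = 0.0
    return draws
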