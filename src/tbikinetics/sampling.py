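"""Mean-preserving input samplers for the Monte Carlo analyses.

Model inputs are positive, so their uncertainty is described by a
lognormal distribution parameterised to preserve the nominal value as the
mean:

    p ~ lognormal(log(p_nom) - sigma^2/2, sigma^2)

so that E[p] = p_nom for any shape parameter ``sigma``.  Normal and
uniform families are available for the blood-volume and sampling-time
scenarios.

Reproducibility contract: every sampler takes a seed (or an explicit
``numpy`` Generator), and matrices of joint draws use one deterministic
substream per named column, so adding a column to a study never perturbs
the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_JOINT_SIGMAS",
    "SINGLE_PARAMETER_SIGMA",
    "InputDistribution",
    "substream",
    "sample",
    "sample_lognormal",
    "draw_matrix",
    "empirical_cdf",
]

#: Lognormal shape parameters of the joint sensitivity/uncertainty study:
#: the released amount D0 varies over a larger range than the volume and
#: rate constants.
DEFAULT_JOINT_SIGMAS: dict[str, float] = {"D0": 0.3, "Vd": 0.1, "ka": 0.1, "ke": 0.1}

#: Shape parameter for single-rate-constant uncertainty bands.
SINGLE_PARAMETER_SIGMA = 0.2


@dataclass(frozen=True)
class InputDistribution:
    """Distribution of one model input.

    ``sigma`` is the lognormal shape parameter (unitless) for the
    lognormal family; for ``normal`` it is the standard deviation and for
    ``uniform`` the half-width, both in the input's own units.
    """

    nominal: float
    sigma: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and not (self.nominal > 0):
            raise ValueError("lognormal nominal must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label random substream of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample(dist: InputDistribution, n: int, seed_or_rng=None) -> np.ndarray:
    """Draw ``n`` values from an input distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed_or_rng)
    if dist.sigma == 0:
        return np.full(n, dist.nominal)
    if dist.family == "lognormal":
        mu = np.log(dist.nominal) - dist.sigma**2 / 2.0
        return rng.lognormal(mean=mu, sigma=dist.sigma, size=n)
    if dist.family == "normal":
        return rng.normal(loc=dist.nominal, scale=dist.sigma, size=n)
    return rng.uniform(dist.nominal - dist.sigma, dist.nominal + dist.sigma, size=n)


def sample_lognormal(dist: InputDistribution, n: int, seed_or_rng=None) -> np.ndarray:
    """Mean-preserving lognormal draws: E[sample] = nominal."""
    if dist.family != "lognormal":
        raise ValueError("sample_lognormal requires a lognormal distribution")
    return sample(dist, n, seed_or_rng)


def draw_matrix(
    dists: Mapping[str, InputDistribution], n: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Joint sample matrix: ``n`` rows, one named column per input.

    Each column is drawn from its own seed substream keyed by the column
    name, so the draws of one input are invariant to which other inputs
    are in the study.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    data = {
        name: sample(dist, n, substream(seed, name)) for name, dist in dists.items()
    }
    return pd.DataFrame(data, columns=list(dists))


def empirical_cdf(samples) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values with cumulative probabilities i/n."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empirical_cdf requires a nonempty sample")
    xs = np.sort(x)
    probs = np.arange(1, xs.size + 1, dtype=float) / xs.size
    return xs, probs
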