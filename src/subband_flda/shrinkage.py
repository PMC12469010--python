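"""Wavelet-shrinkage denoising of undecimated detail coefficients.

Two classical shrinkage rules are provided. Hard thresholding is the
keep-or-kill rule: a coefficient strictly larger than the threshold in
magnitude is kept unchanged, anything else is set to zero (the boundary
``|x| = lambda`` is killed). Soft thresholding shrinks magnitudes toward zero
by the threshold, ``sign(x) * max(|x| - lambda, 0)``, giving a continuous
map and smoother reconstructions; it is the pipeline default.

Thresholds are level-dependent. The source procedure requires an "optimal"
threshold without naming one, so the standard, deterministic choice is used:
the universal threshold ``lambda = sigma * sqrt(2 ln N)`` with the noise
scale ``sigma`` estimated robustly from detail coefficients by the median
absolute deviation, ``sigma = MAD / 0.6745``. By default sigma comes from the
level-1 details once per channel (MAD_LEVEL1); MAD_PER_LEVEL and FIXED are
available as configuration. The approximation band is never thresholded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping

import numpy as np

from .errors import ArgumentError, ShapeError
from .swt import SWTDecomposition

#: Ratio between the MAD and the standard deviation of a Gaussian.
MAD_TO_SIGMA = 0.6745

Rule = Literal["hard", "soft"]
SigmaEstimator = Literal["mad_level1", "mad_per_level", "fixed"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Shrinkage rule plus how the level-dependent thresholds are obtained.

    ``lambdas`` may pin explicit per-level thresholds; levels it does not
    cover fall back to the universal threshold under ``sigma_estimator``.
    """

    rule: Rule = "soft"
    lambdas: Mapping[int, float] | None = None
    sigma_estimator: SigmaEstimator = "mad_level1"
    fixed_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("hard", "soft"):
            raise ArgumentError(f"rule must be 'hard' or 'soft', got {self.rule!r}")
        if self.sigma_estimator not in ("mad_level1", "mad_per_level", "fixed"):
            raise ArgumentError(f"unknown sigma_estimator {self.sigma_estimator!r}")
        if self.lambdas:
            for j, lam in self.lambdas.items():
                if lam < 0:
                    raise ArgumentError(f"lambda_{j} must be >= 0, got {lam}")
        if self.sigma_estimator == "fixed":
            if self.fixed_sigma is None or self.fixed_sigma < 0:
                raise ArgumentError("fixed sigma estimator needs fixed_sigma >= 0")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "lambdas": dict(self.lambdas) if self.lambdas else None,
            "sigma_estimator": self.sigma_estimator,
            "fixed_sigma": self.fixed_sigma,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdSpec":
        lambdas = d.get("lambdas")
        if lambdas is not None:
            lambdas = {int(k): float(v) for k, v in lambdas.items()}
        return cls(
            rule=d.get("rule", "soft"),
            lambdas=lambdas,
            sigma_estimator=d.get("sigma_estimator", "mad_level1"),
            fixed_sigma=d.get("fixed_sigma"),
        )


def hard_threshold(x, lam: float):
    """Keep-or-kill: ``x`` where ``|x| > lam``, else 0 (boundary killed)."""
    if lam < 0:
        raise ArgumentError(f"threshold must be >= 0, got {lam}")
    x = np.asarray(x, dtype=np.float64)
    out = np.where(np.abs(x) > lam, x, 0.0)
    return out if out.ndim else float(out)


def soft_threshold(x, lam: float):
    """Shrink toward zero: ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ArgumentError(f"threshold must be >= 0, got {lam}")
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
    return out if out.ndim else float(out)


def estimate_sigma(d1) -> float:
    """Robust noise scale from detail coefficients: ``MAD / 0.6745``."""
    d1 = np.asarray(d1, dtype=np.float64).ravel()
    if d1.size < 2:
        raise ArgumentError(f"need at least 2 coefficients, got {d1.size}")
    return float(np.median(np.abs(d1 - np.median(d1))) / MAD_TO_SIGMA)


def universal_threshold(sigma: float, n: int) -> float:
    """Universal shrinkage threshold ``sigma * sqrt(2 ln n)``."""
    if sigma < 0:
        raise ArgumentError(f"sigma must be >= 0, got {sigma}")
    if n < 2:
        raise ArgumentError(f"need n >= 2 coefficients, got {n}")
    return sigma * math.sqrt(2.0 * math.log(n))


_RULES = {"hard": hard_threshold, "soft": soft_threshold}


def denoise(dec: SWTDecomposition, spec: ThresholdSpec | None = None) -> SWTDecomposition:
    """Threshold every detail level of a decomposition; approximation untouched.

    Thresholding is applied per channel independently (channels differ in
    scale). Explicit ``spec.lambdas`` entries apply to all channels of that
    level; other levels get the universal threshold with sigma estimated per
    channel according to ``spec.sigma_estimator`` and ``N`` = the per-channel
    coefficient count.
    """
    if spec is None:
        spec = ThresholdSpec()
    if spec.lambdas:
        extra = set(spec.lambdas) - set(range(1, dec.levels + 1))
        if extra:
            raise ShapeError(f"lambdas name levels {sorted(extra)} outside 1..{dec.levels}")
    thresh = _RULES[spec.rule]
    n = dec.padded_length
    n_channels = dec.approximation.shape[1]

    if spec.sigma_estimator == "mad_level1":
        sigma_l1 = np.array([estimate_sigma(dec.details[0][:, c]) for c in range(n_channels)])

    new_details = []
    for j in range(1, dec.levels + 1):
        d = dec.details[j - 1]
        if spec.lambdas and j in spec.lambdas:
            new_details.append(thresh(d, spec.lambdas[j]))
            continue
        out = np.empty_like(d)
        for c in range(n_channels):
            if spec.sigma_estimator == "fixed":
                sigma = float(spec.fixed_sigma)
            elif spec.sigma_estimator == "mad_per_level":
                sigma = estimate_sigma(d[:, c])
            else:
                sigma = float(sigma_l1[c])
            out[:, c] = thresh(d[:, c], universal_threshold(sigma, n))
        new_details.append(out)
    return replace(dec, details=new_details, approximation=dec.approximation.copy())
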