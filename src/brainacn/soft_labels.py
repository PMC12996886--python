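"""Distributional (soft) age labels.

A scalar age is converted to a 90-bin probability vector over integer ages
5..94 by integrating a normal density centred at the age over unit-width bins
(CDF differences), then renormalising over the truncated support.  The decode
direction is the expectation of the distribution.  Soft labels are what the
age head of the network is trained against (via a KL term) and what it emits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

AGE_MIN = 5
AGE_MAX = 94
N_BINS = AGE_MAX - AGE_MIN + 1  # 90
BIN_CENTERS = np.arange(AGE_MIN, AGE_MAX + 1, dtype=np.float64)


@dataclass(frozen=True)
class SoftLabel:
    """A probability distribution over integer ages 5..94.

    probs must be length 90, nonnegative, and sum to 1 within 1e-9.
    """

    probs: np.ndarray
    bin_centers: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_BINS,):
            raise ValueError(f"soft label must have exactly {N_BINS} bins, got shape {p.shape}")
        if np.any(p < 0):
            raise ValueError("soft label probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"soft label probabilities must sum to 1 within 1e-9 (sum={p.sum():.12f})")


def age_to_soft_label(age: float, sigma: float = 2.0) -> SoftLabel:
    """Convert a scalar age to its soft label.

    Bin j (center c_j) receives mass F(c_j + 0.5) - F(c_j - 0.5) where F is
    the normal CDF with mean `age` and standard deviation `sigma`; the vector
    is then renormalised over the truncated support [4.5, 94.5].  Ages outside
    [5, 94] are clamped to the nearest bound with a warning.
    """
    if not np.isfinite(age):
        raise ValueError(f"age must be finite, got {age}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if age < AGE_MIN or age > AGE_MAX:
        clamped = min(max(age, AGE_MIN), AGE_MAX)
        warnings.warn(
            f"age {age} outside soft-label support [{AGE_MIN}, {AGE_MAX}]; clamped to {clamped}",
            stacklevel=2,
        )
        age = clamped
    edges = np.arange(AGE_MIN - 0.5, AGE_MAX + 1.5)  # 91 edges 4.5 .. 94.5
    cdf = norm.cdf(edges, loc=age, scale=sigma)
    probs = np.diff(cdf)
    total = probs.sum()
    if total <= 0:  # sigma so small that all mass collapsed numerically
        probs = np.zeros(N_BINS)
        probs[int(np.clip(round(age), AGE_MIN, AGE_MAX)) - AGE_MIN] = 1.0
    else:
        probs = probs / total
    return SoftLabel(probs=probs)


def ages_to_soft_labels(ages: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Vectorised soft labels: (n,) ages -> (n, 90) probability matrix."""
    ages = np.asarray(ages, dtype=np.float64)
    out = np.empty((ages.size, N_BINS))
    for i, a in enumerate(ages.ravel()):
        out[i] = age_to_soft_label(float(a), sigma).probs
    return out


def soft_label_to_age(label: SoftLabel | np.ndarray) -> float:
    """Expectation decode: sum_j probs[j] * c_j."""
    probs = label.probs if isinstance(label, SoftLabel) else np.asarray(label, dtype=np.float64)
    if probs.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} probabilities, got shape {probs.shape}")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities not normalised (sum={probs.sum():.8f})")
    return float(probs @ BIN_CENTERS)


def soft_labels_to_ages(probs: np.ndarray) -> np.ndarray:
    """Vectorised expectation decode of an (n, 90) probability matrix."""
    probs = np.asarray(probs, dtype=np.float64)
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probabilities not normalised")
    return probs @ BIN_CENTERS
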