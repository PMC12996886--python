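"""Synthetic phantom-MRI cohorts.

Each phantom is a bright brain-like ellipsoid with a central dark ventricle.
Ageing is encoded geometrically — the ventricle radius grows linearly with
age (ventricular enlargement / atrophy) — while the two confounds are encoded
separably: data site as a multiplicative intensity factor and gender as a
global structure-scale offset.  i.i.d. Gaussian voxel noise is added last.
Because the age signal is geometric and the site signal is intensity-only,
adversarial removal of site information can in principle preserve the age
signal; the generator exists to make that separation testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .io import SubjectRecord, Volume

GENDER_LABELS = ("F", "M")


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level knobs for the phantom generator.

    site_bias_strength is the per-site multiplicative intensity step (site s
    scales intensities by 1 + s * site_bias_strength); gender_effect is the
    relative structure-scale gap between genders; atrophy_rate is ventricle
    radius growth in voxels per year.
    """

    n_subjects: int = 600
    grid_shape: Tuple[int, int, int] = (32, 40, 32)
    age_range: Tuple[float, float] = (5.0, 94.0)
    n_sites: int = 2
    site_bias_strength: float = 0.1
    gender_effect: float = 0.05
    atrophy_rate: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0
    confound_age_site: bool = False
    ventricle_base_radius: float = 1.5
    brain_fill: float = 1.0
    ventricle_fill: float = 0.15

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 dims all >= 8, got {self.grid_shape}")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError(f"age_range must satisfy 0 <= min < max <= 120, got {self.age_range}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.site_bias_strength < 0 or self.gender_effect < 0:
            raise ValueError("site_bias_strength and gender_effect must be >= 0")

    def site_labels(self) -> List[str]:
        return [f"site{s}" for s in range(self.n_sites)]


def _ellipsoid_mask(shape: Tuple[int, int, int], center: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def generate_subject(
    config: PhantomConfig,
    age: float,
    gender: str,
    site: str,
    rng: np.random.Generator,
) -> Volume:
    """Render one phantom volume for the given age/gender/site."""
    lo, hi = config.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside configured age_range [{lo}, {hi}]")
    if gender not in GENDER_LABELS:
        raise ValueError(f"gender must be one of {GENDER_LABELS}, got {gender!r}")
    sites = config.site_labels()
    if site not in sites:
        raise ValueError(f"site must be one of {sites}, got {site!r}")

    shape = config.grid_shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    gender_scale = 1.0 + config.gender_effect * (GENDER_LABELS.index(gender) - 0.5)
    brain_axes = 0.40 * np.asarray(shape, dtype=float) * gender_scale
    vent_radius = config.ventricle_base_radius + config.atrophy_rate * age

    vox = np.zeros(shape, dtype=np.float64)
    brain = _ellipsoid_mask(shape, center, brain_axes)
    vox[brain] = config.brain_fill
    vent = _ellipsoid_mask(shape, center, np.full(3, vent_radius)) & brain
    vox[vent] = config.ventricle_fill

    site_factor = 1.0 + config.site_bias_strength * sites.index(site)
    vox *= site_factor
    if config.noise_sd > 0:
        vox = vox + rng.normal(0.0, config.noise_sd, size=shape)
    return Volume(voxels=vox, spacing=(1.5, 1.5, 1.5))


def generate_cohort(config: PhantomConfig) -> Tuple[List[Volume], List[SubjectRecord]]:
    """Simulate a full cohort.

    Ages are uniform over age_range (per-site contiguous age windows when
    confound_age_site is set); genders and sites are assigned round-robin so
    the cohort is balanced.  Fully deterministic given config.seed.
    """
    if config.n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {config.n_subjects}")
    rng = np.random.default_rng(config.seed)
    sites = config.site_labels()
    lo, hi = config.age_range

    volumes: List[Volume] = []
    records: List[SubjectRecord] = []
    for i in range(config.n_subjects):
        gender = GENDER_LABELS[i % 2]
        site = sites[i % config.n_sites]
        if config.confound_age_site:
            w = (hi - lo) / config.n_sites
            s = sites.index(site)
            age = float(rng.uniform(lo + s * w, lo + (s + 1) * w))
        else:
            age = float(rng.uniform(lo, hi))
        vol = generate_subject(config, age, gender, site, rng)
        sid = f"sub-{i:04d}"
        vol.subject_id = sid
        volumes.append(vol)
        records.append(SubjectRecord(subject_id=sid, age=age, gender=gender, site=site))
    return volumes, records
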