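"""Seed-reproducible synthetic herbarium collections.

The generator emulates the statistical structure the analysis chain
assumes, so the whole pipeline (PI scoring, detector evaluation,
phenoclimatic models) runs end-to-end without any external data.  Per
specimen:

1. a collection site (latitude, longitude, elevation) and year are drawn
   uniformly over a montane-California-like range;
2. site climate follows the elevation: spring Tmax declines with a lapse
   rate plus noise, winter PPT is log-normal;
3. a latent reproductive stage u ~ Uniform(0, 3) sets the true
   phenological progression (PI_true = 1 + u);
4. organ composition comes from a Gaussian kernel over the four class
   index values centred on PI_true, weighted by per-class abundance and
   normalised so that each class's expected count across the collection
   equals its configured mean; the total per sheet is negative-binomial
   and manual counts are a multinomial split of it;
5. collection DOY is linear in year, climate and the stage's expected
   composition PI, plus Gaussian residual noise — so regressing DOY on the
   scored PI recovers the configured days-per-PI-unit rate by
   construction;
6. detector-predicted counts are a binomial thinning of the manual counts
   with class-specific detection probabilities (an undercounting detector),
   optionally degraded with specimen age.

Everything is driven by a single seeded generator with a fixed draw order,
so a given (config, seed) pair always yields the identical collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .phenology import ORGAN_CLASSES, OrganCounts, SpecimenRecord

__all__ = ["SimulationConfig", "simulate_collection", "fixture_small",
           "coco_training_fixture", "expected_composition_pi"]

_KERNEL_GRID = np.linspace(0.0, 3.0, 601)  # quadrature grid for stage kernel normalisers


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameterisation of a synthetic collection.

    Defaults describe a collection resembling a century-long sample of a
    montane annual herb: class mean abundances of roughly 27/29/11/13
    organs per sheet, a detector that finds 16-30% of the organs a human
    counts depending on class, flowering ~5 days earlier per degC of
    spring warming, and a progression rate of 17 days per PI unit.
    """

    n_specimens: int = 700
    seed: int = 0

    # collection window and site model
    year_range: tuple[int, int] = (1900, 2013)
    latitude_range: tuple[float, float] = (35.5, 41.5)
    longitude_range: tuple[float, float] = (-123.0, -118.0)
    elevation_range: tuple[float, float] = (200.0, 3200.0)

    # climate model: tmax = intercept + lapse * elevation + N(0, sd); ppt log-normal (mm)
    tmax_intercept: float = 20.0
    tmax_lapse: float = -0.005      # degC per m
    tmax_sd: float = 2.0
    ppt_log_mean: float = 6.2
    ppt_log_sd: float = 0.55

    # collection-date model (days)
    alpha: float = 215.0            # baseline DOY at year 1950, 0 degC, 0 mm, PI = 1
    beta_year: float = -0.10        # days per year
    beta_tmax: float = -5.3         # days per degC
    beta_ppt: float = 0.0072        # days per mm
    progression_days: float = 17.0  # days per PI unit
    residual_sd: float = 15.0

    # organ totals and composition
    class_means: tuple[float, float, float, float] = (27.4, 28.5, 11.0, 12.5)
    total_dispersion: float = 5.0   # negative-binomial size; larger = closer to Poisson
    tau: float = 0.6                # stage-kernel width over class index values

    # detector model
    detection_probs: tuple[float, float, float, float] = (0.16, 0.22, 0.30, 0.28)
    age_error_rate: float = 0.0     # fractional detection change per year relative to 2000

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not all(0 < p <= 1 for p in self.detection_probs):
            raise ValueError("detection probabilities must lie in (0, 1]")
        if any(m <= 0 for m in self.class_means):
            raise ValueError("class means must be positive")
        if self.total_dispersion <= 0:
            raise ValueError("total_dispersion must be > 0")
        if self.year_range[0] >= self.year_range[1]:
            raise ValueError("year_range must be increasing")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def _stage_kernel(u: np.ndarray, tau: float) -> np.ndarray:
    """Unnormalised class affinity exp(-(k - PI_true)^2 / (2 tau^2)), shape (n, 4)."""
    k = np.arange(1, 5)
    return np.exp(-((k[None, :] - (1.0 + np.asarray(u)[:, None])) ** 2) / (2.0 * tau**2))


def _class_rates(u: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Per-class expected counts s_k(u), normalised so E_u[s_k] = class mean.

    Dividing each kernel column by its average over the uniform stage
    distribution makes the collection-wide expectation of every class's
    count equal the configured mean, whatever tau is.
    """
    phi = _stage_kernel(u, cfg.tau)
    norm = np.trapezoid(_stage_kernel(_KERNEL_GRID, cfg.tau), _KERNEL_GRID, axis=0) / 3.0
    return np.asarray(cfg.class_means) * phi / norm


def expected_composition_pi(u: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Expected PI of the organ composition at latent stage u.

    This is the composition-weighted mean class index Σ k w_k(u); it is the
    quantity a scored PI estimates, and the DOY model is linear in it.  It
    compresses slightly near the endpoints (a sheet at stage 0 still bears
    a few flowers), which is why scored PIs span ~1.1-3.9 rather than the
    full [1, 4].
    """
    s = _class_rates(np.atleast_1d(u), cfg)
    w = s / s.sum(axis=1, keepdims=True)
    return w @ np.arange(1, 5)


def simulate_collection(config: SimulationConfig | None = None, **overrides) -> list[SpecimenRecord]:
    """Generate a synthetic scored collection.

    Keyword overrides patch individual config fields, e.g.
    ``simulate_collection(n_specimens=100, seed=3)``.  Deterministic for a
    fixed config: the random stream is seeded once and consumed in a fixed
    order (sites -> years -> climate -> stage -> DOY -> totals -> manual
    counts -> thinning).
    """
    cfg = replace(config or SimulationConfig(), **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_specimens

    lat = rng.uniform(*cfg.latitude_range, n)
    lon = rng.uniform(*cfg.longitude_range, n)
    elev = rng.uniform(*cfg.elevation_range, n)
    year = rng.integers(cfg.year_range[0], cfg.year_range[1] + 1, n)
    tmax = cfg.tmax_intercept + cfg.tmax_lapse * elev + rng.normal(0.0, cfg.tmax_sd, n)
    ppt = rng.lognormal(cfg.ppt_log_mean, cfg.ppt_log_sd, n)

    u = rng.uniform(0.0, 3.0, n)
    pi_comp = expected_composition_pi(u, cfg)

    doy_mean = (
        cfg.alpha
        + cfg.beta_year * (year - 1950)
        + cfg.beta_tmax * tmax
        + cfg.beta_ppt * ppt
        + cfg.progression_days * (pi_comp - 1.0)
    )
    doy = np.clip(np.rint(doy_mean + rng.normal(0.0, cfg.residual_sd, n)), 1, 366).astype(int)

    s = _class_rates(u, cfg)                      # (n, 4) expected class counts
    mu = s.sum(axis=1)
    w = s / mu[:, None]
    size = cfg.total_dispersion
    total = rng.negative_binomial(size, size / (size + mu))
    total = np.maximum(total, 1)                  # collections contain only fertile sheets
    manual = np.vstack([rng.multinomial(t, wi) for t, wi in zip(total, w)])

    p_eff = np.clip(
        np.asarray(cfg.detection_probs)[None, :]
        * (1.0 + cfg.age_error_rate * (year[:, None] - 2000)),
        0.0, 1.0,
    )
    predicted = rng.binomial(manual, p_eff)

    records = []
    for i in range(n):
        records.append(
            SpecimenRecord(
                id=f"SIM{i:05d}",
                year=int(year[i]),
                doy=int(doy[i]),
                latitude=float(lat[i]),
                longitude=float(lon[i]),
                elevation=float(elev[i]),
                spring_tmax=float(tmax[i]),
                winter_ppt=float(ppt[i]),
                manual_counts=OrganCounts(*(int(c) for c in manual[i])),
                predicted_counts=OrganCounts(*(int(c) for c in predicted[i])),
            )
        )
    return records


def fixture_small(n: int = 25, seed: int = 20210709) -> list[SpecimenRecord]:
    """Tiny deterministic collection for unit tests and documentation.

    Every sheet bears at least one organ, so all PIs are defined.
    """
    return simulate_collection(SimulationConfig(n_specimens=n, seed=seed))


def coco_training_fixture(
    class_totals: Sequence[int] = (279, 349, 196, 212),
    n_images: int = 21,
) -> dict:
    """Synthetic COCO-style instance-annotation payload.

    Builds a deposit-shaped stand-in for a training annotation set: 21
    images carrying 279 bud, 349 flower, 196 immature-fruit and 212
    mature-fruit instances (1036 total) by default.  Annotations are dealt
    round-robin across images with placeholder geometry; only the
    image/category/instance bookkeeping is meaningful.
    """
    categories = [
        {"id": k + 1, "name": name} for k, name in enumerate(
            ("flower bud", "flower", "immature fruit", "mature fruit"))
    ]
    images = [
        {"id": i + 1, "file_name": f"synthetic_sheet_{i + 1:02d}.jpg",
         "width": 2000, "height": 3000}
        for i in range(n_images)
    ]
    annotations = []
    ann_id = 1
    for cat_id, total in enumerate(class_totals, start=1):
        for j in range(total):
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": (ann_id - 1) % n_images + 1,
                    "category_id": cat_id,
                    "bbox": [10.0 * j % 1900, 10.0 * j % 2900, 40.0, 60.0],
                    "area": 2400.0,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return {"images": images, "annotations": annotations, "categories": categories}
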