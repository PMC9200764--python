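"""Synthetic H&E-like slides and censored survival cohorts with known truth.

Each synthetic patient gets a slide whose local "nuclear" density is the
single informative image feature.  The slide-level mean density (over
tissue) is standardized across the cohort into a score z, and event times
are drawn from a proportional-hazards model

    T ~ Exponential(rate = h0 * exp(beta_true * z)),

with independent uniform censoring calibrated to a target censored
fraction.  Per-pixel ground-truth informativeness maps (local nuclear
density on a fixed absolute scale) make risk heatmaps checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.draw import ellipse

from .cohort_io import Cohort, PatientRecord, write_cohort

__all__ = ["SynthParams", "SynthSlide", "generate_slide", "generate_cohort", "write_bundle"]

# fixed absolute reference for scaling local nuclear coverage into [0, 1];
# chosen so the densest default slides approach but do not saturate 1
INFORMATIVENESS_REF = 0.25

# mean H&E-like colors (RGB in [0,1])
_STROMA = np.array([0.84, 0.55, 0.72])
_NUCLEUS = np.array([0.30, 0.13, 0.44])


@dataclass
class SynthParams:
    """Study conditions for a synthetic cohort.

    ``nuclei_density_range`` is in nuclei per pixel^2 at the working
    magnification; ``h0`` in events/month; ``beta_true`` is the log-hazard
    per standard deviation of the slide-mean density feature.
    """

    n_patients: int = 40
    slide_size: int = 256
    h0: float = 0.02
    beta_true: float = 1.5
    censor_rate: float = 0.3
    nuclei_density_range: tuple[float, float] = (5e-4, 3e-3)
    seed: int = 0
    heterogeneity: float = 0.6  # amplitude of within-slide density variation
    weibull_shape: float = 1.0  # 1.0 = exponential event times

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        lo, hi = self.nuclei_density_range
        if not lo < hi:
            raise ValueError("nuclei_density_range must be (low, high) with low < high")


@dataclass
class SynthSlide:
    """A generated slide plus its ground truth."""

    image: np.ndarray            # H x W x 3 RGB in [0, 1]
    informativeness: np.ndarray  # H x W in [0, 1], local nuclear density
    patient_feature: float       # mean informativeness over tissue
    tissue_fraction: float
    tissue: np.ndarray = field(repr=False, default=None)  # ground-truth tissue mask
    n_nuclei: int = 0


def _smooth_field(shape, rng, sigma):
    """Zero-mean, unit-ish amplitude smooth random field."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma)
    s = f.std()
    return f / s if s > 0 else f


def generate_slide(density: float, slide_size: int = 256, seed: int = 0,
                   heterogeneity: float = 0.6) -> SynthSlide:
    """Generate one H&E-like slide with the given mean nuclear density.

    A pink stroma blob on a white glass margin, with dark-purple
    elliptical nuclei placed by an inhomogeneous point process whose local
    intensity varies smoothly around ``density``.  Bit-deterministic given
    the seed.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    n = slide_size
    yy, xx = np.mgrid[0:n, 0:n]

    # tissue blob: a wobbled ellipse leaving a glass margin
    cy, cx = n / 2 + rng.uniform(-0.04, 0.04) * n, n / 2 + rng.uniform(-0.04, 0.04) * n
    ry, rx = 0.42 * n * rng.uniform(0.9, 1.05), 0.42 * n * rng.uniform(0.9, 1.05)
    wobble = 1.0 + 0.15 * _smooth_field((n, n), rng, sigma=n / 8)
    tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= wobble

    # glass background with faint scanner noise
    img = np.empty((n, n, 3))
    img[:] = 0.97
    img += rng.normal(0, 0.004, size=(n, n, 1))

    # stroma texture inside tissue
    texture = 0.05 * _smooth_field((n, n), rng, sigma=6)
    for c in range(3):
        img[..., c] = np.where(tissue, _STROMA[c] + texture, img[..., c])

    # inhomogeneous nucleus point process
    intensity = np.clip(1.0 + heterogeneity * _smooth_field((n, n), rng, sigma=n / 6), 0.05, None)
    intensity = intensity * tissue
    total = intensity.sum()
    n_nuclei = int(rng.poisson(density * tissue.sum())) if density > 0 else 0
    nuc_map = np.zeros((n, n))
    if n_nuclei > 0 and total > 0:
        p = (intensity / total).ravel()
        centers = rng.choice(n * n, size=n_nuclei, replace=True, p=p)
        for idx in centers:
            y0, x0 = divmod(int(idx), n)
            r0 = rng.uniform(2.5, 4.5)
            r1 = rng.uniform(2.5, 4.5)
            rot = rng.uniform(0, np.pi)
            rr, cc = ellipse(y0, x0, r0, r1, shape=(n, n), rotation=rot)
            shade = np.clip(_NUCLEUS + rng.normal(0, 0.03, size=3), 0, 1)
            img[rr, cc] = shade
            nuc_map[rr, cc] = 1.0

    # ground truth: local nuclear coverage on a fixed absolute scale
    local = ndimage.gaussian_filter(nuc_map, sigma=slide_size / 16)
    informativeness = np.clip(local / INFORMATIVENESS_REF, 0.0, 1.0)
    tissue_fraction = float(tissue.mean())
    feature = float(informativeness[tissue].mean()) if tissue.any() else 0.0

    return SynthSlide(
        image=np.clip(img, 0, 1),
        informativeness=informativeness,
        patient_feature=feature,
        tissue_fraction=tissue_fraction,
        tissue=tissue,
        n_nuclei=n_nuclei,
    )


def _censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Upper bound q of Uniform(0, q) censoring hitting the target fraction.

    With T ~ Exp(rate) and C ~ U(0, q), P(censored) = mean over patients of
    (1 - exp(-rate*q)) / (rate*q); solve for q by bisection.
    """

    def frac(q):
        x = rates * q
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac(hi) > censor_rate and hi < 1e12:
        hi *= 10.0
    return optimize.brentq(lambda q: frac(q) - censor_rate, lo, hi)


def generate_cohort(params: SynthParams):
    """Generate slides, a censored cohort, and the ground-truth table.

    Returns ``(slides, cohort, truth)`` where ``slides`` maps slide id to
    :class:`SynthSlide`, ``cohort`` is a :class:`~wsisurv.cohort_io.Cohort`
    whose slide ids reference ``slides``, and ``truth`` is a DataFrame with
    per-patient density ``d``, standardized feature ``z``, and latent event
    time ``T``.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.nuclei_density_range
    densities = rng.uniform(lo, hi, size=params.n_patients)
    slide_seeds = rng.integers(0, 2**31 - 1, size=params.n_patients)

    slides = {}
    features = np.empty(params.n_patients)
    for i in range(params.n_patients):
        slide = generate_slide(densities[i], params.slide_size,
                               seed=int(slide_seeds[i]),
                               heterogeneity=params.heterogeneity)
        slides[f"S{i:04d}"] = slide
        features[i] = slide.patient_feature

    sd = features.std()
    z = (features - features.mean()) / (sd if sd > 0 else 1.0)
    rates = params.h0 * np.exp(params.beta_true * z)

    u = rng.uniform(size=params.n_patients)
    T = -np.log(u) / rates
    if params.weibull_shape != 1.0:
        # inverse-CDF Weibull with the same proportional-hazards structure
        T = (-np.log(u) / rates) ** (1.0 / params.weibull_shape)

    if params.censor_rate > 0:
        q = _censor_horizon(rates, params.censor_rate)
        C = rng.uniform(0, q, size=params.n_patients)
    else:
        C = np.full(params.n_patients, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)

    patients = [
        PatientRecord(
            patient_id=f"P{i:04d}",
            slide_ids=[f"S{i:04d}"],
            time_months=float(time[i]),
            event=int(event[i]),
        )
        for i in range(params.n_patients)
    ]
    cohort = Cohort(patients=patients, name="synthetic")
    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "slide_id": [p.slide_ids[0] for p in patients],
            "d": densities,
            "z": z,
            "T": T,
            "time_months": time,
            "event": event,
        }
    )
    return slides, cohort, truth


def write_bundle(slides, cohort: Cohort, truth: pd.DataFrame, out_dir) -> None:
    """Write slides as PNG, the cohort as CSV, and the truth table as CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    id_to_path = {}
    for sid, slide in slides.items():
        path = out / f"{sid}.png"
        iio.imwrite(path, (slide.image * 255).astype(np.uint8))
        id_to_path[sid] = str(path)
    on_disk = Cohort(
        patients=[
            PatientRecord(
                patient_id=p.patient_id,
                slide_ids=[id_to_path[s] for s in p.slide_ids],
                time_months=p.time_months,
                event=p.event,
                covariates=p.covariates,
            )
            for p in cohort.patients
        ],
        name=cohort.name,
    )
    write_cohort(on_disk, out / "cohort.csv")
    truth.to_csv(out / "truth.csv", index=False)
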