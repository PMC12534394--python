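"""Synthetic dental-like phantoms and multi-modal patient cohorts.

The phantom generator emulates the appearance cues the image operators
target: a bright, noisy enamel-like background, dark circular carious
lesions with smooth (plateau + Gaussian) edges, and inflammation disks
that raise an auxiliary clinical channel rather than the grayscale
image.  Ground-truth masks are exact disk indicators.

The cohort generator draws patients whose four modality scores
(clinical, radiographic, genetic, behavioral) are noisy monotone
functions of a latent disease severity; the radiographic modality also
carries a phantom image whose lesion severity equals the latent
severity.  Labels follow four strata: healthy below a severity
threshold, then incipient / moderate / severe by thirds of the
remaining range.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "PatientRecord",
    "PhantomResult",
    "PhantomSpec",
    "make_cohort",
    "make_patient",
    "make_phantom",
    "severity_label",
]

MODALITIES = ("clinical", "radiographic", "genetic", "behavioral")

#: Severity below this threshold counts as healthy; the remaining range
#: splits into thirds for incipient / moderate / severe.
HEALTHY_THRESHOLD = 0.2

LESION_DARKENING = 0.5  # maximal intensity drop at full severity


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of a synthetic dental phantom."""

    height: int = 64
    width: int = 64
    background_mu: float = 0.75
    noise_sigma: float = 0.03
    lesions: tuple = ()  # ((row, col), radius, severity)
    inflammations: tuple = ()  # ((row, col), radius, intensity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not (0.0 <= self.background_mu <= 1.0) or self.noise_sigma < 0:
            raise ValueError("background_mu must be in [0,1] and noise_sigma >= 0")
        for (center, radius, level) in tuple(self.lesions) + tuple(self.inflammations):
            r, c = center
            if not (0.0 <= level <= 1.0):
                raise ValueError("lesion severity / inflammation intensity must be in [0, 1]")
            if r - radius < 0 or r + radius > self.height - 1 or c - radius < 0 or c + radius > self.width - 1:
                raise ValueError(f"disk at {center} radius {radius} exceeds image bounds")


@dataclass
class PhantomResult:
    """Phantom image with exact ground-truth masks and the clinical channel."""

    image: np.ndarray
    lesion_mask: np.ndarray
    inflammation_mask: np.ndarray
    clinical_map: np.ndarray


def _disk_profile(shape: tuple[int, int], center, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact disk indicator and a smooth plateau-Gaussian edge profile.

    Full response inside 0.7 * radius, Gaussian falloff (sigma = 0.2 *
    radius) beyond — smooth edges without shrinking the lesion core.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    mask = dist <= radius
    core = 0.7 * radius
    sigma = max(0.2 * radius, 1e-9)
    profile = np.where(
        dist <= core, 1.0, np.exp(-((dist - core) ** 2) / (2.0 * sigma**2))
    )
    return mask, profile


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a phantom: noisy background, dark lesions, inflammation channel."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    image = rng.normal(spec.background_mu, spec.noise_sigma, size=shape)
    lesion_mask = np.zeros(shape, dtype=bool)
    inflammation_mask = np.zeros(shape, dtype=bool)
    clinical = np.zeros(shape, dtype=float)
    for center, radius, severity in spec.lesions:
        mask, profile = _disk_profile(shape, center, radius)
        image = image - severity * LESION_DARKENING * profile
        lesion_mask |= mask
    for center, radius, intensity in spec.inflammations:
        mask, profile = _disk_profile(shape, center, radius)
        clinical = clinical + intensity * profile
        inflammation_mask |= mask
    return PhantomResult(
        image=np.clip(image, 0.0, 1.0),
        lesion_mask=lesion_mask,
        inflammation_mask=inflammation_mask,
        clinical_map=np.clip(clinical, 0.0, 1.0),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic patient cohort."""

    n: int = 200
    prevalence: float = 0.5
    severity_noise: float = 0.05
    modality_noise: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    age_range: tuple[float, float] = (3.0, 17.0)
    image_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        if self.severity_noise < 0 or any(m < 0 for m in self.modality_noise):
            raise ValueError("noise levels must be non-negative")


@dataclass
class PatientRecord:
    """One synthetic patient: age, modality scores and ground truth."""

    age: float
    clinical: Optional[float] = None
    radiographic: Optional[float] = None
    genetic: Optional[float] = None
    behavioral: Optional[float] = None
    image: Optional[np.ndarray] = None
    clinical_map: Optional[np.ndarray] = None
    latent_severity: Optional[float] = None
    label: Optional[str] = None

    def modality_scores(self) -> dict[str, float]:
        """Present modality scores keyed by modality name."""
        return {
            m: getattr(self, m)
            for m in MODALITIES
            if getattr(self, m) is not None
        }


def severity_label(severity: float) -> str:
    """Four diagnostic strata from latent severity."""
    if severity < HEALTHY_THRESHOLD:
        return "healthy"
    span = (1.0 - HEALTHY_THRESHOLD) / 3.0
    if severity < HEALTHY_THRESHOLD + span:
        return "incipient"
    if severity < HEALTHY_THRESHOLD + 2 * span:
        return "moderate"
    return "severe"


def make_patient(
    age: float,
    latent_severity: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> PatientRecord:
    """Draw one patient whose modality scores track the latent severity."""
    if not (0.0 <= latent_severity <= 1.0):
        raise ValueError("latent severity must lie in [0, 1]")
    scores = {}
    for modality, noise in zip(MODALITIES, spec.modality_noise):
        scores[modality] = float(
            np.clip(latent_severity + rng.normal(0.0, noise), 0.0, 1.0)
        )
    size = spec.image_size
    lesions = ()
    if latent_severity > 0:
        radius = size // 6
        lo, hi = radius, size - 1 - radius
        center = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        lesions = ((center, radius, latent_severity),)
    phantom = make_phantom(
        PhantomSpec(
            height=size,
            width=size,
            lesions=lesions,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    )
    return PatientRecord(
        age=age,
        image=phantom.image,
        clinical_map=phantom.clinical_map,
        latent_severity=latent_severity,
        label=severity_label(latent_severity),
        **scores,
    )


def make_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw ``spec.n`` patients; diseased fraction targets the prevalence.

    Healthy patients draw latent severity uniformly below the healthy
    threshold; diseased patients uniformly above it.  Severity noise
    jitters the draw within its stratum.  Ages are uniform over the
    age range.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    lo_age, hi_age = spec.age_range
    for _ in range(spec.n):
        diseased = rng.random() < spec.prevalence
        if diseased:
            sev = rng.uniform(HEALTHY_THRESHOLD + 0.05, 1.0)
        else:
            sev = rng.uniform(0.0, HEALTHY_THRESHOLD - 0.05)
        sev = float(np.clip(sev + rng.normal(0.0, spec.severity_noise), 0.0, 1.0))
        # Keep the jittered draw inside its stratum so labels stay exact.
        if diseased:
            sev = max(sev, HEALTHY_THRESHOLD)
        else:
            sev = min(sev, HEALTHY_THRESHOLD - 1e-9)
        age = float(rng.uniform(lo_age, hi_age))
        records.append(make_patient(age, sev, spec, rng))
    return records
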