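"""Neutrosophic membership functions for pediatric dental images.

A neutrosophic set assigns every image element three independent
memberships — truth ``T`` (evidence for pathology), indeterminacy ``I``
(diagnostic ambiguity) and falsehood ``F`` (evidence for healthy
tissue) — each in ``[0, 1]`` with ``T + I + F <= 3``.  Unlike a fuzzy
membership pair, the indeterminacy channel carries examiner
disagreement and developmental ambiguity (mixed dentition, erupting
teeth) explicitly, which is the dominant uncertainty source in
pediatric radiography.

The truth map blends a sigmoid intensity response with clinical and
genetic evidence; the indeterminacy map peaks at a transitional
intensity via a Gaussian kernel and adds examiner / developmental
uncertainty; the falsehood map rewards low truth, healthy-tissue
evidence and the residual ``max(0, 1 - I - T)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "AgeGroup",
    "AuxEvidence",
    "MembershipParams",
    "NeutrosophicMap",
    "NeutrosophicTriple",
    "age_adjusted_params",
    "age_group_of",
    "falsehood_membership",
    "indeterminacy_membership",
    "neutrosophize_image",
    "truth_membership",
]


class AgeGroup(enum.Enum):
    """Pediatric developmental strata by dentition stage."""

    EARLY_CHILDHOOD = "early_childhood"  # 3-6 y, primary dentition
    SCHOOL_AGE = "school_age"  # 7-12 y, mixed dentition
    ADOLESCENCE = "adolescence"  # 13-17 y, permanent dentition


def age_group_of(age: float) -> AgeGroup:
    """Map an age in years (3-17) to its developmental stratum.

    Boundaries are closed above: 6 -> early childhood, 12 -> school age.
    """
    if not np.isfinite(age) or age < 3 or age > 17:
        raise ValueError(f"age must lie in [3, 17] years, got {age!r}")
    if age <= 6:
        return AgeGroup.EARLY_CHILDHOOD
    if age <= 12:
        return AgeGroup.SCHOOL_AGE
    return AgeGroup.ADOLESCENCE


@dataclass(frozen=True)
class MembershipParams:
    """Weights and shape parameters of the three membership functions.

    The three weight triples act on (intensity response, clinical
    evidence, genetic evidence) for truth; (transition kernel, examiner
    uncertainty, developmental uncertainty) for indeterminacy; and
    (1 - T, healthy-tissue evidence, residual) for falsehood.

    ``dark_lesions`` selects the radiographic convention in which
    carious lesions are darker than sound enamel: the sigmoid argument
    is negated so demineralized (dark) pixels raise truth.  With the
    flag off, the sigmoid uses the signed difference
    ``(intensity - mu_healthy) / sigma_pathological`` and bright pixels
    raise truth.
    """

    alpha_t: float = 0.45
    beta_t: float = 0.35
    gamma_t: float = 0.20
    gamma_i: float = 0.40
    delta_i: float = 0.35
    epsilon_i: float = 0.25
    zeta_f: float = 0.50
    eta_f: float = 0.30
    theta_f: float = 0.20
    mu_healthy: float = 0.75
    sigma_pathological: float = 0.15
    mu_transition: float = 0.50
    sigma_developmental: float = 0.12
    dark_lesions: bool = True

    def __post_init__(self) -> None:
        weights = (
            self.alpha_t, self.beta_t, self.gamma_t,
            self.gamma_i, self.delta_i, self.epsilon_i,
            self.zeta_f, self.eta_f, self.theta_f,
        )
        if any(not np.isfinite(w) or w < 0 for w in weights):
            raise ValueError("all membership weights must be finite and non-negative")
        if not (0.0 <= self.mu_healthy <= 1.0 and 0.0 <= self.mu_transition <= 1.0):
            raise ValueError("mu_healthy and mu_transition must lie in [0, 1]")
        if self.sigma_pathological <= 0 or self.sigma_developmental <= 0:
            raise ValueError("sigma parameters must be strictly positive")


# Table-derived age modifiers: each stratum touches exactly one truth weight.
_AGE_MODIFIERS = {
    AgeGroup.EARLY_CHILDHOOD: ("alpha_t", 1.15),
    AgeGroup.SCHOOL_AGE: ("beta_t", 1.10),
    AgeGroup.ADOLESCENCE: ("gamma_t", 0.88),
}


def age_adjusted_params(base: MembershipParams, group: AgeGroup) -> MembershipParams:
    """Return a copy of ``base`` with the stratum's weight modifier applied.

    Early childhood raises ``alpha_t`` by 15% (higher diagnostic
    confidence needed for primary dentition), school age raises
    ``beta_t`` by 10% (mixed-dentition ambiguity), adolescence lowers
    ``gamma_t`` by 12% (mature tissue patterns).  No renormalization is
    performed; memberships are clipped downstream.  Apply once per
    stratum — repeated application compounds the modifier.
    """
    name, factor = _AGE_MODIFIERS[group]
    return replace(base, **{name: getattr(base, name) * factor})


@dataclass(frozen=True)
class NeutrosophicTriple:
    """A single (truth, indeterminacy, falsehood) evidence element."""

    t: float
    i: float
    f: float

    def __post_init__(self) -> None:
        for name, v in (("t", self.t), ("i", self.i), ("f", self.f)):
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"component {name}={v!r} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.t, self.i, self.f], dtype=float)


@dataclass(frozen=True)
class NeutrosophicMap:
    """Co-registered truth / indeterminacy / falsehood grids over an image."""

    t_grid: np.ndarray
    i_grid: np.ndarray
    f_grid: np.ndarray

    def __post_init__(self) -> None:
        t, i, f = (np.asarray(g, dtype=float) for g in (self.t_grid, self.i_grid, self.f_grid))
        if not (t.shape == i.shape == f.shape) or t.ndim != 2 or t.size == 0:
            raise ValueError("T, I, F grids must be non-empty 2-D arrays of equal shape")
        for name, g in (("t", t), ("i", i), ("f", f)):
            if not np.all(np.isfinite(g)):
                raise ValueError(f"{name}_grid contains non-finite values")
            if g.min() < 0.0 or g.max() > 1.0:
                raise ValueError(f"{name}_grid has values outside [0, 1]")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "i_grid", i)
        object.__setattr__(self, "f_grid", f)

    @property
    def height(self) -> int:
        return self.t_grid.shape[0]

    @property
    def width(self) -> int:
        return self.t_grid.shape[1]

    def mean_triple(self) -> NeutrosophicTriple:
        """Summarize the map by the spatial mean of each channel."""
        return NeutrosophicTriple(
            float(self.t_grid.mean()), float(self.i_grid.mean()), float(self.f_grid.mean())
        )

    def top_decile_triple(self) -> NeutrosophicTriple:
        """Summarize by the mean over the top decile of each channel."""
        out = []
        for g in (self.t_grid, self.i_grid, self.f_grid):
            flat = np.sort(g.ravel())
            k = max(1, flat.size // 10)
            out.append(float(flat[-k:].mean()))
        return NeutrosophicTriple(*out)


@dataclass
class AuxEvidence:
    """Optional auxiliary evidence grids co-registered with the image.

    Any absent grid defaults to a neutral constant: zero clinical,
    genetic, examiner and developmental evidence, and full healthy
    prior (``healthy_map = 1``).
    """

    clinical_map: Optional[np.ndarray] = None
    genetic_map: Optional[np.ndarray] = None
    examiner_map: Optional[np.ndarray] = None
    development_map: Optional[np.ndarray] = None
    healthy_map: Optional[np.ndarray] = None

    def resolved(self, shape: tuple[int, int]) -> "AuxEvidence":
        """Return a copy with every grid materialized at ``shape``."""
        def _grid(g: Optional[np.ndarray], default: float) -> np.ndarray:
            if g is None:
                return np.full(shape, default, dtype=float)
            arr = np.asarray(g, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"auxiliary grid shape {arr.shape} does not match image shape {shape}"
                )
            if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
                raise ValueError("auxiliary grids must be finite and within [0, 1]")
            return arr

        return AuxEvidence(
            clinical_map=_grid(self.clinical_map, 0.0),
            genetic_map=_grid(self.genetic_map, 0.0),
            examiner_map=_grid(self.examiner_map, 0.0),
            development_map=_grid(self.development_map, 0.0),
            healthy_map=_grid(self.healthy_map, 1.0),
        )


def _check_unit(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def truth_membership(intensity, clinical, genetic, p: MembershipParams):
    """Truth membership: sigmoid intensity response plus clinical/genetic evidence.

    ``clip(alpha_t * sigmoid(z) + beta_t * clinical + gamma_t * genetic, 0, 1)``
    where ``z = (intensity - mu_healthy) / sigma_pathological``, negated
    under the ``dark_lesions`` convention.  Accepts scalars or arrays.
    """
    intensity = _check_unit("intensity", intensity)
    clinical = _check_unit("clinical", clinical)
    genetic = _check_unit("genetic", genetic)
    z = (intensity - p.mu_healthy) / p.sigma_pathological
    if p.dark_lesions:
        z = -z
    sig = special.expit(z)
    raw = p.alpha_t * sig + p.beta_t * clinical + p.gamma_t * genetic
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def indeterminacy_membership(intensity, examiner_u, dev_u, p: MembershipParams):
    """Indeterminacy membership: Gaussian transition kernel plus uncertainty terms.

    ``clip(gamma_i * exp(-(intensity - mu_transition)^2 / (2 sigma_dev^2))
    + delta_i * examiner_u + epsilon_i * dev_u, 0, 1)``.
    """
    intensity = _check_unit("intensity", intensity)
    examiner_u = _check_unit("examiner_u", examiner_u)
    dev_u = _check_unit("dev_u", dev_u)
    kernel = np.exp(-((intensity - p.mu_transition) ** 2) / (2.0 * p.sigma_developmental**2))
    raw = p.gamma_i * kernel + p.delta_i * examiner_u + p.epsilon_i * dev_u
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def falsehood_membership(t, i, h_normal, p: MembershipParams):
    """Falsehood membership from already-computed truth and indeterminacy.

    ``clip(zeta_f * (1 - t) + eta_f * h_normal + theta_f * max(0, 1 - i - t), 0, 1)``.
    Inputs must lie in [0, 1].
    """
    arrs = []
    for name, x in (("t", t), ("i", i), ("h_normal", h_normal)):
        arr = _check_unit(name, x)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{name} outside [0, 1]")
        arrs.append(arr)
    t, i, h_normal = arrs
    raw = p.zeta_f * (1.0 - t) + p.eta_f * h_normal + p.theta_f * np.maximum(0.0, 1.0 - i - t)
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def neutrosophize_image(
    image: np.ndarray,
    aux: Optional[AuxEvidence] = None,
    p: Optional[MembershipParams] = None,
) -> NeutrosophicMap:
    """Apply the three membership functions element-wise over an image.

    The image must be a 2-D array of intensities in [0, 1]; auxiliary
    grids default to neutral evidence.  The returned map satisfies the
    neutrosophic constraint ``T + I + F <= 3`` everywhere by clipping.
    """
    p = p if p is not None else MembershipParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)) or img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must be finite and within [0, 1]")
    ev = (aux if aux is not None else AuxEvidence()).resolved(img.shape)
    t = truth_membership(img, ev.clinical_map, ev.genetic_map, p)
    i = indeterminacy_membership(img, ev.examiner_map, ev.development_map, p)
    f = falsehood_membership(t, i, ev.healthy_map, p)
    return NeutrosophicMap(t_grid=np.atleast_2d(t), i_grid=np.atleast_2d(i), f_grid=np.atleast_2d(f))
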