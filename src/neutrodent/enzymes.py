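"""Enzyme-kinetic feature operators for dental image analysis.

Each operator transplants a salivary-defense enzyme's rate law into
image space:

* alpha-amylase — a Michaelis-Menten law with competitive inhibition.
  Substrate is the caries-indicative pixel signal (``1 - intensity``
  under the dark-lesion convention) and the inhibitor is healthy-tissue
  evidence, so sound enamel suppresses the response.
* substrate binding — an Arrhenius-type affinity whose activation
  energy falls linearly with age (45 kJ/mol at age 3 to 35 kJ/mol at
  age 17), modeling enamel maturation, times a per-tooth maturation
  factor in [0.8, 1.2].
* lysozyme — multi-pattern matching against a library of reference
  infection patterns: a weighted sum of basis responses attenuated by
  ``exp(-d_k / sigma_cleavage)`` where ``d_k`` is Euclidean distance in
  feature space.
* immune scaling — a linear age ramp on baseline immune capacity.
* lactoferrin — competitive iron/calcium binding; the iron channel
  proxies inflammation, the calcium channel sound mineral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from neutrodent.membership import AuxEvidence

__all__ = [
    "FeatureMaps",
    "ImmuneParams",
    "KineticParams",
    "LactoferrinParams",
    "PatternLibrary",
    "amylase_rate",
    "binding_affinity",
    "default_pattern_library",
    "enzyme_feature_map",
    "immune_scaling",
    "lactoferrin_binding",
    "lysozyme_activity",
    "texture_features",
]

GAS_CONSTANT = 8.314  # J / (mol K)


@dataclass(frozen=True)
class KineticParams:
    """Constants of the amylase rate law and the age-dependent binding affinity.

    ``classical_competitive`` switches the inhibition factor from the
    as-adapted placement (multiplying the substrate term) to the
    textbook competitive form (multiplying ``k_m``).
    """

    v_max: float = 1.2
    k_m: float = 0.3
    k_i: float = 2.1
    k0: float = 1.5e6
    e_act_young: float = 45_000.0  # J/mol at age 3
    e_act_old: float = 35_000.0  # J/mol at age 17
    gas_r: float = GAS_CONSTANT
    temp: float = 310.0  # K
    maturation: float = 1.0
    classical_competitive: bool = False

    def __post_init__(self) -> None:
        if min(self.v_max, self.k_m, self.k_i, self.k0, self.temp) <= 0:
            raise ValueError("v_max, k_m, k_i, k0 and temp must be strictly positive")
        if self.e_act_young < self.e_act_old:
            raise ValueError("activation energy must not increase with age")
        if not (0.8 <= self.maturation <= 1.2):
            raise ValueError("maturation factor must lie in [0.8, 1.2]")


@dataclass
class PatternLibrary:
    """Reference infection patterns for the lysozyme operator."""

    templates: np.ndarray  # (n_patterns, dim)
    weights: np.ndarray  # (n_patterns,) in [0.1, 0.9]
    basis_gains: np.ndarray  # (n_patterns,) phi_k response gains
    sigma_cleavage: float = 0.15

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.basis_gains = np.asarray(self.basis_gains, dtype=float)
        n = self.templates.shape[0]
        if self.weights.shape != (n,) or self.basis_gains.shape != (n,):
            raise ValueError("templates, weights and basis_gains must have equal length")
        if self.sigma_cleavage <= 0:
            raise ValueError("sigma_cleavage must be strictly positive")


N_PATTERNS = 12
_FEATURE_DIM = 12  # mean, variance, gradient magnitude + 9 oriented responses


def default_pattern_library(seed: int = 1729) -> PatternLibrary:
    """Seeded library of 12 reference infection patterns in the 12-D texture space."""
    rng = np.random.default_rng(seed)
    templates = rng.uniform(0.0, 1.0, size=(N_PATTERNS, _FEATURE_DIM))
    weights = rng.uniform(0.1, 0.9, size=N_PATTERNS)
    gains = np.ones(N_PATTERNS)
    return PatternLibrary(templates=templates, weights=weights, basis_gains=gains)


@dataclass(frozen=True)
class ImmuneParams:
    """Age ramp of immune response capacity with a genetic multiplier."""

    i_baseline: float = 1.0
    beta: float = 0.5
    age_min: float = 3.0
    age_max: float = 17.0
    g_genet: float = 1.0

    def __post_init__(self) -> None:
        if self.i_baseline <= 0 or self.g_genet <= 0:
            raise ValueError("i_baseline and g_genet must be strictly positive")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")


@dataclass(frozen=True)
class LactoferrinParams:
    """Competitive iron/calcium binding constants.

    The default profile is rescaled to the normalized [0, 1] image
    domain.  ``literal_molar`` reproduces the molar constants
    (K_d,Fe = 1e-20 M, K_d,Ca = 1e-6 M); at image scale the iron term
    then saturates immediately.
    """

    l_total: float = 1.0
    kd_fe: float = 0.1
    kd_ca: float = 0.5

    def __post_init__(self) -> None:
        if min(self.l_total, self.kd_fe, self.kd_ca) <= 0:
            raise ValueError("all lactoferrin constants must be strictly positive")

    @classmethod
    def literal_molar(cls) -> "LactoferrinParams":
        return cls(l_total=1.0, kd_fe=1e-20, kd_ca=1e-6)


def _nonneg(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{name} must be finite and non-negative")
    return arr


def amylase_rate(s, inh, p: Optional[KineticParams] = None):
    """Amylase-inspired Michaelis-Menten rate with competitive inhibition.

    ``v = v_max * s / (k_m + s * (1 + inh / k_i))`` by default; the
    textbook competitive placement ``k_m * (1 + inh / k_i) + s`` is
    available via ``classical_competitive``.
    """
    p = p if p is not None else KineticParams()
    s = _nonneg("substrate", s)
    inh = _nonneg("inhibitor", inh)
    factor = 1.0 + inh / p.k_i
    if p.classical_competitive:
        denom = p.k_m * factor + s
    else:
        denom = p.k_m + s * factor
    out = p.v_max * s / denom
    return float(out) if out.ndim == 0 else out


def activation_energy(age: float, p: Optional[KineticParams] = None) -> float:
    """Age-dependent activation energy, linear from age 3 to age 17 (J/mol)."""
    p = p if p is not None else KineticParams()
    if not (3.0 <= age <= 17.0):
        raise ValueError(f"age must lie in [3, 17] years, got {age!r}")
    frac = (age - 3.0) / 14.0
    return p.e_act_young + frac * (p.e_act_old - p.e_act_young)


def binding_affinity(age: float, p: Optional[KineticParams] = None) -> float:
    """Arrhenius-type enamel binding affinity, increasing with age.

    ``k0 * exp(-E_act(age) / (R T)) * maturation``.
    """
    p = p if p is not None else KineticParams()
    e_act = activation_energy(age, p)
    return p.k0 * float(np.exp(-e_act / (p.gas_r * p.temp))) * p.maturation


def lysozyme_activity(feature_vec: Sequence[float], lib: PatternLibrary) -> float:
    """Multi-pattern antimicrobial response of a single feature vector.

    ``sum_k w_k * phi_k * exp(-d_k / sigma_cleavage)`` with ``d_k`` the
    Euclidean distance to reference pattern k.
    """
    v = np.asarray(feature_vec, dtype=float)
    if v.ndim != 1 or v.shape[0] != lib.templates.shape[1]:
        raise ValueError(
            f"feature vector dimension {v.shape} does not match template "
            f"dimension {lib.templates.shape[1]}"
        )
    d = np.linalg.norm(lib.templates - v[None, :], axis=1)
    return float(np.sum(lib.weights * lib.basis_gains * np.exp(-d / lib.sigma_cleavage)))


def immune_scaling(age: float, p: Optional[ImmuneParams] = None) -> float:
    """Linear developmental ramp of immune capacity over the pediatric age range."""
    p = p if p is not None else ImmuneParams()
    if not (p.age_min <= age <= p.age_max):
        raise ValueError(f"age must lie in [{p.age_min}, {p.age_max}], got {age!r}")
    frac = (age - p.age_min) / (p.age_max - p.age_min)
    return p.i_baseline * (1.0 + p.beta * frac) * p.g_genet


def lactoferrin_binding(fe, ca, p: Optional[LactoferrinParams] = None):
    """Competitive iron-sequestration response.

    ``l_total * fe / (kd_fe + fe + ca / kd_ca)``; calcium competes in
    the denominator, so the response decreases in ``ca`` at fixed iron.
    """
    p = p if p is not None else LactoferrinParams()
    fe = _nonneg("fe", fe)
    ca = _nonneg("ca", ca)
    out = p.l_total * fe / (p.kd_fe + fe + ca / p.kd_ca)
    return float(out) if out.ndim == 0 else out


def texture_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel 12-D texture descriptor used by the lysozyme operator.

    Channels: local mean, local variance, gradient magnitude, and nine
    oriented Gaussian-derivative responses (absolute value), each
    min-max normalized to [0, 1] over the image (constant channels map
    to zero).  Filters use nearest-neighbor boundaries so a constant
    image yields constant features.
    """
    img = np.asarray(image, dtype=float)
    mean = ndimage.uniform_filter(img, size=3, mode="nearest")
    sq_mean = ndimage.uniform_filter(img**2, size=3, mode="nearest")
    var = np.maximum(sq_mean - mean**2, 0.0)
    gy = ndimage.gaussian_filter(img, sigma=1.0, order=(1, 0), mode="nearest")
    gx = ndimage.gaussian_filter(img, sigma=1.0, order=(0, 1), mode="nearest")
    grad = np.hypot(gx, gy)
    channels = [mean, var, grad]
    for theta in np.linspace(0.0, np.pi, 9, endpoint=False):
        channels.append(np.abs(np.cos(theta) * gx + np.sin(theta) * gy))
    out = np.empty(img.shape + (len(channels),), dtype=float)
    for k, ch in enumerate(channels):
        lo, hi = float(ch.min()), float(ch.max())
        out[..., k] = (ch - lo) / (hi - lo) if hi > lo else 0.0
    return out


@dataclass
class FeatureMaps:
    """Bundle of per-pixel enzyme feature grids and per-patient scalars."""

    amylase: np.ndarray
    lysozyme: np.ndarray
    lactoferrin: np.ndarray
    affinity: float
    immune: float


def enzyme_feature_map(
    image: np.ndarray,
    aux: Optional[AuxEvidence] = None,
    age: float = 8.0,
    kinetic: Optional[KineticParams] = None,
    library: Optional[PatternLibrary] = None,
    immune: Optional[ImmuneParams] = None,
    lactoferrin: Optional[LactoferrinParams] = None,
    dark_lesions: bool = True,
) -> FeatureMaps:
    """Apply every enzyme operator over an image.

    Substrate is ``1 - intensity`` under the dark-lesion convention
    (demineralized pixels are high-substrate) and the competitive
    inhibitor is the healthy-tissue evidence grid.  The iron proxy is
    the auxiliary clinical (inflammation) channel and the calcium proxy
    is pixel brightness.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image must be normalized to [0, 1]")
    kinetic = kinetic if kinetic is not None else KineticParams()
    library = library if library is not None else default_pattern_library()
    lactoferrin = lactoferrin if lactoferrin is not None else LactoferrinParams()
    ev = (aux if aux is not None else AuxEvidence()).resolved(img.shape)

    substrate = 1.0 - img if dark_lesions else img
    amylase = amylase_rate(substrate, ev.healthy_map, kinetic)

    feats = texture_features(img)
    flat = feats.reshape(-1, feats.shape[-1])
    d = np.linalg.norm(flat[:, None, :] - library.templates[None, :, :], axis=2)
    act = (library.weights * library.basis_gains * np.exp(-d / library.sigma_cleavage)).sum(axis=1)
    lysozyme = act.reshape(img.shape)

    lacto = lactoferrin_binding(ev.clinical_map, img, lactoferrin)

    return FeatureMaps(
        amylase=amylase,
        lysozyme=lysozyme,
        lactoferrin=lacto,
        affinity=binding_affinity(age, kinetic),
        immune=immune_scaling(age, immune),
    )
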