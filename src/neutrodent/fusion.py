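"""Multi-modal evidence fusion and diagnostic scoring.

Per-modality neutrosophic triples are combined by a convex weighted
mean (weights non-negative, normalized); the composed pipeline is
``Output = O(Fused(D(N(x))))`` — neutrosophify each modality, apply
temporal decay, fuse, then map the fused triple to a diagnosis.  The
diagnosis score is ``(T + (1 - F)) / 2`` — evidence for disease plus
absence of evidence against — and the reported uncertainty is the
fused indeterminacy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from neutrodent.config import Config, ConfigError
from neutrodent.diffusion import SourceField, evolve_indeterminacy, evolve_truth, temporal_decay
from neutrodent.membership import (
    AuxEvidence,
    MembershipParams,
    NeutrosophicMap,
    NeutrosophicTriple,
    age_adjusted_params,
    age_group_of,
    falsehood_membership,
    indeterminacy_membership,
    neutrosophize_image,
    truth_membership,
)
from neutrodent.phantoms import MODALITIES, PatientRecord

logger = logging.getLogger("neutrodent.fusion")

__all__ = ["Diagnosis", "FusionWeights", "decay_then_fuse", "diagnose", "fuse", "run_pipeline"]

LABELS = ("healthy", "incipient", "moderate", "severe")


@dataclass(frozen=True)
class FusionWeights:
    """Non-negative per-modality weights summing to one."""

    weights: tuple[float, ...] = (0.35, 0.40, 0.15, 0.10)

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if len(w) < 1:
            raise ConfigError("at least one fusion weight is required")
        if any(x < 0 for x in w):
            raise ConfigError("fusion weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError(f"fusion weights must sum to 1, got {sum(w)!r}")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class Diagnosis:
    """Fused diagnostic output: score, uncertainty and stratum label."""

    score: float
    uncertainty: float
    label: str
    fused: NeutrosophicTriple


def fuse(triples: Sequence[NeutrosophicTriple], w: FusionWeights) -> NeutrosophicTriple:
    """Component-wise convex combination of per-modality triples."""
    if len(triples) != len(w.weights):
        raise ValueError(
            f"got {len(triples)} triples but {len(w.weights)} weights"
        )
    arr = np.stack([tr.as_array() for tr in triples])
    out = np.asarray(w.weights) @ arr
    out = np.clip(out, 0.0, 1.0)  # guard rounding at the boundary
    return NeutrosophicTriple(*map(float, out))


def decay_then_fuse(
    triples: Sequence[NeutrosophicTriple],
    w: FusionWeights,
    lam: float,
    t: float,
) -> NeutrosophicTriple:
    """Apply temporal decay to every triple component, then fuse."""
    decayed = [
        NeutrosophicTriple(*(temporal_decay(tr.as_array(), lam, t)))
        for tr in triples
    ]
    return fuse(decayed, w)


def diagnose(
    fused: NeutrosophicTriple,
    thresholds: Sequence[float] = (0.25, 0.50, 0.75),
) -> Diagnosis:
    """Map a fused triple to a scored, labeled diagnosis.

    ``score = (T + (1 - F)) / 2``; the label is the stratum of the
    score against three strictly increasing thresholds in (0, 1).
    """
    t = tuple(thresholds)
    if len(t) != 3 or not (0.0 < t[0] < t[1] < t[2] < 1.0):
        raise ConfigError("thresholds must be three strictly increasing values in (0, 1)")
    score = (fused.t + (1.0 - fused.f)) / 2.0
    label = LABELS[int(np.searchsorted(t, score, side="right"))]
    return Diagnosis(score=float(score), uncertainty=fused.i, label=label, fused=fused)


def _scalar_modality_triple(
    modality: str, score: float, p: MembershipParams
) -> NeutrosophicTriple:
    """Neutrosophify a scalar modality score.

    The score is mapped onto the image-intensity convention (disease is
    dark): intensity ``1 - score``, healthy evidence ``1 - score``, and
    the score itself feeds the modality's own evidence channel.
    """
    intensity = 1.0 - score if p.dark_lesions else score
    clinical = score if modality == "clinical" else 0.0
    genetic = score if modality == "genetic" else 0.0
    t = truth_membership(intensity, clinical, genetic, p)
    i = indeterminacy_membership(intensity, 0.0, 0.0, p)
    f = falsehood_membership(t, i, 1.0 - score, p)
    return NeutrosophicTriple(t, i, f)


def _imaging_triple(record: PatientRecord, p: MembershipParams, cfg: Config) -> NeutrosophicTriple:
    """Neutrosophify the radiographic image, diffuse, and summarize."""
    aux = AuxEvidence(clinical_map=record.clinical_map)
    nmap = neutrosophize_image(record.image, aux, p)
    dp = cfg.diffusion
    src = SourceField(s_grid=np.zeros_like(nmap.t_grid))
    t_grid = evolve_truth(nmap.t_grid, src, dp)
    i_grid = evolve_indeterminacy(nmap.i_grid, dp)
    ev = aux.resolved(t_grid.shape)
    f_grid = falsehood_membership(t_grid, i_grid, ev.healthy_map, p)
    diffused = NeutrosophicMap(t_grid, i_grid, np.asarray(f_grid))
    if cfg.fusion.summarizer == "top_decile":
        return diffused.top_decile_triple()
    return diffused.mean_triple()


def run_pipeline(record: PatientRecord, config: Optional[Config] = None) -> Diagnosis:
    """Run the full diagnostic pipeline on one patient record.

    Each present modality is neutrosophified (the radiographic image
    additionally passes through the diffusion stage and is summarized
    spatially), weights are renormalized over present modalities,
    triples are decayed and fused, and the fused triple is scored.
    """
    cfg = config if config is not None else Config()
    p = age_adjusted_params(cfg.membership, age_group_of(record.age))
    scores = record.modality_scores()
    if not scores and record.image is None:
        raise ValueError("record must carry at least one modality")

    triples: list[NeutrosophicTriple] = []
    weights: list[float] = []
    base_w = dict(zip(MODALITIES, cfg.fusion.weights))
    for modality in MODALITIES:
        if modality == "radiographic" and record.image is not None:
            triples.append(_imaging_triple(record, p, cfg))
            weights.append(base_w[modality])
            logger.debug("modality=%s summarized from image", modality)
        elif modality in scores:
            triples.append(_scalar_modality_triple(modality, scores[modality], p))
            weights.append(base_w[modality])
            logger.debug("modality=%s score=%.3f", modality, scores[modality])

    total = sum(weights)
    w = FusionWeights(tuple(x / total for x in weights))
    fused = decay_then_fuse(triples, w, cfg.diffusion.decay_lambda, cfg.fusion.decay_time)
    result = diagnose(fused, cfg.fusion.thresholds)
    logger.debug(
        "fused T=%.3f I=%.3f F=%.3f score=%.3f label=%s",
        fused.t, fused.i, fused.f, result.score, result.label,
    )
    return result
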