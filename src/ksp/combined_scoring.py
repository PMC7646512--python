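"""Normalization and combination of the network and sequence scorers.

Per query site, each scorer's raw scores over the candidate kinases are
min-max normalized to [0, 1]; SequenceScore is the sum of the normalized
PWM and CBS scores, and OverallScore adds the normalized network affinity
on top.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .io_formats import PhosphoSite
from .network_scoring import KinaseAffinityGraph, rank_candidates
from .sequence_scoring import (
    DEFAULT_K_FRACTION,
    PWMModel,
    TrainingCorpus,
    cbs_score,
    pwm_score,
)

SCORERS = ("ksp", "pwm", "cbs")
MODES = ("ksp", "pwm", "cbs", "sequence", "overall")


def normalize_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize a score vector; constant vectors map to all zeros."""
    if not raw:
        raise ValueError("cannot normalize an empty score vector")
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {k: 0.0 for k in raw}
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


@dataclass
class ScoreVector:
    """All raw, normalized and combined scores for one query site."""

    site: PhosphoSite
    raw: dict[str, dict[str, float]] = field(default_factory=dict)
    norm: dict[str, dict[str, float]] = field(default_factory=dict)
    sequence_score: dict[str, float] = field(default_factory=dict)
    overall_score: dict[str, float] = field(default_factory=dict)
    missing_scorers: frozenset[str] = frozenset()


def build_score_vector(
    site: PhosphoSite,
    affinity: KinaseAffinityGraph | None,
    models: Sequence[PWMModel] | None,
    corpus: TrainingCorpus | None,
    k_fraction: float = DEFAULT_K_FRACTION,
) -> ScoreVector:
    """Collect raw scores from every available scorer for one site.

    A substrate absent from the affinity graph leaves the ``ksp`` scorer
    unpopulated (flagged in :attr:`ScoreVector.missing_scorers`) rather
    than failing, so a sequence-only ranking is still possible.
    """
    sv = ScoreVector(site=site)
    missing = set(SCORERS)
    if affinity is not None and site.substrate_id in affinity.proteins:
        scores = affinity.kinase_scores(site.substrate_id)
        sv.raw["ksp"] = {k: scores.get(k, 0.0) for k in affinity.kinases}
        missing.discard("ksp")
    if models:
        sv.raw["pwm"] = {m.kinase_id: pwm_score(m, site.peptide) for m in models}
        missing.discard("pwm")
    if corpus is not None and len(corpus) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cbs = cbs_score(corpus, site.peptide, k_fraction=k_fraction)
        sv.raw["cbs"] = {kin: cbs.get(kin, 0.0) for kin in corpus.kinases}
        missing.discard("cbs")
    sv.missing_scorers = frozenset(missing)
    return sv


def combine(sv: ScoreVector, candidates: str = "intersection") -> ScoreVector:
    """Fill normalized and combined scores in place (and return ``sv``).

    ``candidates`` chooses the kinase set carrying OverallScore:
    ``"intersection"`` (default) restricts to kinases known to every
    populated scorer; ``"union"`` scores all kinases, treating missing
    components as 0.
    """
    if candidates not in ("intersection", "union"):
        raise ValueError(f"unknown candidate policy {candidates!r}")
    if not sv.raw:
        raise ValueError("no raw scores populated")
    kinase_sets = [set(v) for v in sv.raw.values()]
    if candidates == "intersection":
        cand = set.intersection(*kinase_sets)
    else:
        cand = set.union(*kinase_sets)
    if not cand:
        raise ValueError("candidate kinase set is empty under the chosen policy")
    for scorer, raw in sv.raw.items():
        restricted = {k: raw[k] for k in cand if k in raw}
        sv.norm[scorer] = normalize_scores(restricted) if restricted else {}
    npwm = sv.norm.get("pwm", {})
    ncbs = sv.norm.get("cbs", {})
    nksp = sv.norm.get("ksp", {})
    sv.sequence_score = {
        k: npwm.get(k, 0.0) + ncbs.get(k, 0.0) for k in sorted(cand)
    }
    sv.overall_score = {
        k: nksp.get(k, 0.0) + sv.sequence_score[k] for k in sorted(cand)
    }
    return sv


def rank_kinases_overall(
    sv: ScoreVector, mode: str = "overall", top_k: int = 10
) -> list[tuple[str, float]]:
    """Rank kinases for one site by the requested scorer or combination."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode in SCORERS:
        scores = sv.norm.get(mode) or sv.raw.get(mode)
        if not scores:
            raise ValueError(f"scorer {mode!r} was not computed for this site")
    elif mode == "sequence":
        if not sv.sequence_score:
            raise ValueError("sequence score was not computed for this site")
        scores = sv.sequence_score
    else:
        if not sv.overall_score:
            raise ValueError("overall score was not computed for this site")
        scores = sv.overall_score
    return rank_candidates(scores, top_k)


def score_and_rank(
    site: PhosphoSite,
    affinity: KinaseAffinityGraph | None,
    models: Sequence[PWMModel] | None,
    corpus: TrainingCorpus | None,
    mode: str = "overall",
    top_k: int = 10,
    k_fraction: float = DEFAULT_K_FRACTION,
    candidates: str = "intersection",
) -> tuple[ScoreVector, list[tuple[str, float]]]:
    """End-to-end convenience: raw scores -> combination -> ranking."""
    sv = build_score_vector(site, affinity, models, corpus, k_fraction=k_fraction)
    if mode in ("sequence", "overall") and sv.missing_scorers >= {"pwm", "cbs"}:
        raise ValueError("sequence scorers unavailable; cannot combine")
    if mode == "overall" and "ksp" in sv.missing_scorers:
        # soft fallback documented in the vector's missing_scorers flag
        combine(sv, candidates=candidates)
        return sv, rank_kinases_overall(sv, mode="sequence", top_k=top_k)
    combine(sv, candidates=candidates)
    return sv, rank_kinases_overall(sv, mode=mode, top_k=top_k)
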