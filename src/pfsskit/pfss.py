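"""Core similarity scoring: difference scores, gamma normalization, per-site
PFSS, and the three-level aggregation to group assessments.

For a reference-side functional-site prediction with cumulative probability
``p_ref`` and the prediction at the corresponding site of a structure model
with probability ``p_model``:

* difference score ``d = |p_ref - p_model|``
* similarity score ``SS = 1 - d``
* ``PFSS = SS / gamma``, where gamma is the mean reference-side probability
  of the included predictions of that SeqFEATURE model within that domain.

Aggregation is unweighted at both upper levels: per (group, domain), site
PFSS values are averaged within each SeqFEATURE model, those per-model means
are averaged to the per-domain gPFSS (each model counts once regardless of
its number of site instances), and a group's final gPFSS / cumPFSS are the
mean / sum of its per-domain values over the domains it addressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .calibration import SiteProbability
from .errors import AssessmentError, DomainValueError, NormalizationError
from .io import DomainDefinition, residues_in_domain

__all__ = [
    "SitePair",
    "GroupAssessment",
    "difference_score",
    "pair_sites",
    "compute_gamma",
    "pfss_of_pair",
    "apply_gamma",
    "aggregate_domain",
    "per_model_pfss",
    "assess_group",
]

GammaTable = dict[tuple[str, str], float]
"""Map (sf_model_id, domain_id) -> gamma normalization factor in (0, 1]."""


@dataclass(frozen=True)
class SitePair:
    """A matched reference/model functional-site prediction.

    ``diff`` is always the absolute probability difference; the signed raw
    difference is recoverable as ``p_model - p_ref``.  ``pfss`` is ``None``
    until gamma normalization has been applied; normalized values may exceed
    1 when the model-side probability overshoots a gamma below 1.
    """

    sf_model_id: str
    domain_id: str
    group_name: str
    model_attempt: int
    residue_number: int
    p_ref: float
    p_model: float
    diff: float
    similarity: float
    pfss: float | None = None


@dataclass(frozen=True)
class GroupAssessment:
    """Per-group summary: per-domain gPFSS values, their mean (final gPFSS),
    sample SD, and sum (cumPFSS) over the ``n_domains`` domains addressed."""

    group_name: str
    per_domain_gpfss: dict[str, float]
    gpfss: float
    gpfss_sd: float
    cumpfss: float
    n_domains: int


def difference_score(p_ref: float, p_model: float) -> float:
    """Absolute difference of two cumulative probabilities."""
    for name, p in (("p_ref", p_ref), ("p_model", p_model)):
        if not 0.0 <= p <= 1.0:
            raise DomainValueError(f"{name} must be in [0, 1], got {p}")
    return abs(p_ref - p_model)


def pair_sites(ref_sites: Sequence[SiteProbability],
               model_sites: Sequence[SiteProbability],
               domain: DomainDefinition,
               *,
               group_name: str = "",
               model_attempt: int = 1,
               missing_policy: str = "skip",
               require_chain_match: bool = False) -> tuple[list[SitePair], int]:
    """Match filtered reference sites to model-side sites within one domain.

    One pair is produced per reference site whose anchor residue lies in the
    domain's residue ranges and whose (sf_model_id, residue_number,
    anchor_atom) — plus chain when ``require_chain_match`` — exists among
    ``model_sites``.  A reference site with no model-side counterpart is
    skipped (counted in the returned skip tally) under the default policy, or
    scored as if the model probability were 0 under ``missing_policy=
    "penalize"``.  Pairs carry diff and similarity but no PFSS yet.

    Returns ``(pairs, n_skipped)``.
    """
    if missing_policy not in ("skip", "penalize"):
        raise DomainValueError(f"unknown missing-site policy {missing_policy!r}")
    residues = residues_in_domain(domain)

    def model_key(sp: SiteProbability):
        key = (sp.site.sf_model_id, sp.site.residue_number, sp.site.anchor_atom)
        return key + (sp.site.chain,) if require_chain_match else key

    model_index = {model_key(sp): sp for sp in model_sites}

    pairs: list[SitePair] = []
    n_skipped = 0
    for ref in ref_sites:
        if ref.site.residue_number not in residues:
            continue
        counterpart = model_index.get(model_key(ref))
        if counterpart is None:
            if missing_policy == "skip":
                n_skipped += 1
                continue
            p_model = 0.0
        else:
            p_model = counterpart.p
        diff = difference_score(ref.p, p_model)
        pairs.append(SitePair(
            sf_model_id=ref.site.sf_model_id,
            domain_id=domain.domain_id,
            group_name=group_name,
            model_attempt=model_attempt,
            residue_number=ref.site.residue_number,
            p_ref=ref.p,
            p_model=p_model,
            diff=diff,
            similarity=1.0 - diff,
        ))
    return pairs, n_skipped


def compute_gamma(included_ref_sites: Iterable[tuple[SiteProbability, str]]) -> GammaTable:
    """Gamma normalization factors from included reference sites.

    Takes (scored site, domain_id) assignments — only sites that passed the
    specificity filter and fall inside the domain belong here — and returns,
    for each (sf_model_id, domain_id) with at least one site, the arithmetic
    mean of the reference cumulative probabilities.  Keys with no sites are
    simply absent: downstream treats them as "no sites to score".
    """
    sums: dict[tuple[str, str], list[float]] = {}
    for sp, domain_id in included_ref_sites:
        sums.setdefault((sp.site.sf_model_id, domain_id), []).append(sp.p)
    return {key: math.fsum(ps) / len(ps) for key, ps in sums.items()}


def pfss_of_pair(similarity: float, gamma: float) -> float:
    """Normalize one similarity score: ``similarity / gamma``."""
    if not gamma > 0:
        raise NormalizationError(f"gamma must be > 0, got {gamma}")
    return similarity / gamma


def apply_gamma(pairs: Iterable[SitePair], gamma: GammaTable) -> list[SitePair]:
    """Fill the PFSS field of each pair from its (sf_model, domain) gamma."""
    out = []
    for pair in pairs:
        key = (pair.sf_model_id, pair.domain_id)
        if key not in gamma:
            raise NormalizationError(f"no gamma for (sf_model, domain) {key!r}")
        out.append(replace(pair, pfss=pfss_of_pair(pair.similarity, gamma[key])))
    return out


def aggregate_domain(pairs: Sequence[SitePair]) -> float:
    """Per-domain gPFSS for one (group, domain): the unweighted mean over
    SeqFEATURE models of each model's mean site PFSS.

    The two-level average deliberately differs from the pooled mean whenever
    models contribute unequal site counts.
    """
    if not pairs:
        raise AssessmentError("aggregate_domain requires at least one pair")
    by_model: dict[str, list[float]] = {}
    for pair in pairs:
        if pair.pfss is None:
            raise AssessmentError("pair has no PFSS; apply gamma normalization first")
        by_model.setdefault(pair.sf_model_id, []).append(pair.pfss)
    model_means = [math.fsum(v) / len(v) for v in by_model.values()]
    return math.fsum(model_means) / len(model_means)


def per_model_pfss(pairs: Iterable[SitePair],
                   group_name: str | None = None) -> dict[str, float]:
    """Mean PFSS per SeqFEATURE model over all pairs (optionally one group's).

    This pooling supports follow-up head-to-head comparisons at the
    SeqFEATURE-model level: two groups' per-model average arrays, restricted
    to the models both groups share, can be compared with a Mann-Whitney U
    test as a finer-grained alternative to the per-domain comparison.
    """
    by_model: dict[str, list[float]] = {}
    for pair in pairs:
        if group_name is not None and pair.group_name != group_name:
            continue
        if pair.pfss is None:
            raise AssessmentError("pair has no PFSS; apply gamma normalization first")
        by_model.setdefault(pair.sf_model_id, []).append(pair.pfss)
    return {m: math.fsum(v) / len(v) for m, v in sorted(by_model.items())}


def assess_group(group_name: str, per_domain: Mapping[str, float]) -> GroupAssessment:
    """Fold per-domain gPFSS values into the final group assessment:
    gPFSS = mean, cumPFSS = sum, over the domains the group addressed.

    ``gpfss_sd`` is the sample standard deviation across domains (0 when only
    one domain was addressed).
    """
    if not per_domain:
        raise AssessmentError(f"group {group_name!r} addressed no domains")
    values = list(per_domain.values())
    n = len(values)
    cumpfss = math.fsum(values)
    gpfss = cumpfss / n
    if n > 1:
        sd = math.sqrt(math.fsum((v - gpfss) ** 2 for v in values) / (n - 1))
    else:
        sd = 0.0
    return GroupAssessment(
        group_name=group_name,
        per_domain_gpfss=dict(per_domain),
        gpfss=gpfss,
        gpfss_sd=sd,
        cumpfss=cumpfss,
        n_domains=n,
    )
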