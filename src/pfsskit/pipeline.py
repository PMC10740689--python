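"""Campaign orchestration: tables in, pairs / gammas / group assessments out.

Glues together calibration, domain mapping, pairing, gamma normalization and
aggregation for a whole benchmarking campaign (many groups, many targets),
and provides TSV round-trip I/O for the result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as tbl
from .calibration import SiteProbability, filter_reference_sites, score_sites
from .errors import FormatError, ValidationError
from .pfss import (GammaTable, GroupAssessment, SitePair, aggregate_domain,
                   apply_gamma, assess_group, compute_gamma, pair_sites)

__all__ = [
    "CampaignResult",
    "score_campaign",
    "assign_reference_domains",
    "write_pair_table", "read_pair_table",
    "write_gamma_table", "read_gamma_table",
    "write_per_domain_table", "read_per_domain_table",
    "write_group_table", "read_group_table",
]

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["sf_model_id", "domain_id", "group_name", "model_attempt",
                "residue_number", "p_ref", "p_model", "diff", "similarity", "pfss"]
GAMMA_COLUMNS = ["sf_model_id", "domain_id", "gamma"]
PER_DOMAIN_COLUMNS = ["group_name", "domain_id", "gpfss"]
GROUP_COLUMNS = ["group_name", "gpfss", "gpfss_sd", "cumpfss", "n_domains"]


@dataclass
class CampaignResult:
    """Everything a scored campaign produces, plus per-stage audit counts."""

    pairs: list[SitePair]
    gamma: GammaTable
    per_domain: dict[str, dict[str, float]]  # group -> domain -> gPFSS
    assessments: dict[str, GroupAssessment]
    n_reference_sites: int = 0
    n_included_sites: int = 0
    n_pairs: int = 0
    n_skipped: int = 0


def assign_reference_domains(ref_sites: Sequence[SiteProbability],
                             domains: Sequence[tbl.DomainDefinition],
                             ) -> list[tuple[SiteProbability, str]]:
    """Assign scored reference sites to domains by target id and residue
    membership; sites outside every domain are dropped."""
    by_target: dict[str, list[tuple[tbl.DomainDefinition, set[int]]]] = {}
    for d in domains:
        by_target.setdefault(d.target_id, []).append((d, tbl.residues_in_domain(d)))
    assigned = []
    for sp in ref_sites:
        for domain, residues in by_target.get(sp.site.structure_id, []):
            if sp.site.residue_number in residues:
                assigned.append((sp, domain.domain_id))
    return assigned


def score_campaign(reference_sites: Sequence[tbl.SitePrediction],
                   model_sites: Sequence[tbl.SitePrediction],
                   calibration: Sequence[tbl.CalibrationEntry],
                   domains: Sequence[tbl.DomainDefinition],
                   *,
                   category: str | None = None,
                   attempt_policy: str = "first",
                   missing_policy: str = "skip",
                   require_chain_match: bool = False) -> CampaignResult:
    """Run the full scoring chain for one campaign.

    ``reference_sites`` carry target ids as structure ids; ``model_sites``
    carry ``"<target>/<group>/<attempt>"`` ids.  ``category`` restricts the
    analysis to domains of one difficulty category.  ``attempt_policy`` is
    ``"first"`` (use attempt 1 submissions only) or ``"best"`` (per (group,
    domain), keep the attempt with the highest per-domain gPFSS).
    """
    if attempt_policy not in ("first", "best"):
        raise ValidationError(f"unknown attempt policy {attempt_policy!r}")
    if category is not None:
        if category not in tbl.CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        domains = [d for d in domains if d.category == category]

    cal_index = tbl.calibration_index(calibration)
    scored_ref = score_sites(reference_sites, cal_index)
    included = filter_reference_sites(scored_ref, cal_index)
    log.info("reference sites read: %d; above specificity threshold: %d",
             len(scored_ref), len(included))

    assigned = assign_reference_domains(included, domains)
    gamma = compute_gamma(assigned)

    # reference sites grouped per domain for pairing
    ref_by_domain: dict[str, list[SiteProbability]] = {}
    for sp, domain_id in assigned:
        ref_by_domain.setdefault(domain_id, []).append(sp)
    domain_by_id = {d.domain_id: d for d in domains}

    # model-side sites grouped per (group, attempt, target); scored, unfiltered
    scored_model = score_sites(model_sites, cal_index)
    model_groups: dict[tuple[str, int, str], list[SiteProbability]] = {}
    for sp in scored_model:
        target, group, attempt = tbl.split_model_structure_id(sp.site.structure_id)
        model_groups.setdefault((group, attempt, target), []).append(sp)

    # candidate per-(group, domain, attempt) scoring
    candidates: dict[tuple[str, str], dict[int, tuple[float, list[SitePair]]]] = {}
    n_skipped = 0
    for (group, attempt, target), sites in sorted(model_groups.items()):
        if attempt_policy == "first" and attempt != 1:
            continue
        for domain in [d for d in domains if d.target_id == target]:
            refs = ref_by_domain.get(domain.domain_id, [])
            if not refs:
                continue
            pairs, skipped = pair_sites(
                refs, sites, domain_by_id[domain.domain_id],
                group_name=group, model_attempt=attempt,
                missing_policy=missing_policy,
                require_chain_match=require_chain_match)
            n_skipped += skipped
            if not pairs:
                log.info("group %s domain %s attempt %d: no pairs formed",
                         group, domain.domain_id, attempt)
                continue
            pairs = apply_gamma(pairs, gamma)
            value = aggregate_domain(pairs)
            candidates.setdefault((group, domain.domain_id), {})[attempt] = (value, pairs)

    # resolve attempt policy and assemble results
    all_pairs: list[SitePair] = []
    per_domain: dict[str, dict[str, float]] = {}
    for (group, domain_id), by_attempt in sorted(candidates.items()):
        if attempt_policy == "first":
            value, pairs = by_attempt[1]
        else:
            best = max(by_attempt.items(), key=lambda kv: (kv[1][0], -kv[0]))
            value, pairs = best[1]
        per_domain.setdefault(group, {})[domain_id] = value
        all_pairs.extend(pairs)

    assessments = {group: assess_group(group, dom) for group, dom in per_domain.items()}
    log.info("pairs formed: %d; reference sites without model counterpart: %d",
             len(all_pairs), n_skipped)
    return CampaignResult(
        pairs=all_pairs,
        gamma=gamma,
        per_domain=per_domain,
        assessments=assessments,
        n_reference_sites=len(scored_ref),
        n_included_sites=len(included),
        n_pairs=len(all_pairs),
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# result-table I/O (full precision; round-trip safe)


def write_pair_table(pairs: Iterable[SitePair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.sf_model_id, p.domain_id, p.group_name, p.model_attempt, p.residue_number,
          repr(p.p_ref), repr(p.p_model), repr(p.diff), repr(p.similarity),
          "" if p.pfss is None else repr(p.pfss)) for p in pairs],
        columns=PAIR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> list[SitePair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pair table ({path}): missing column(s): {', '.join(missing)}")
    return [SitePair(
        sf_model_id=r.sf_model_id, domain_id=r.domain_id, group_name=r.group_name,
        model_attempt=int(r.model_attempt), residue_number=int(r.residue_number),
        p_ref=float(r.p_ref), p_model=float(r.p_model), diff=float(r.diff),
        similarity=float(r.similarity),
        pfss=None if r.pfss == "" else float(r.pfss),
    ) for r in df.itertuples(index=False)]


def write_gamma_table(gamma: GammaTable, path: str | Path) -> None:
    pd.DataFrame(
        [(m, d, repr(g)) for (m, d), g in sorted(gamma.items())],
        columns=GAMMA_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_gamma_table(path: str | Path) -> GammaTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GAMMA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gamma table ({path}): missing column(s): {', '.join(missing)}")
    return {(r.sf_model_id, r.domain_id): float(r.gamma) for r in df.itertuples(index=False)}


def write_per_domain_table(per_domain: Mapping[str, Mapping[str, float]],
                           path: str | Path) -> None:
    pd.DataFrame(
        [(g, d, repr(v)) for g in sorted(per_domain) for d, v in sorted(per_domain[g].items())],
        columns=PER_DOMAIN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_per_domain_table(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PER_DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"per-domain table ({path}): missing column(s): {', '.join(missing)}")
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.group_name, {})[r.domain_id] = float(r.gpfss)
    return out


def write_group_table(assessments: Mapping[str, GroupAssessment], path: str | Path) -> None:
    pd.DataFrame(
        [(a.group_name, repr(a.gpfss), repr(a.gpfss_sd), repr(a.cumpfss), a.n_domains)
         for _, a in sorted(assessments.items())],
        columns=GROUP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_group_table(path: str | Path) -> dict[str, GroupAssessment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"group table ({path}): missing column(s): {', '.join(missing)}")
    out = {}
    for r in df.itertuples(index=False):
        out[r.group_name] = GroupAssessment(
            group_name=r.group_name, per_domain_gpfss={},
            gpfss=float(r.gpfss), gpfss_sd=float(r.gpfss_sd),
            cumpfss=float(r.cumpfss), n_domains=int(r.n_domains))
    return out
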