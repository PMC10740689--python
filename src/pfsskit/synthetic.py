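"""Synthetic benchmarking campaigns (fully simulated, no real CASP data).

Generates every table the pipeline consumes — per-SeqFEATURE-model
calibrations, reference-structure hit tables, per-group model-side score
tables, and standard-metric tables correlated with each group's injected
error — plus a truth record of the injected error scales, so the whole
chain is testable end to end with seeded reproducibility.

The generative model mirrors the real data flow: raw scores are normal per
SeqFEATURE model; the specificity threshold is the 90th percentile of a
simulated background (negative) score sample; reference hits are drawn from
the upper truncated normal above that threshold by inverse-CDF sampling;
each group's model-side raw score is the reference raw score plus Gaussian
noise with standard deviation ``error_scale * sigma`` — noise enters on the
raw-score scale so the calibration chain is exercised end to end.  Synthetic
LDDT/GDT-TS/RMS-CA values are decreasing (increasing for RMS) deterministic
functions of the group's realized mean |Delta p| per domain, plus small
noise.  Default dimensions are about a quarter of a full CASP-scale
campaign (26 domains, 30 groups) to keep desk-scale runtimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import io as tbl
from .errors import SimulationSpecError

__all__ = [
    "GroupSpec", "SyntheticSpec", "SyntheticCampaign",
    "default_groups", "generate_campaign", "write_campaign",
]

# residue/atom vocabulary for synthetic SeqFEATURE model names
_ANCHORS = (("ASP", "OD2"), ("ARG", "NE"), ("HIS", "ND1"), ("CYS", "SG"),
            ("SER", "OG"), ("GLU", "OE1"), ("LYS", "NZ"), ("TRP", "NE1"))

#: category proportions roughly matching a real mixed-difficulty target set
_CATEGORY_P = (0.40, 0.37, 0.12, 0.08, 0.03)

_BACKGROUND_SAMPLE = 2000  # background scores drawn to place the 90% threshold


@dataclass(frozen=True)
class GroupSpec:
    """One simulated modeling group: its injected error level (in units of
    the per-model raw-score SD) and the fraction of domains it models."""

    name: str
    error_scale: float
    coverage_fraction: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Dimensions and conditions of a synthetic campaign."""

    n_sf_models: int = 20
    n_targets: int = 13
    domains_per_target: int = 2
    sites_per_domain: float = 5.0      # Poisson mean, floored at 1
    groups: tuple[GroupSpec, ...] = ()
    seed: int = 0
    metric_noise: float = 0.01         # SD of the noise on synthetic LDDT

    def validate(self) -> None:
        if self.n_sf_models < 1 or self.n_targets < 1 or self.domains_per_target < 1:
            raise SimulationSpecError("model/target/domain counts must be >= 1")
        if not self.sites_per_domain > 0:
            raise SimulationSpecError("sites_per_domain must be > 0")
        if not self.groups:
            raise SimulationSpecError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise SimulationSpecError("group names must be unique")
        for g in self.groups:
            if g.error_scale < 0:
                raise SimulationSpecError(f"error_scale must be >= 0 for {g.name!r}")
            if not 0 < g.coverage_fraction <= 1:
                raise SimulationSpecError(
                    f"coverage_fraction must be in (0, 1] for {g.name!r}")
        if self.metric_noise < 0:
            raise SimulationSpecError("metric_noise must be >= 0")


@dataclass
class SyntheticCampaign:
    """All generated tables plus the truth record of injected error levels."""

    calibration: list[tbl.CalibrationEntry]
    reference_sites: list[tbl.SitePrediction]
    model_sites: list[tbl.SitePrediction]
    domains: list[tbl.DomainDefinition]
    metrics: list[tbl.MetricRecord]
    truth: pd.DataFrame  # group_name, error_scale, coverage_fraction, n_domains


def default_groups(n: int = 30) -> tuple[GroupSpec, ...]:
    """A deterministic spread of groups: error scales log-spaced over
    [0.02, 2.0] (weak to severe perturbation), two thirds with full domain
    coverage and every third group covering 70%."""
    scales = np.geomspace(0.02, 2.0, n)
    return tuple(
        GroupSpec(name=f"group{i:02d}", error_scale=float(scales[i]),
                  coverage_fraction=1.0 if i % 3 != 2 else 0.7)
        for i in range(n))


def generate_campaign(spec: SyntheticSpec) -> SyntheticCampaign:
    """Generate one complete campaign; identical spec + seed gives identical
    tables."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- SeqFEATURE model calibrations -----------------------------------
    calibration: list[tbl.CalibrationEntry] = []
    anchor_of: dict[str, str] = {}
    for i in range(spec.n_sf_models):
        res, atom = _ANCHORS[i % len(_ANCHORS)]
        name = f"SYN{i:03d}.{res}.{atom}"
        mu = float(rng.uniform(-20.0, 80.0))
        sigma = float(rng.uniform(4.0, 20.0))
        background = rng.normal(mu, sigma, _BACKGROUND_SAMPLE)
        z_threshold = float(np.quantile((background - mu) / sigma, 0.90))
        calibration.append(tbl.CalibrationEntry(name, mu, sigma, z_threshold))
        anchor_of[name] = atom
    cal_by_name = {c.sf_model_id: c for c in calibration}

    # --- targets, domains, residue ranges --------------------------------
    domains: list[tbl.DomainDefinition] = []
    for t in range(spec.n_targets):
        target = f"SYNT{t:04d}"
        cursor = int(rng.integers(1, 40))
        for j in range(spec.domains_per_target):
            if rng.random() < 0.3:  # discontinuous domain: two segments
                gap = int(rng.integers(5, 20))
                ranges = ((cursor, cursor + 29), (cursor + 30 + gap, cursor + 59 + gap))
                cursor = cursor + 60 + gap + int(rng.integers(3, 15))
            else:
                ranges = ((cursor, cursor + 59),)
                cursor = cursor + 60 + int(rng.integers(3, 15))
            category = str(rng.choice(tbl.CATEGORIES, p=_CATEGORY_P))
            domains.append(tbl.DomainDefinition(
                target_id=target, domain_id=f"{target}-D{j + 1}",
                ranges=ranges, category=category))

    # --- reference hit sites (truncated normal above threshold) ----------
    reference_sites: list[tbl.SitePrediction] = []
    sites_by_domain: dict[str, list[tbl.SitePrediction]] = {}
    for domain in domains:
        residues = sorted(tbl.residues_in_domain(domain))
        n_sites = max(1, int(rng.poisson(spec.sites_per_domain)))
        n_sites = min(n_sites, len(residues))
        chosen = sorted(int(r) for r in rng.choice(residues, n_sites, replace=False))
        for residue in chosen:
            cal = calibration[int(rng.integers(spec.n_sf_models))]
            u = rng.uniform(ndtr(cal.z_threshold), 1.0)
            z = float(ndtri(u))
            site = tbl.SitePrediction(
                structure_id=domain.target_id,
                sf_model_id=cal.sf_model_id,
                chain="A",
                residue_number=residue,
                anchor_atom=anchor_of[cal.sf_model_id],
                raw_score=cal.mu + z * cal.sigma,
            )
            reference_sites.append(site)
            sites_by_domain.setdefault(domain.domain_id, []).append(site)

    # --- per-group model-side scores and correlated metrics --------------
    n_domains = len(domains)
    model_sites: list[tbl.SitePrediction] = []
    metrics: list[tbl.MetricRecord] = []
    truth_rows = []
    for group in spec.groups:
        k = max(1, round(group.coverage_fraction * n_domains))
        covered_idx = sorted(int(i) for i in rng.choice(n_domains, k, replace=False))
        for idx in covered_idx:
            domain = domains[idx]
            dp_values = []
            for ref in sites_by_domain.get(domain.domain_id, []):
                cal = cal_by_name[ref.sf_model_id]
                noise = rng.normal(0.0, group.error_scale * cal.sigma)
                raw_model = ref.raw_score + noise
                model_sites.append(tbl.SitePrediction(
                    structure_id=tbl.make_model_structure_id(
                        domain.target_id, group.name, 1),
                    sf_model_id=ref.sf_model_id,
                    chain=ref.chain,
                    residue_number=ref.residue_number,
                    anchor_atom=ref.anchor_atom,
                    raw_score=raw_model,
                ))
                p_ref = ndtr((ref.raw_score - cal.mu) / cal.sigma)
                p_model = ndtr((raw_model - cal.mu) / cal.sigma)
                dp_values.append(abs(p_ref - p_model))
            dp_mean = float(np.mean(dp_values)) if dp_values else 0.0
            eps = float(rng.normal(0.0, spec.metric_noise))
            lddt = float(np.clip(0.95 - 0.85 * dp_mean + eps, 0.0, 1.0))
            gdt_ts = float(np.clip(95.0 - 90.0 * dp_mean + 100.0 * eps, 0.0, 100.0))
            rms_ca = max(0.1, 0.5 + 10.0 * dp_mean - 5.0 * eps)
            for metric_name, value in (("LDDT", lddt), ("GDT-TS", gdt_ts),
                                       ("RMS-CA", rms_ca)):
                metrics.append(tbl.MetricRecord(
                    group_name=group.name, domain_id=domain.domain_id,
                    metric_name=metric_name, value=value))
        truth_rows.append((group.name, group.error_scale,
                           group.coverage_fraction, len(covered_idx)))

    truth = pd.DataFrame(truth_rows, columns=[
        "group_name", "error_scale", "coverage_fraction", "n_domains"])
    return SyntheticCampaign(
        calibration=calibration,
        reference_sites=reference_sites,
        model_sites=model_sites,
        domains=domains,
        metrics=metrics,
        truth=truth,
    )


def write_campaign(campaign: SyntheticCampaign, outdir: str | Path) -> dict[str, Path]:
    """Write all campaign tables under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calibration": outdir / "calibration.tsv",
        "reference_sites": outdir / "reference_sites.tsv",
        "model_sites": outdir / "model_sites.tsv",
        "domains": outdir / "domains.tsv",
        "metrics": outdir / "metrics.tsv",
        "truth": outdir / "truth.tsv",
    }
    tbl.write_calibration_table(campaign.calibration, paths["calibration"])
    tbl.write_site_table(campaign.reference_sites, paths["reference_sites"])
    tbl.write_site_table(campaign.model_sites, paths["model_sites"])
    tbl.write_domain_table(campaign.domains, paths["domains"])
    tbl.write_metric_table(campaign.metrics, paths["metrics"])
    campaign.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
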