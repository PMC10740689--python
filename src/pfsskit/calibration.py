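"""Raw score -> Z-score -> cumulative probability, and the reference-side
specificity filter.

Raw microenvironment scores are assumed normally distributed per SeqFEATURE
model; with the per-model (mu, sigma) from the calibration table a raw score
becomes a Z-score, and the standard normal CDF turns the Z-score into a
cumulative probability in [0, 1].  Reference-structure predictions enter an
analysis only when their Z-score is strictly greater than the per-model
threshold set at >=90% specificity; model-side predictions at the matched
sites are kept regardless of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.special import ndtr

from .errors import CalibrationError, DomainValueError, UnknownModelError
from .io import CalibrationEntry, SitePrediction

__all__ = [
    "SiteProbability",
    "compute_z",
    "z_to_probability",
    "score_site",
    "score_sites",
    "filter_reference_sites",
]


@dataclass(frozen=True)
class SiteProbability:
    """A site prediction with its Z-score and cumulative probability."""

    site: SitePrediction
    z: float
    p: float


def compute_z(raw: float, cal: CalibrationEntry) -> float:
    """Standardize a raw score: ``(raw - mu) / sigma``."""
    if not cal.sigma > 0:
        raise CalibrationError(
            f"sigma must be > 0 for {cal.sf_model_id!r}, got {cal.sigma}")
    return (raw - cal.mu) / cal.sigma


def z_to_probability(z: float) -> float:
    """Cumulative probability of a Z-score under the standard normal CDF."""
    if not math.isfinite(z):
        raise DomainValueError(f"Z-score must be finite, got {z}")
    return float(ndtr(z))


def score_site(site: SitePrediction, cal_index: Mapping[str, CalibrationEntry]) -> SiteProbability:
    """Attach Z-score and cumulative probability to one site prediction."""
    try:
        cal = cal_index[site.sf_model_id]
    except KeyError:
        raise UnknownModelError(
            f"no calibration entry for SeqFEATURE model {site.sf_model_id!r}") from None
    z = compute_z(site.raw_score, cal)
    return SiteProbability(site=site, z=z, p=z_to_probability(z))


def score_sites(sites: Iterable[SitePrediction],
                cal_index: Mapping[str, CalibrationEntry]) -> list[SiteProbability]:
    """Score every site; raises :class:`UnknownModelError` naming any
    SeqFEATURE model absent from the calibration table."""
    return [score_site(site, cal_index) for site in sites]


def filter_reference_sites(sites: Iterable[SiteProbability],
                           cal_index: Mapping[str, CalibrationEntry]) -> list[SiteProbability]:
    """Keep exactly the sites whose Z-score is strictly above their model's
    specificity threshold, preserving order.

    Applies to reference structures only: this is the inclusion criterion for
    the study, and the matched model-side predictions are never filtered.
    Ties at exactly the threshold are excluded.  Idempotent.
    """
    kept = []
    for sp in sites:
        try:
            cal = cal_index[sp.site.sf_model_id]
        except KeyError:
            raise UnknownModelError(
                f"no calibration entry for SeqFEATURE model {sp.site.sf_model_id!r}") from None
        if sp.z > cal.z_threshold:
            kept.append(sp)
    return kept
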