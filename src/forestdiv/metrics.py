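"""Paired managed-vs-reference community metrics.

Four metrics are computed per study and management system from the
site-averaged communities:

* **Intactness (IN)** — mean species abundance: the managed/reference
  abundance ratio per reference species, truncated at 1, averaged over the
  reference species.  Species found only in managed sites are removed before
  the ratio is taken; a reference species missing from the managed community
  contributes a ratio of 0.  IN = 1 means every reference species is at least
  as abundant under management; IN = 0 means none persists.
* **Compositional similarity (SI)** — Sørensen index 2T/(2T+F) on
  presence/absence, where T counts species shared by both communities and F
  counts species unique to either side.
* **Relative species richness (SR)** — ln(S_managed / S_reference).
* **Relative total abundance (TA)** — ln(sum of managed abundances / sum of
  reference abundances), with managed-only species included in the numerator.

IN and SI live in [0, 1]; SR and TA are log-response ratios centred on 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import StudyCommunity

logger = logging.getLogger(__name__)

METRIC_NAMES = ("IN", "SI", "SR", "TA")


class EmptyReferenceError(ValueError):
    """Metrics are undefined against an empty reference community."""


@dataclass
class CommunityComparison:
    """Species-level bookkeeping for one managed-vs-reference pair.

    ``ratios`` holds the truncated abundance ratio min(A_m/A_r, 1) for every
    reference species (0 when the species is absent from the managed
    community).  Managed-only species are excluded from ``ratios`` but are
    counted in ``n_man``/``n_diff`` and summed into ``total_man``.
    """

    study_id: str
    source_id: str
    system: str
    ratios: dict[str, float]
    n_ref: int
    n_man: int
    n_shared: int
    n_diff: int
    total_man: float
    total_ref: float


@dataclass
class MetricRecord:
    """The four metric values plus model weight for one study x system."""

    study_id: str
    source_id: str
    system: str
    IN: float
    SI: float
    SR: float | None
    TA: float | None
    n_ref: int
    weight: float
    taxon_group: str | None = None
    continent: str | None = None
    time_since_years: float | None = None


def compare_communities(
    managed: StudyCommunity, reference: StudyCommunity
) -> CommunityComparison:
    """Tabulate abundance ratios, overlap counts and totals for one pair."""
    ref = reference.species_mean_abundance
    man = managed.species_mean_abundance
    if not ref:
        raise EmptyReferenceError(
            f"study {reference.study_id}: empty reference community"
        )
    # reference-side zeros cannot occur: a species with zero mean abundance
    # was never detected and is not "found in reference sites"
    bad = [s for s, a in ref.items() if a <= 0]
    if bad:
        raise ValueError(f"reference species with non-positive abundance: {bad[:5]}")

    ratios = {s: min(man.get(s, 0.0) / a_r, 1.0) for s, a_r in ref.items()}
    shared = [s for s in ref if man.get(s, 0.0) > 0]
    man_species = [s for s, a in man.items() if a > 0]
    n_ref, n_man, n_shared = len(ref), len(man_species), len(shared)
    n_diff = n_ref + n_man - 2 * n_shared
    return CommunityComparison(
        study_id=managed.study_id,
        source_id=managed.source_id,
        system=managed.system,
        ratios=ratios,
        n_ref=n_ref,
        n_man=n_man,
        n_shared=n_shared,
        n_diff=n_diff,
        total_man=float(sum(man.values())),
        total_ref=float(sum(ref.values())),
    )


def intactness(cmp: CommunityComparison) -> float:
    """Mean truncated abundance ratio over reference species (IN, in [0, 1])."""
    if cmp.n_ref < 1:
        raise EmptyReferenceError("intactness undefined for empty reference")
    return float(sum(cmp.ratios.values()) / cmp.n_ref)


def sorensen_similarity(cmp: CommunityComparison) -> float:
    """Sørensen index 2T/(2T+F) on species overlap (SI, in [0, 1])."""
    t, f = cmp.n_shared, cmp.n_diff
    if t + f < 1:
        raise ValueError("similarity undefined: both communities empty")
    return 2.0 * t / (2.0 * t + f)


def relative_richness(cmp: CommunityComparison) -> float | None:
    """ln(managed richness / reference richness) (SR); None when undefined."""
    if cmp.n_man < 1 or cmp.n_ref < 1:
        logger.warning(
            "study %s system %s: zero richness, SR excluded", cmp.study_id, cmp.system
        )
        return None
    return math.log(cmp.n_man / cmp.n_ref)


def relative_abundance(cmp: CommunityComparison) -> float | None:
    """ln(summed managed / summed reference abundance) (TA); None when undefined."""
    if cmp.total_man <= 0 or cmp.total_ref <= 0:
        logger.warning(
            "study %s system %s: zero total abundance, TA excluded",
            cmp.study_id,
            cmp.system,
        )
        return None
    return math.log(cmp.total_man / cmp.total_ref)


def compute_all_metrics(
    communities: list[StudyCommunity],
    *,
    exclusion_log: list[dict] | None = None,
) -> list[MetricRecord]:
    """One MetricRecord per (study, managed system) with a paired reference.

    The study weight is sqrt(number of reference species); per-metric
    exclusions (zero richness or totals) yield missing SR/TA rather than
    aborting the batch.
    """
    from .transforms import study_weight

    by_study: dict[tuple[str, str], dict[str, StudyCommunity]] = {}
    for c in communities:
        by_study.setdefault((c.source_id, c.study_id), {})[c.system] = c

    records: list[MetricRecord] = []
    for (source_id, study_id), systems in sorted(by_study.items()):
        reference = systems.get("REFERENCE")
        if reference is None:
            logger.warning("study %s/%s lacks reference community", source_id, study_id)
            if exclusion_log is not None:
                exclusion_log.append(
                    {"source_id": source_id, "study_id": study_id, "reason": "no_reference_community"}
                )
            continue
        for system, managed in sorted(systems.items()):
            if system == "REFERENCE":
                continue
            cmp = compare_communities(managed, reference)
            records.append(
                MetricRecord(
                    study_id=study_id,
                    source_id=source_id,
                    system=system,
                    IN=intactness(cmp),
                    SI=sorensen_similarity(cmp),
                    SR=relative_richness(cmp),
                    TA=relative_abundance(cmp),
                    n_ref=cmp.n_ref,
                    weight=study_weight(cmp.n_ref),
                    taxon_group=managed.taxon_group,
                    continent=managed.continent,
                    time_since_years=managed.time_since_years,
                )
            )
    return records


def metrics_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy metric table: one row per study x system."""
    return pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "source_id": r.source_id,
                "system": r.system,
                "IN": r.IN,
                "SI": r.SI,
                "SR": r.SR,
                "TA": r.TA,
                "n_ref": r.n_ref,
                "weight": r.weight,
                "taxon_group": r.taxon_group,
                "continent": r.continent,
                "time_since_years": r.time_since_years,
            }
            for r in records
        ]
    )


def metric_correlations(metrics: pd.DataFrame | list[MetricRecord]):
    """Spearman correlation matrix and PCA summary of the four metrics.

    Returns ``(rho, pca)`` where ``rho`` is the 4x4 Spearman matrix over
    complete rows and ``pca`` is a dict with standardized-matrix component
    ``loadings`` (columns = components) and ``explained_variance`` (summing
    to the total variance of the standardized metrics).
    """
    from scipy import stats

    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_to_frame(metrics)
    x = df[list(METRIC_NAMES)].dropna()
    if len(x) < 3:
        raise ValueError(f"need >=3 complete metric rows, got {len(x)}")
    rho = pd.DataFrame(
        stats.spearmanr(x.to_numpy()).statistic,
        index=METRIC_NAMES,
        columns=METRIC_NAMES,
    )
    z = (x - x.mean()) / x.std(ddof=1)
    cov = np.cov(z.to_numpy().T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    pca = {
        "loadings": pd.DataFrame(
            evecs[:, order],
            index=METRIC_NAMES,
            columns=[f"PC{i+1}" for i in range(len(order))],
        ),
        "explained_variance": evals[order],
    }
    return rho, pca
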