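"""Gene-neighborhood co-occurrence screen for PTDR-dnd association.

A PT-dependent restriction endonuclease that cleaves the same modified
sequence its host's dnd cluster writes would self-restrict, so PTDR genes
are expected to be rare in the immediate vicinity of dnd modification
genes.  This module implements the screen over pre-built neighborhood
tables: coverage filtering of homology hits, a gene-index proximity scan,
and the flagged-fraction estimate with an exact binomial interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .core import InputError
from .simulate import DND_LABELS, NeighborhoodTable

__all__ = [
    "HitRecord",
    "ProximityResult",
    "CooccurrenceEstimate",
    "filter_hits",
    "proximity_scan",
    "cooccurrence_fraction",
]


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit with its query coverage."""

    hit_id: str
    query_coverage: float
    genome_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise InputError(f"{self.hit_id}: coverage {self.query_coverage} outside [0,1]")


@dataclass(frozen=True)
class ProximityResult:
    genome_id: str
    min_separation: float  # gene-count distance; adjacent = 1; inf if no partner
    flagged: bool


@dataclass(frozen=True)
class CooccurrenceEstimate:
    fraction: float
    n_flagged: int
    n_total: int
    ci_low: float
    ci_high: float


def filter_hits(hits: Iterable[HitRecord], min_coverage: float = 0.90) -> list[HitRecord]:
    """Retain hits with query coverage strictly above ``min_coverage``.

    The inequality is strict ("coverage above 90%"), so a hit at exactly
    the threshold is dropped.
    """
    return [h for h in hits if h.query_coverage > min_coverage]


def proximity_scan(
    table: NeighborhoodTable,
    focal_label: str = "ptdr",
    partner_labels: Sequence[str] = DND_LABELS,
    max_sep: int = 4,
) -> ProximityResult:
    """Distance (in genes) from the focal gene to the nearest partner gene.

    ``min_separation`` is the minimum absolute gene-index difference over
    all partner-labeled genes (adjacent genes are 1 apart); the genome is
    flagged when it is strictly below ``max_sep`` ("less than four genes
    apart" at the default).  Raises InputError unless the table holds
    exactly one focal gene.
    """
    focal = [i for i, lab, _ in table.genes if lab == focal_label]
    if len(focal) != 1:
        raise InputError(
            f"{table.genome_id}: expected exactly one {focal_label!r} gene, found {len(focal)}"
        )
    partners = set(partner_labels)
    seps = [abs(i - focal[0]) for i, lab, _ in table.genes if lab in partners]
    min_sep = min(seps) if seps else math.inf
    return ProximityResult(table.genome_id, min_sep, min_sep < max_sep)


def cooccurrence_fraction(results: Sequence[ProximityResult]) -> CooccurrenceEstimate:
    """Flagged fraction with a 95% exact (Clopper-Pearson) binomial CI."""
    if not results:
        raise InputError("no proximity results supplied")
    k = sum(r.flagged for r in results)
    n = len(results)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return CooccurrenceEstimate(k / n, k, n, float(lo), float(hi))
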