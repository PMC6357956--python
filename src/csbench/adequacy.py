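"""Site adequacy analysis: benchmarking caesarean provision by indication.

For each site, the indication-specific caesarean prevalence (caesareans for
one life-saving indication over *all* deliveries in the catchment, home
births included) is compared against literature reference bands.  A site is
adequately served for an indication when its prevalence is at or above the
25th percentile of the literature; prevalence above the 75th percentile
flags likely over-use.  Comparisons with band thresholds are inclusive
("at or above"), with a small relative tolerance so that a prevalence
constructed to equal a threshold exactly is classified at it.

The per-site report also decomposes the caesareans into life-saving versus
other indications and, across a collection of sites, derives the minimum
overall caesarean prevalence that still covers the life-saving minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .bands import PERCENTILE_KEYS, ReferenceBandTable
from .errors import AnalysisError
from .prevalence import PrevalenceEstimate
from .registry import SiteSummary
from .taxonomy import ALL_INDICATIONS, LIFE_SAVING_INDICATIONS, IndicationCategory

Classification = str  # "below_minimum" | "acceptable" | "above_maximum"


def _at_or_above(prevalence: float, threshold: float) -> bool:
    # inclusive comparison, robust to float rounding of exact-threshold inputs
    return prevalence > threshold or math.isclose(
        prevalence, threshold, rel_tol=1e-9, abs_tol=1e-12
    )


def site_indication_prevalence(
    summary: SiteSummary, indication: IndicationCategory
) -> PrevalenceEstimate:
    """Specific caesarean prevalence of one indication at one site.

    The denominator is the site's total deliveries (the whole catchment
    population), never facility deliveries only.
    """
    if summary.total_deliveries <= 0:
        raise AnalysisError(f"{summary.site_id}: site has zero total deliveries")
    return PrevalenceEstimate(
        numerator=summary.count(indication), denominator=summary.total_deliveries
    )


@dataclass(frozen=True)
class BandStatus:
    """Where one indication's prevalence sits relative to its reference band."""

    indication: IndicationCategory
    prevalence: PrevalenceEstimate
    at_or_above: Mapping[str, bool]

    @property
    def classification(self) -> Classification:
        if not self.at_or_above["p25"]:
            return "below_minimum"
        if self.at_or_above["p75"]:
            return "above_maximum"
        return "acceptable"


@dataclass(frozen=True)
class AdequacyReport:
    """Full per-site benchmarking result."""

    site_id: str
    overall_cs: PrevalenceEstimate
    statuses: tuple[BandStatus, ...]
    life_saving: PrevalenceEstimate
    other: PrevalenceEstimate
    shares_of_cs: Mapping[IndicationCategory, float]

    @property
    def counts_at_or_above(self) -> dict[str, int]:
        return {
            q: sum(1 for s in self.statuses if s.at_or_above[q]) for q in PERCENTILE_KEYS
        }

    def to_dict(self) -> dict:
        """JSON-serialisable nested representation."""
        return {
            "site_id": self.site_id,
            "overall_cs": {
                "numerator": self.overall_cs.numerator,
                "denominator": self.overall_cs.denominator,
                "proportion": self.overall_cs.proportion,
            },
            "life_saving": {
                "count": self.life_saving.numerator,
                "proportion": self.life_saving.proportion,
            },
            "other": {
                "count": self.other.numerator,
                "proportion": self.other.proportion,
            },
            "counts_at_or_above": self.counts_at_or_above,
            "indications": {
                s.indication.value: {
                    "count": s.prevalence.numerator,
                    "prevalence": s.prevalence.proportion,
                    "at_or_above": dict(s.at_or_above),
                    "classification": s.classification,
                }
                for s in self.statuses
            },
            "shares_of_cs": {cat.value: p for cat, p in self.shares_of_cs.items()},
        }


def life_saving_totals(summary: SiteSummary) -> tuple[int, PrevalenceEstimate]:
    """Total caesareans for the six life-saving indications and their prevalence."""
    count = summary.life_saving_total
    return count, PrevalenceEstimate(numerator=count, denominator=summary.total_deliveries)


def cs_share(summary: SiteSummary, indication: IndicationCategory) -> float:
    """Share of a site's caesarean *procedures* done for one indication.

    The denominator here is the number of caesareans, not deliveries.
    """
    if summary.caesarean_total <= 0:
        raise AnalysisError(f"{summary.site_id}: site has no caesarean sections")
    return summary.count(indication) / summary.caesarean_total


def classify_site(summary: SiteSummary, bands: ReferenceBandTable) -> AdequacyReport:
    """Benchmark one site's indication-specific prevalences against the bands.

    Sites with zero caesareans yield a full report with every indication
    below its minimum, not an error: under-provision is the central case of
    interest.
    """
    statuses = []
    for cat in LIFE_SAVING_INDICATIONS:
        prev = site_indication_prevalence(summary, cat)
        at_or_above = {
            q: _at_or_above(prev.proportion, bands.bands[cat][q]) for q in PERCENTILE_KEYS
        }
        statuses.append(BandStatus(indication=cat, prevalence=prev, at_or_above=at_or_above))
    ls_count, ls_prev = life_saving_totals(summary)
    other_prev = PrevalenceEstimate(
        numerator=summary.caesarean_total - ls_count,
        denominator=summary.total_deliveries,
    )
    if summary.caesarean_total > 0:
        shares = {cat: cs_share(summary, cat) for cat in ALL_INDICATIONS}
    else:
        shares = {}
    return AdequacyReport(
        site_id=summary.site_id,
        overall_cs=PrevalenceEstimate(
            numerator=summary.caesarean_total, denominator=summary.total_deliveries
        ),
        statuses=tuple(statuses),
        life_saving=ls_prev,
        other=other_prev,
        shares_of_cs=shares,
    )


def reports_to_frame(reports: Iterable[AdequacyReport]) -> "pd.DataFrame":
    """Flat per-site table: overall rate, per-indication counts and
    prevalences, life-saving/other split, and counts at or above each
    percentile level."""
    import pandas as pd

    rows = []
    for r in reports:
        row: dict = {
            "site_id": r.site_id,
            "total_deliveries": r.overall_cs.denominator,
            "caesarean_total": r.overall_cs.numerator,
            "caesarean_rate": r.overall_cs.proportion,
        }
        for s in r.statuses:
            row[f"{s.indication.value}_n"] = s.prevalence.numerator
            row[f"{s.indication.value}_prevalence"] = s.prevalence.proportion
        row["life_saving_n"] = r.life_saving.numerator
        row["life_saving_prevalence"] = r.life_saving.proportion
        row["other_n"] = r.other.numerator
        row["other_prevalence"] = r.other.proportion
        for q, n in r.counts_at_or_above.items():
            row[f"n_at_or_above_{q}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def band_sum_minimum(bands: ReferenceBandTable) -> float:
    """Floor on overall caesarean prevalence implied by the band minima.

    Summing the 25th-percentile prevalence of each life-saving indication
    gives the smallest overall caesarean proportion at which every
    life-saving minimum could simultaneously be met.
    """
    return bands.total_band["p25"]


def minimum_adequate_cs_rate(
    reports: Iterable[AdequacyReport], min_indications: int = 3
) -> PrevalenceEstimate:
    """Smallest overall caesarean prevalence among adequately-serving sites.

    A site qualifies when at least ``min_indications`` of its six
    life-saving indications are at or above their 25th-percentile minima.
    The default of 3 reflects that covering half the life-saving indications
    marks the transition between clearly under-served populations and those
    approaching adequate provision; it is an explicit, adjustable parameter.
    """
    qualifying = [r for r in reports if r.counts_at_or_above["p25"] >= min_indications]
    if not qualifying:
        raise AnalysisError(
            f"no site met at least {min_indications} indication minima at the 25th percentile"
        )
    best = min(qualifying, key=lambda r: r.overall_cs.proportion)
    return best.overall_cs
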