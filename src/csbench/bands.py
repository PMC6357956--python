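"""Percentile reference bands for indication-specific caesarean prevalence.

A *reference band* for a life-saving indication is the set of 10th, 25th,
50th and 75th percentiles of the indication-specific caesarean prevalence
(caesareans for that indication over all deliveries) across published
studies.  The 25th-75th band defines the acceptable range: below the 25th
percentile a population is assumed to be under-served for that indication,
above the 75th over-served.

Bands can be built from a table of literature studies (:func:`build_bands`)
or taken from the bundled values of the published 20-study literature review
(:func:`literature_bands`), which is the reference used by all benchmarking
against the MNHR sites.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParseError, ValidationError
from .prevalence import PrevalenceEstimate
from .taxonomy import LIFE_SAVING_INDICATIONS, IndicationCategory

PERCENTILE_KEYS = ("p10", "p25", "p50", "p75")
PERCENTILE_LEVELS = {"p10": 0.10, "p25": 0.25, "p50": 0.50, "p75": 0.75}


def study_specific_prevalence(
    caesarean_count: int, total_deliveries: int
) -> PrevalenceEstimate:
    """Specific caesarean prevalence of one indication in one study.

    Defined as the number of caesarean sections performed for the indication
    divided by the total number of deliveries in the study population.  For
    example a study of 24 157 deliveries with 178 caesareans for severe
    pre-eclampsia/eclampsia has a specific prevalence of 0.00737, displayed
    as "1%" at integer precision.
    """
    return PrevalenceEstimate(numerator=caesarean_count, denominator=total_deliveries)


def compute_percentiles(
    values: Sequence[float], levels: Sequence[float]
) -> list[float]:
    """Percentiles of ``values`` by linear interpolation of order statistics.

    The k-th of n sorted values sits at probability (k-1)/(n-1); requested
    levels between adjacent order statistics are linearly interpolated.
    """
    if len(values) == 0:
        raise AnalysisError("cannot compute percentiles of an empty list")
    levels = list(levels)
    if any(not 0.0 <= q <= 1.0 for q in levels):
        raise AnalysisError("percentile levels must lie in [0, 1]")
    return [float(v) for v in np.quantile(np.asarray(values, dtype=float), levels)]


@dataclass(frozen=True)
class LiteratureStudy:
    """One published study contributing indication-specific prevalences.

    Studies report different subsets of indications.  Counts (with the
    study's total deliveries) take precedence; a directly extracted
    proportion is used where no count is available.
    """

    study_id: str
    total_deliveries: int | None = None
    caesarean_counts: Mapping[IndicationCategory, int] = field(default_factory=dict)
    proportions: Mapping[IndicationCategory, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, n in self.caesarean_counts.items():
            if n < 0:
                raise ValidationError(f"{self.study_id}: negative count for {cat.value}")
            if self.total_deliveries is None:
                raise ValidationError(
                    f"{self.study_id}: counts given without total_deliveries"
                )
            if n > self.total_deliveries:
                raise ValidationError(
                    f"{self.study_id}: count for {cat.value} exceeds total deliveries"
                )
        for cat, p in self.proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"{self.study_id}: proportion for {cat.value} outside [0, 1]"
                )

    def prevalence(self, indication: IndicationCategory) -> float | None:
        """Specific prevalence for ``indication``, or None if not reported."""
        if indication in self.caesarean_counts:
            return study_specific_prevalence(
                self.caesarean_counts[indication], self.total_deliveries
            ).proportion
        if indication in self.proportions:
            return float(self.proportions[indication])
        return None


@dataclass(frozen=True)
class ReferenceBandTable:
    """Reference percentiles per life-saving indication, as proportions.

    ``bands`` maps each of the six life-saving indications to its
    p10/p25/p50/p75 values; ``total_band`` is the column-wise sum over the
    six indications and bounds the overall caesarean prevalence attributable
    to life-saving need.
    """

    bands: Mapping[IndicationCategory, Mapping[str, float]]
    n_studies: Mapping[IndicationCategory, int] | None = None

    def __post_init__(self) -> None:
        for cat in LIFE_SAVING_INDICATIONS:
            if cat not in self.bands:
                raise ValidationError(f"missing band for {cat.value}")
            band = self.bands[cat]
            values = [band[k] for k in PERCENTILE_KEYS]
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ValidationError(f"{cat.value}: band values outside [0, 1]")
            if any(a > b + 1e-12 for a, b in zip(values, values[1:])):
                raise ValidationError(
                    f"{cat.value}: band percentiles are not non-decreasing"
                )

    @property
    def total_band(self) -> dict[str, float]:
        return {
            q: sum(self.bands[cat][q] for cat in LIFE_SAVING_INDICATIONS)
            for q in PERCENTILE_KEYS
        }

    def to_frame(self) -> pd.DataFrame:
        """Band table as a DataFrame (proportions), one row per indication plus total."""
        rows = {cat.value: dict(self.bands[cat]) for cat in LIFE_SAVING_INDICATIONS}
        rows["total"] = self.total_band
        return pd.DataFrame.from_dict(rows, orient="index")[list(PERCENTILE_KEYS)]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("indication").to_csv(path, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceBandTable":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        bands: dict[IndicationCategory, dict[str, float]] = {}
        for i, row in enumerate(rows, start=2):
            label = row.get("indication", "")
            if label == "total":
                continue
            try:
                cat = IndicationCategory(label)
            except ValueError:
                raise ParseError(f"row {i}: unknown indication label {label!r}") from None
            try:
                bands[cat] = {q: float(row[q]) for q in PERCENTILE_KEYS}
            except (KeyError, TypeError, ValueError):
                raise ParseError(f"row {i}: malformed percentile values") from None
        return cls(bands=bands)


def build_bands(studies: Iterable[LiteratureStudy]) -> ReferenceBandTable:
    """Build a reference band table from a collection of literature studies.

    Per indication, percentiles are taken over the specific prevalences of
    the studies that report it (studies are weighted equally).  Every
    life-saving indication must be reported by at least one study.
    """
    studies = list(studies)
    bands: dict[IndicationCategory, dict[str, float]] = {}
    n_studies: dict[IndicationCategory, int] = {}
    for cat in LIFE_SAVING_INDICATIONS:
        values = [p for s in studies if (p := s.prevalence(cat)) is not None]
        if not values:
            raise AnalysisError(f"no study reports indication {cat.value}")
        percentiles = compute_percentiles(values, [PERCENTILE_LEVELS[q] for q in PERCENTILE_KEYS])
        bands[cat] = dict(zip(PERCENTILE_KEYS, percentiles))
        n_studies[cat] = len(values)
    return ReferenceBandTable(bands=bands, n_studies=n_studies)


# Bundled bands from the published literature review of 20 studies
# (values as published: p10/p50 at one-decimal percent precision, p25/p75 at
# two decimals; stored as proportions).  The per-study prevalences behind
# them were never published, so these printed percentiles — not a
# recomputation — are the reference for all site benchmarking.
_LITERATURE_BANDS_PERCENT = {
    IndicationCategory.CORD_PROLAPSE_FETAL_DISTRESS: (0.1, 0.25, 1.2, 3.30),
    IndicationCategory.MAJOR_ANTEPARTUM_HAEMORRHAGE: (0.2, 0.42, 0.6, 1.58),
    IndicationCategory.OBSTRUCTED_PROLONGED_LABOUR: (0.7, 1.91, 2.5, 4.58),
    IndicationCategory.SEVERE_PREECLAMPSIA_ECLAMPSIA: (0.3, 0.53, 0.8, 1.45),
    IndicationCategory.MALPRESENTATION: (0.3, 1.03, 2.2, 4.35),
    IndicationCategory.UTERINE_RUPTURE: (0.1, 0.20, 0.4, 2.40),
}

_LITERATURE_N_STUDIES = {
    IndicationCategory.CORD_PROLAPSE_FETAL_DISTRESS: 13,
    IndicationCategory.MAJOR_ANTEPARTUM_HAEMORRHAGE: 10,
    IndicationCategory.OBSTRUCTED_PROLONGED_LABOUR: 21,
    IndicationCategory.SEVERE_PREECLAMPSIA_ECLAMPSIA: 15,
    IndicationCategory.MALPRESENTATION: 22,
    IndicationCategory.UTERINE_RUPTURE: 7,
}


def literature_bands() -> ReferenceBandTable:
    """The bundled reference bands from the published literature review.

    The summed 25th/75th percentiles over the six indications are 4.34% and
    17.66%: the floor and ceiling on the overall caesarean prevalence
    attributable to life-saving indications.  (Note: the published p50
    values, printed at one decimal, sum to 7.7% while the review prints a
    7.6% total — unprinted extra precision; the table here reports the sum
    of the printed per-indication values.)
    """
    bands = {
        cat: dict(zip(PERCENTILE_KEYS, (v / 100.0 for v in values)))
        for cat, values in _LITERATURE_BANDS_PERCENT.items()
    }
    return ReferenceBandTable(bands=bands, n_studies=dict(_LITERATURE_N_STUDIES))
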