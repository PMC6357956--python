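"""Bundled site-level data from the Global Network MNHR, 2010-13.

The Maternal and Newborn Health Registry (MNHR) is a prospective,
population-based registry of all pregnancies in defined geographic clusters
at seven research sites in six low- and middle-income countries (Argentina,
Guatemala, two Indian sites, Pakistan, Kenya, Zambia); 271 855 deliveries in
total.  The raw record-level data are not public; what is bundled here are
the published site-level counts: total deliveries, birth-location
breakdowns, caesarean totals, caesareans by indication category, and the
marginal rates of four reported obstetric complications among all
deliveries.

The published indication breakdown is internally inconsistent for two sites
(the twelve per-indication counts do not sum to the printed caesarean
total), whereas the published life-saving/other split sums exactly for every
site.  The summaries returned here are reconciled accordingly: the six
life-saving counts and the overall split are taken at face value, the five
specific non-life-saving categories keep their published counts, and the
heterogeneous ``other`` category absorbs the remainder so that each
summary's indication counts exactly partition its caesareans.
"""

from __future__ import annotations

from .registry import SiteSummary
from .taxonomy import ALL_INDICATIONS, IndicationCategory

I = IndicationCategory

MNHR_SITE_IDS = (
    "argentina",
    "guatemala",
    "nagpur",
    "belgaum",
    "pakistan",
    "kenya",
    "zambia",
)

# site -> (total deliveries, facility deliveries, caesarean total)
_TOTALS = {
    "argentina": (9901, 9813, 3467),
    "guatemala": (30259, 13414, 5576),
    "nagpur": (39250, 37444, 7697),
    "belgaum": (79674, 74514, 11218),
    "pakistan": (49550, 26667, 4632),
    "kenya": (35621, 14851, 550),
    "zambia": (27600, 16764, 303),
}

# Caesarean counts for the six life-saving indications, canonical order:
# cord prolapse/fetal distress, major APH, obstructed/prolonged labour,
# severe pre-eclampsia/eclampsia, malpresentation, uterine rupture.
_LIFE_SAVING_COUNTS = {
    "argentina": (60, 61, 792, 316, 295, 19),
    "guatemala": (364, 57, 1234, 382, 788, 75),
    "nagpur": (504, 64, 3608, 268, 953, 17),
    "belgaum": (307, 175, 5831, 363, 893, 67),
    "pakistan": (222, 183, 2291, 120, 532, 18),
    "kenya": (21, 19, 321, 17, 93, 3),
    "zambia": (8, 67, 2, 9, 36, 3),
}

# Published counts for the specific non-life-saving categories:
# previous caesarean, previous fistula repair, maternal request,
# no clear indication, no data.  "other" is derived (see module docstring).
_SPECIFIC_OTHER_COUNTS = {
    "argentina": (1245, 3, 204, 127, 192),
    "guatemala": (1337, 30, 66, 300, 99),
    "nagpur": (1209, 16, 67, 649, 4),
    "belgaum": (1782, 14, 230, 195, 866),
    "pakistan": (1017, 24, 76, 20, 88),
    "kenya": (59, 0, 1, 2, 3),
    "zambia": (26, 0, 1, 14, 33),
}

_SPECIFIC_OTHER_ORDER = (
    I.PREVIOUS_CAESAREAN,
    I.PREVIOUS_FISTULA_REPAIR,
    I.MATERNAL_REQUEST,
    I.NO_CLEAR_INDICATION,
    I.NO_DATA,
)

# Birth-location counts (hospital, clinic, home/other) per site.
MNHR_LOCATION_COUNTS = {
    "argentina": (9788, 25, 83),
    "guatemala": (12047, 1367, 16844),
    "nagpur": (26635, 10809, 1781),
    "belgaum": (53878, 20636, 5097),
    "pakistan": (14362, 12305, 22821),
    "kenya": (4613, 10238, 20769),
    "zambia": (3435, 13329, 10833),
}

# Reported obstetric complications among all deliveries (counts), per site:
# major APH, obstructed/prolonged labour, severe PE/eclampsia, malpresentation.
MNHR_COMPLICATION_COUNTS = {
    "argentina": (68, 793, 378, 205),
    "guatemala": (504, 2151, 1212, 939),
    "nagpur": (225, 4177, 854, 1100),
    "belgaum": (531, 8218, 1731, 1107),
    "pakistan": (2393, 9943, 3307, 1795),
    "kenya": (837, 3820, 579, 575),
    "zambia": (339, 1174, 242, 281),
}

COMPLICATION_ORDER = (
    I.MAJOR_ANTEPARTUM_HAEMORRHAGE,
    I.OBSTRUCTED_PROLONGED_LABOUR,
    I.SEVERE_PREECLAMPSIA_ECLAMPSIA,
    I.MALPRESENTATION,
)


def mnhr_site_summaries() -> list[SiteSummary]:
    """The seven bundled MNHR site summaries (reconciled; always valid)."""
    summaries = []
    for site in MNHR_SITE_IDS:
        total, facility, cs_total = _TOTALS[site]
        counts: dict[IndicationCategory, int] = dict.fromkeys(ALL_INDICATIONS, 0)
        for cat, n in zip(ALL_INDICATIONS[:6], _LIFE_SAVING_COUNTS[site]):
            counts[cat] = n
        for cat, n in zip(_SPECIFIC_OTHER_ORDER, _SPECIFIC_OTHER_COUNTS[site]):
            counts[cat] = n
        counts[I.OTHER] = cs_total - sum(counts.values())
        summaries.append(
            SiteSummary(
                site_id=site,
                total_deliveries=total,
                facility_deliveries=facility,
                caesarean_total=cs_total,
                indication_counts=counts,
            )
        )
    return summaries
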