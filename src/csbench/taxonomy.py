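"""Indication taxonomy for caesarean section deliveries.

Twelve clinician-assigned indication categories are recognised, of which six
are *life-saving*: conditions for which a caesarean section is assumed
necessary to save the mother's or the fetus's life (cord prolapse or fetal
distress; major antepartum haemorrhage; obstructed or prolonged labour;
severe pre-eclampsia or eclampsia; transverse/oblique lie or breech
presentation; uterine rupture).  The remaining six categories (previous
caesarean, previous fistula repair, maternal request, other, no clear
indication, no data) are retained as distinct labels but all count as
non-life-saving.
"""

from __future__ import annotations

from enum import Enum


class BirthLocation(str, Enum):
    """Where a delivery took place; hospital and clinic are facility births."""

    HOSPITAL = "hospital"
    CLINIC = "clinic"
    HOME_OTHER = "home_other"

    @property
    def is_facility(self) -> bool:
        return self is not BirthLocation.HOME_OTHER


class IndicationCategory(str, Enum):
    """Clinician-defined indication recorded for a caesarean delivery."""

    CORD_PROLAPSE_FETAL_DISTRESS = "cord_prolapse_fetal_distress"
    MAJOR_ANTEPARTUM_HAEMORRHAGE = "major_antepartum_haemorrhage"
    OBSTRUCTED_PROLONGED_LABOUR = "obstructed_prolonged_labour"
    SEVERE_PREECLAMPSIA_ECLAMPSIA = "severe_preeclampsia_eclampsia"
    MALPRESENTATION = "malpresentation"
    UTERINE_RUPTURE = "uterine_rupture"
    PREVIOUS_CAESAREAN = "previous_caesarean"
    PREVIOUS_FISTULA_REPAIR = "previous_fistula_repair"
    MATERNAL_REQUEST = "maternal_request"
    OTHER = "other"
    NO_CLEAR_INDICATION = "no_clear_indication"
    NO_DATA = "no_data"

    @property
    def life_saving(self) -> bool:
        return self in LIFE_SAVING_INDICATIONS


#: The six indications for which a caesarean is assumed life-saving,
#: in canonical reporting order.
LIFE_SAVING_INDICATIONS: tuple[IndicationCategory, ...] = (
    IndicationCategory.CORD_PROLAPSE_FETAL_DISTRESS,
    IndicationCategory.MAJOR_ANTEPARTUM_HAEMORRHAGE,
    IndicationCategory.OBSTRUCTED_PROLONGED_LABOUR,
    IndicationCategory.SEVERE_PREECLAMPSIA_ECLAMPSIA,
    IndicationCategory.MALPRESENTATION,
    IndicationCategory.UTERINE_RUPTURE,
)

#: All twelve categories in canonical reporting order.
ALL_INDICATIONS: tuple[IndicationCategory, ...] = tuple(IndicationCategory)
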