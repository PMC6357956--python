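"""Synthetic delivery-registry generator.

Generates record-level registries with the statistical structure of the
seven MNHR research sites, so the whole analysis pipeline is exercisable
without the (non-public) study data.  Each site is described by a
:class:`SiteProfile`; the bundled :func:`default_profiles` reproduce the
published marginals: total deliveries, birth-location mix, overall
caesarean proportion, the conditional distribution of the twelve indication
categories among caesareans, and the marginal rates of the four reported
obstetric complications among all deliveries.

Sampling is two-stage per delivery: birth location is multinomial; among
facility births a caesarean is a Bernoulli draw with probability
``p_caesarean / P(facility)``, which preserves the configured overall
caesarean proportion in expectation while keeping every caesarean inside a
facility; the indication is then multinomial among caesareans.  A caesarean
whose indication is life-saving always carries the matching complication
flag; all other records draw complication flags independently at background
rates calibrated so the marginal complication rate matches the profile
(clipped at zero where the indication-driven flags alone already reach the
target — the published complication and indication tables are not mutually
consistent everywhere).

One global seed drives everything; each site gets an independent substream
derived from the seed and a hash of the site id, so per-site output does not
depend on the order in which sites are listed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .errors import ConfigurationError
from .registry import DeliveryRecord
from .taxonomy import (
    ALL_INDICATIONS,
    LIFE_SAVING_INDICATIONS,
    BirthLocation,
    IndicationCategory,
)

_LOCATIONS = (BirthLocation.HOSPITAL, BirthLocation.CLINIC, BirthLocation.HOME_OTHER)


@dataclass(frozen=True)
class SiteProfile:
    """Generative parameters for one site."""

    site_id: str
    n_deliveries: int
    p_location: Mapping[BirthLocation, float]
    p_caesarean: float
    indication_distribution: Mapping[IndicationCategory, float]
    complication_rates: Mapping[IndicationCategory, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_deliveries < 0:
            raise ConfigurationError(f"{self.site_id}: negative n_deliveries")
        loc = [self.p_location.get(l, 0.0) for l in _LOCATIONS]
        if any(not 0.0 <= p <= 1.0 for p in loc) or abs(sum(loc) - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.site_id}: p_location must sum to 1")
        if not 0.0 <= self.p_caesarean <= 1.0:
            raise ConfigurationError(f"{self.site_id}: p_caesarean outside [0, 1]")
        dist = [self.indication_distribution.get(c, 0.0) for c in ALL_INDICATIONS]
        if any(not 0.0 <= p <= 1.0 for p in dist):
            raise ConfigurationError(f"{self.site_id}: indication probabilities outside [0, 1]")
        if self.p_caesarean > 0 and abs(sum(dist) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.site_id}: indication_distribution must sum to 1"
            )
        p_facility = loc[0] + loc[1]
        if self.p_caesarean > p_facility + 1e-12:
            raise ConfigurationError(
                f"{self.site_id}: p_caesarean {self.p_caesarean:.4f} exceeds facility "
                f"probability {p_facility:.4f} (caesareans occur only in facilities)"
            )
        for cat, rate in self.complication_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{self.site_id}: complication rate for "
                                         f"{cat.value} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """A set of site profiles plus the mandatory global seed."""

    profiles: Sequence[SiteProfile]
    seed: int

    def validate(self) -> None:
        ids = [p.site_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("site_ids must be distinct")
        for p in self.profiles:
            p.validate()


def default_profiles(scale: float = 1.0) -> list[SiteProfile]:
    """Profiles reproducing the published marginals of the seven MNHR sites.

    ``scale`` shrinks every site's delivery count proportionally (rounded to
    the nearest integer) while leaving all probabilities untouched; useful
    for fast smoke runs.
    """
    profiles = []
    for summary in datasets.mnhr_site_summaries():
        site = summary.site_id
        loc_counts = datasets.MNHR_LOCATION_COUNTS[site]
        loc_total = sum(loc_counts)
        p_location = {l: c / loc_total for l, c in zip(_LOCATIONS, loc_counts)}
        cs_total = summary.caesarean_total
        indication_distribution = {
            cat: (summary.count(cat) / cs_total if cs_total else 0.0)
            for cat in ALL_INDICATIONS
        }
        complication_rates = {
            cat: n / summary.total_deliveries
            for cat, n in zip(
                datasets.COMPLICATION_ORDER, datasets.MNHR_COMPLICATION_COUNTS[site]
            )
        }
        profiles.append(
            SiteProfile(
                site_id=site,
                n_deliveries=int(round(summary.total_deliveries * scale)),
                p_location=p_location,
                p_caesarean=cs_total / summary.total_deliveries,
                indication_distribution=indication_distribution,
                complication_rates=complication_rates,
            )
        )
    return profiles


def _site_rng(seed: int, site_id: str) -> np.random.Generator:
    # substream keyed on (seed, crc32(site_id)): site-order independent
    return np.random.default_rng([seed, zlib.crc32(site_id.encode("utf-8"))])


def _generate_site_frame(profile: SiteProfile, rng: np.random.Generator) -> pd.DataFrame:
    n = profile.n_deliveries
    p_loc = np.array([profile.p_location.get(l, 0.0) for l in _LOCATIONS])
    p_loc = p_loc / p_loc.sum() if p_loc.sum() > 0 else p_loc
    location = rng.choice(len(_LOCATIONS), size=n, p=p_loc)
    facility = location < 2

    p_facility = p_loc[0] + p_loc[1]
    p_cs_given_facility = profile.p_caesarean / p_facility if p_facility > 0 else 0.0
    caesarean = facility & (rng.random(n) < p_cs_given_facility)

    indication = np.full(n, -1, dtype=int)
    n_cs = int(caesarean.sum())
    if n_cs:
        dist = np.array([profile.indication_distribution.get(c, 0.0) for c in ALL_INDICATIONS])
        dist = dist / dist.sum()
        indication[caesarean] = rng.choice(len(ALL_INDICATIONS), size=n_cs, p=dist)

    frame = pd.DataFrame(
        {
            "site_id": profile.site_id,
            "birth_location": pd.Categorical.from_codes(
                location, categories=[l.value for l in _LOCATIONS]
            ),
            "caesarean": caesarean,
            "indication": [
                ALL_INDICATIONS[i].value if i >= 0 else "" for i in indication
            ],
        }
    )

    ls_index = {c: i for i, c in enumerate(ALL_INDICATIONS)}
    for cat in LIFE_SAVING_INDICATIONS:
        forced = indication == ls_index[cat]
        target = profile.complication_rates.get(cat)
        if target is None:
            flags = forced
        else:
            # background rate so the marginal matches the configured target
            p_forced = profile.p_caesarean * profile.indication_distribution.get(cat, 0.0)
            background = max(0.0, (target - p_forced) / (1.0 - p_forced)) if p_forced < 1 else 0.0
            flags = forced | (~forced & (rng.random(n) < background))
        frame[f"compl_{cat.value}"] = flags.astype(int)
    return frame


def generate_frame(config: GeneratorConfig) -> pd.DataFrame:
    """Vectorised generation: one row per delivery, all sites concatenated."""
    config.validate()
    frames = [
        _generate_site_frame(p, _site_rng(config.seed, p.site_id))
        for p in config.profiles
    ]
    if not frames:
        return pd.DataFrame(columns=["site_id", "birth_location", "caesarean", "indication"])
    return pd.concat(frames, ignore_index=True)


def generate(config: GeneratorConfig) -> list[DeliveryRecord]:
    """Generate validated delivery records for every configured site."""
    frame = generate_frame(config)
    compl_cols = [(c, f"compl_{c.value}") for c in LIFE_SAVING_INDICATIONS]
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        complications = frozenset(c for c, col in compl_cols if d.get(col))
        records.append(
            DeliveryRecord(
                site_id=d["site_id"],
                birth_location=BirthLocation(d["birth_location"]),
                caesarean=bool(d["caesarean"]),
                indication=IndicationCategory(d["indication"]) if d["indication"] else None,
                complications=complications,
            )
        )
    return records
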