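# csbench

Indication-based benchmarking of caesarean section provision for
population-based delivery registries in low-resource settings.

## The problem

Overall caesarean section (CS) rates are a blunt policy target: a 35% rate
can hide large numbers of procedures without medical justification, while a
1–2% rate leaves life-threatening obstetric conditions untreated.  A more
informative question is whether a population receives *enough caesareans
for the conditions that require one*.  `csbench` implements an
indication-based approach: six conditions are treated as **life-saving
indications** for CS — cord prolapse or fetal distress; major antepartum
haemorrhage; obstructed or prolonged labour; severe pre-eclampsia or
eclampsia; transverse/oblique lie or breech presentation; uterine rupture —
and each site's provision is benchmarked per indication against percentile
reference bands derived from published studies.

The core statistic is the **specific caesarean prevalence** of indication
*i* at a site:

```
p_i = (caesarean sections performed for indication i) / (all deliveries in the catchment)
```

with the denominator covering every delivery in the population (home births
included), not just facility deliveries.  Across published studies the
10th/25th/50th/75th percentiles of `p_i` form a **reference band**;
provision for indication *i* is *acceptable* when `p_i` is at or above the
25th percentile and at most the 75th.  Summing the 25th-percentile minima
over the six indications gives a floor (4.34%) on the overall CS proportion
attributable to life-saving need, and the smallest overall CS rate among
sites that still meet at least three of the six minima defines the
**minimum adequate CS rate** of a registry.

The package ships with:

* a registry data model (record-level or site-summary CSV layouts) with
  validation and aggregation,
* a synthetic registry generator whose default profiles emulate the seven
  research sites of the Global Network's Maternal and Newborn Health
  Registry (MNHR, 271 855 deliveries, 2010–13) — the bundled site-level
  counts, since record-level MNHR data are not public,
* reference-band construction from a literature study table, plus the
  bundled bands of the published 20-study review,
* the site adequacy analysis and a `csbench` command-line pipeline
  (`simulate` / `bands` / `assess` / `report`).

## Worked example

```python
from csbench import (classify_site, literature_bands,
                     minimum_adequate_cs_rate, mnhr_site_summaries)

bands = literature_bands()
reports = [classify_site(s, bands) for s in mnhr_site_summaries()]
for r in reports:
    print(f"{r.site_id:10s} overall {r.overall_cs.display(0):>4s}  "
          f"life-saving {r.life_saving.display(1):>5s}  other {r.other.display(1):>5s}  "
          f"at/above p25: {r.counts_at_or_above['p25']}/6")
m = minimum_adequate_cs_rate(reports)
print(f"minimum adequate overall caesarean rate: {m.display(0)} ({m.numerator}/{m.denominator})")
```

prints

```
argentina  overall  35%  life-saving 15.6%  other 19.4%  at/above p25: 5/6
guatemala  overall  18%  life-saving  9.6%  other  8.8%  at/above p25: 5/6
nagpur     overall  20%  life-saving 13.8%  other  5.8%  at/above p25: 4/6
belgaum    overall  14%  life-saving  9.6%  other  4.5%  at/above p25: 3/6
pakistan   overall   9%  life-saving  6.8%  other  2.6%  at/above p25: 3/6
kenya      overall   2%  life-saving  1.3%  other  0.2%  at/above p25: 0/6
zambia     overall   1%  life-saving  0.5%  other  0.6%  at/above p25: 0/6
minimum adequate overall caesarean rate: 9% (4632/49550)
```

Reading: Argentina's 35% CS rate meets five of six life-saving minima but
more than half of its caesareans (19.4 of 35 percentage points) are for
non-life-saving indications; Guatemala reaches the same five minima at an
18% rate; Kenya and Zambia, at 1–2%, meet none.  Pakistan is the
lowest-rate site still meeting at least three minima, so 9% is the minimum
overall CS rate observed to cover life-saving need.

The same pipeline from the shell:

```sh
csbench simulate --seed 1 --scale 0.1 --out registry.csv   # synthetic registry
csbench bands --published --out bands.csv                  # reference bands
csbench assess --registry registry.csv --out-dir reports/  # per-site benchmarking
csbench report --report reports/report.json                # readable table
```

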