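# adherence — possession-based adherence indices from dispensing records

Pharmacy dispensing databases record *when* a medication was supplied, *how
much*, and *at what prescribed daily dose*. From these three elements,
possession-based adherence measures estimate the highest possible level of
medication consumption over an observation period — they measure timeliness of
refills, not actual drug-taking. This package implements that index family for
researchers and pharmacists working with refill/claims data:

* **Single-medication indices.** For refill intervals with days' supply `Aₙ`
  and interval length `Bₙ`: interval adherence `Aₙ/Bₙ`, gaps `Gₙ = Bₙ − Aₙ`,
  the medication possession ratio `MPR = ΣAₙ/ΣBₙ` (uncapped, may exceed 1,
  with or without the last refill's supply) and the capped variant (mean of
  per-interval ratios truncated at 1.0, the PDC-style index), plus gap
  proportions `ΣGₙ/ΣBₙ` signed or with negatives zeroed, and total days
  without medication with forward carryover of oversupply.
* **The daily polypharmacy possession ratio (DPPR).** For a regimen of several
  concurrent medications, a per-day *supply diary* is simulated in dispensing
  units: each day is scored by (medications available) / (medications
  expected), and `DPPR = Σ daily scores / observation days`. Because every
  day's score is bounded by 1, the DPPR cannot be inflated by oversupply,
  stockpiling or duplication — unlike the common practice of averaging
  per-medication MPRs, which this package also provides as a comparator
  (pooled and mean variants) precisely to expose that bias.
* **Standardisation rules** applied before any index: window from first
  dispensation to last refill or review date (half-open, no artificial
  initial/terminal gaps); exclusion of patients with two refills or less;
  merging of therapeutic switches, generic switches, combination pills and
  therapeutic duplication into one index medication; prescribed dose changes;
  exclusion of the last dispensation's doses beyond the window end; carryover
  of surplus forward in time only (no retroactive compensation).
* **A synthetic refill-history generator** with controlled target possession,
  refill jitter, stockpiling, mid-window entry, switching and dose changes,
  plus its own ground-truth coverage bookkeeping for estimator-bias studies.

Dosage schedules use the morning–noon–evening notation (`1-0-1`, `1/2-0-1/2`);
half tablets and all scores are held as exact rationals, so a 925-day diary in
thirds is computed without floating-point drift.

## Worked example

The built-in three-medication scenario (packs of 14/30/60 units, once daily,
15 dispensations, 120-day window):

```
$ adherence fixtures --name fig2_polypharmacy --out fig2.csv
$ adherence report --input fig2.csv
[
  {
    "patient_id": "fig2",
    "window_days": 120,
    "dppr_pct": 83,
    "average_mpr_pooled_pct": 135,
    "average_mpr_mean_pct": 127,
    "surplus_units": 80.0,
    "gap_days_per_medication": { "med1_pack14": 16, "med2_pack30": 29, "med3_pack60": 0 },
    "gap_days_any": 45,
    "mean_gap_pct": -13,
    "per_medication_mpr_pct": { "med1_pack14": 89, "med2_pack30": 100, "med3_pack60": 218 }
  }
]
```

Reading: the three single-medication MPRs are 89 %, 100 % and 218 % — the
60-pack medication was massively over-dispensed — and averaging them pools to
135 %, an apparent "adherence" above perfect. The per-day engine instead finds
that on a typical day only ~83 % of the expected medications were actually on
hand: the 14-pack medication ran out for 16 days, the 30-pack one for 29 days,
and the oversupply (80 surplus units at the review, after excluding the part
of the final fill that could never be consumed inside the window) cannot
compensate for them. `mean_gap_pct` of −13 summarises the same thing per
medication (negative = days without supply).

Other entry points: `adherence mpr` (per-medication indices with `--cap`,
`--drop-last-refill`, `--no-carryover`), `adherence dppr --dump-diary` (tidy
per-day CSV of the supply diary), `adherence simulate --seed N --out r.csv
--truth t.csv` (synthetic records with ground truth), and the library API
(`adherence.build_report`, `adherence.interval_metrics`, ...). Policies are
YAML files mirroring `StandardsPolicy` fields (`--policy rules.yaml`).

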