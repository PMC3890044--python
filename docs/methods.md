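# Methods

## The model

Possession indices treat dispensing records as an upper bound on consumption:
a patient is assumed to start using a dispensation on its dispensing day and
to consume the prescribed daily dose every day supply is on hand. All indices
in this package derive from three recorded elements per refill line: quantity
dispensed, prescribed daily dosage (morning–noon–evening schedule; days'
supply = quantity ÷ daily dose), and the dispensation date.

**Single-medication layer.** The observation window `[start, end)` is
half-open; its length is `end − start` days. With a *refill-date start* the
window opens on the first dispensation and intervals run fill-to-fill, the
last interval closing at the window end; a fill falling exactly on the window
end contributes supply (the "with last refill" numerator) but no interval.
With an *arbitrary start* the first interval runs from the window start to the
second in-window fill, and supply still on hand from a pre-window fill is
credited to it. Uncapped MPR is total days' supply over window length and may
exceed 1; the capped variant is the unweighted mean of per-interval ratios
truncated at 1.0 (an unweighted mean is used deliberately — a length-weighted
variant is available but is not the reported form). Gap proportions are
`ΣGₙ/ΣBₙ`, signed or with negative (surplus) intervals zeroed.

**Carryover.** Surplus moves forward in time only. For per-interval reporting
this is implemented as a forward allocation: walking the intervals in order,
each deficit draws from the pool of earlier, still-unconsumed surpluses
(earliest first); a surplus interval keeps, as a negative gap, only what no
later deficit ever needed. For constant daily dose this reproduces exactly
the gap days of the per-day unit ledger below, and the two are asserted
equivalent on seeded synthetic histories. (A naive rule that always adds
interval *n*'s surplus to interval *n+1* does not reproduce the reference
gap sequence 10, 0, 15, −20, −5, −20 of the single-medication scenario and
is not used.)

**Supply diary / DPPR layer.** Consumption is simulated in *units*, not in
precomputed days of supply: per medication and day, stock rises by the
quantity dispensed that day and falls by the daily dose in force if at least
one dose is on hand; a day is *available* iff consumption occurred. This
makes half-tablet schedules, mid-window dose changes (stock is preserved in
units and re-expressed in days at the new rate automatically) and forward
carryover exact, and makes retroactive compensation impossible by
construction. A medication is *expected* from its first dispensation to the
window end, or to its own `therapy_end` when one is set (needed where a
medication exits the regimen before the review). Each day's score is
(available ÷ expected); days with zero expected medications are dropped from
the denominator (under the default first-fill window start none exist). The
DPPR is the mean daily score, held as an exact rational until formatting.

**Stock accounting.** Because a per-day index bounded at 1 cannot show
oversupply, the report adds: per-medication gap days (expected but not
available), the accumulated surplus at the window end after excluding the
part of the final dispensation that could only have been consumed beyond the
window (excess = last quantity − dose·(days from last fill to window end),
floored at 0, per medication, surplus floored at 0), and `mean_gap_pct` =
−(mean per-medication gap days)/window. The negative sign is a deficit
convention (−10 means the average medication lacked supply on 10 % of days);
the reference case tables print their per-medication gap totals with this
sign, and the per-day engine reproduces those totals as gap-day counts
exactly for the histories whose transcription is trusted (see below).

**Averaged-MPR comparators.** Two non-identical formulas circulate and both
are kept first class: *pooled* (Σ days' supply ÷ Σ per-medication window
days, each medication's denominator capped at its own therapy end) and *mean*
(mean per-medication days' supply ÷ common window length). Either may exceed
1; their divergence from the DPPR is the bias the per-day index exists to
remove.

## Standardisation rules and their defaults

| Rule | Default | Note |
|---|---|---|
| window start | first dispensation | `fixed-date` option for arbitrary starts |
| window end | review date (else last refill) | calendar review date is the excluded half-open bound; an integer review day N means "through day N" (end N+1) |
| eligibility | ≥ 3 refill dates per patient | "two refills or less" excluded; a per-medication variant exists, off by default |
| switch / generic / combination / duplication | merge into one history | index medication = first refill in time; merging is idempotent, order-independent, unit-conserving; therapy classes are opaque user labels, never inferred |
| dose changes | honoured from effective date | contradictory same-date changes rejected |
| last-dispensation excess | excluded | neither covered days nor surplus |
| carryover | on, forward only | no retroactive compensation |
| variable dose / as-needed | disregarded with explicit verdict | days' supply undefined |

Policies are YAML/JSON blocks mirroring `StandardsPolicy`; every report
carries the policy fingerprint that produced it. Report manifests contain no
timestamp by default so that identical input + policy + version give
byte-identical reports.

## Reference scenarios and known inconsistencies of the source tables

The fixture registry encodes the printed scenarios: the 250-day
single-medication history (supplies 60/30/60/60/30/30/30, intervals
70/20/85/40/25/10, analysed from the refill date and from an arbitrary start
20 days earlier), the 120-day three-medication scenario (packs 14/30/60,
15 fills, per-medication review days 110/120/110), and three 31-month case
histories (4, 3 and 6 medications; windows of 932, 925 and 939 days;
European `DD.MM.YY` dates).

Event-level transcriptions of the case tables were validated against every
published per-medication supply total (cases M1 and F2) and, for M1 and F1,
by the strongest check available: the per-day engine run on the raw events
reproduces the published per-day segment decompositions *exactly*, including
every per-medication gap-day total. Three inconsistencies in the published
tables themselves are documented rather than patched:

* the 120-day scenario's printed per-day decomposition (which sums to exactly
  105/120 = 87.5 %) cannot be derived from its printed refills under any
  single carryover/denominator policy: the engine yields 82.5 %, with 29
  rather than 30 missed days for the 30-pack medication (the 16 missed days
  of the 14-pack medication and the surplus of 80 units match);
* case F1's supply-total row conflicts with its own refill rows (the engine,
  which reproduces F1's decomposition exactly, implies twice the printed
  metformin total); published summary values for F1 are therefore asserted
  from the printed totals, events from the transcription;
* case F2's printed decomposition evaluates to 76.9 %, not the printed 75 %
  (the engine on the raw events gives 77.0 %); the faithful computation is
  reported and the difference is not absorbed.

Where a published value and its printed derivation disagree (87.5 vs the
truncated 104.9/120), exact rational arithmetic resolves the artifact.

## Synthetic generator

The generator emulates: several concurrent medications with differing pack
sizes and schedules, refills scheduled around depletion with a late delay
whose mean matches a target possession (coverage per cycle =
supply/(supply+delay)), symmetric day jitter (uniform on [−j, +j], default
j = 3), early refills with probability `p_stockpile` (overlap/stockpiling),
mid-window regimen entry (`p_mid_entry`, default 0.2), therapeutic switching
with explicit annotations (exercising the merge path end to end) and
mid-history dose changes. Defaults: 10 patients, 2–4 medications, packs
{14, 30, 60, 100}, target possession 0.8, 360-day window. One seeded
`numpy` generator drives everything; a fixed config is byte-reproducible.

Its ground truth is the generator's own per-day coverage ledger, implemented
independently of the package's diary. What passing tests on synthetic data do
show: exact unit conservation, interval-engine/per-day equivalence, bounds
and insensitivity properties, and recovery of the target possession on long
windows (±2 points at 10,000 days). What they do not show: real-world
behaviours the generator does not model — hospitalisations and dispensing
pauses, within-day dose-taking patterns, seasonal refill habits, or dosage
instructions outside the fixed morning–noon–evening grammar.

## Numerical choices and limitations

* All supplies, stocks and scores are `fractions.Fraction`; no rounding
  before report formatting, which rounds half away from zero (integer
  percentages by default, matching how these indices are conventionally
  printed).
* Problem sizes: the per-day ledger is linear in window length × medications;
  the test suite simulates ~1,200 synthetic patient records with windows of
  240–720 days plus one 10,000-day recovery run, and the reference scenarios
  are at most 939 days × 6 medications.
* Degenerate inputs: zero total daily dose, non-positive quantities, empty
  regimens, review dates before the first fill, and contradictory same-date
  dose changes are rejected with explicit errors; same-day refills of one
  medication are merged by summing quantity.
* The DPPR is bounded by 1 and insensitive to oversupply and duplication,
  so it cannot detect overuse — that is what the surplus and gap-day
  statistics are for.
* No adherent/non-adherent cut-point is applied anywhere; the indices are
  reported as continuous proportions.
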