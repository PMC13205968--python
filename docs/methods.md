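# Methods

## The instrument

The BetterNest Score screens household environmental exposure across a
nine-question survey ordered macro-to-micro: broad setting (county lead and
air risk), then the home (tobacco smoke, cleaning products, pesticides,
plastics, produce), then personal behavior (personal-care product volume and
ingredient checking). Q1 records the respondent's life stage — considering
pregnancy, currently pregnant, or child at home — and is never scored; it
only selects the wording variant of Q4 and Q6 (the two questions with a
child-at-home phrasing; "considering" respondents see the pregnancy
phrasing). Q2 is a 5-digit ZIP code. Q3–Q9 are fixed-choice questions whose
options are displayed best-to-worst, with raw scores non-increasing down the
option list.

The instrument ships as packaged YAML validated on load (question count,
unique ids, score ranges, option-order monotonicity). Option identifiers are
stable snake_case tokens so stored responses survive copy edits to the
display text. Prompts are UTF-8 with typographic punctuation preserved.

## Domain subscores

Eight domains contribute to the index:

| domain | source | attainable subscores |
|---|---|---|
| lead | county % pre-1980 housing, quintile bands | 1, 3, 5, 7, 9 |
| air | county annual-mean PM2.5, NAAQS-anchored bands | 1, 5, 9 |
| tobacco | Q3 raw score | 1, 3, 6, 10 |
| cleaning | Q4 raw score | 2, 6, 9 |
| pesticides | Q5 raw score | 1, 5, 9 |
| plastics | Q6 raw score | 1, 3, 7, 10 |
| produce | Q7 raw score | 2, 5, 9 |
| personal care | Q8×Q9 lookup matrix | 1, 3, 5, 6, 7, 8, 10 |

**Lead.** Pre-1980 housing share is a standard proxy for lead paint and
plumbing risk. Quintile cut-points (41.05, 50.3, 58.8, 69.3 percent) are
anchored to the 2020 American Community Survey distribution of county
percentages. Bands are uniformly half-open `[lower, upper)` with the top
band closed at 100: a percentage exactly at a cut-point takes the
lower-score (higher-risk) side, and exactly 69.3 scores 1. The published
band notation leaves 69.3 itself ambiguous; one consistent convention is
adopted and pinned by tests — the measure is continuous, so the choice is
practically immaterial, but it must be deterministic.

**Air.** PM2.5 bands anchor to the 2020 NAAQS: below 12 µg/m³ scores 9, the
closed interval [12, 15] scores 5, above 15 scores 1. Reading the middle
band as closed is the only convention consistent with strict "<12" and ">15"
outer bands.

**Personal care.** Q8 (daily product count) does not contribute a ninth
domain. It modifies Q9 (ingredient checking) through a fixed 3×3 lookup:

| Q9 \ Q8 modifier | 9 (<10 products) | 5 (10–18) | 1 (>18) |
|---|---|---|---|
| checks all the time | 10 | 7 | 5 |
| sometimes | 8 | 6 | 3 |
| never | 7 | 3 | 1 |

Every row increases with the Q8 modifier and every column decreases down the
Q9 options, so reducing product count or checking more often can never hurt.
The lookup is implemented verbatim as a table; no arithmetic multiplication
is involved.

## Aggregation and rounding

The index is the unweighted arithmetic mean of the eight integer subscores
— unweighted so it stays interpretable for a non-technical audience, not a
calibrated exposure-dose model. The mean is an exact rational (integer sum
over 8), and the single rounding step is **half-away-from-zero to one
decimal**, computed in integer tenths as `(20*sum + 8) // 16` so no
floating-point intermediate can perturb a half-way case. Half-up is forced
by the instrument's published floor: the worst attainable sum is 10
(subscores 1,1,1,2,1,1,2,1), whose exact mean 1.25 must print as 1.3;
banker's rounding would print 1.2. The attainable range is therefore
[1.3, 9.4] — deliberately excluding both a perfect 10.0 and an exact 1.0 —
which the analyzer certifies by exhaustive enumeration rather than assuming.

Partial response sets are rejected (no imputation): averaging fewer than
eight domains would silently change the index's meaning, and the survey is
nine short questions.

## Recommendations

The three lowest-scoring domains are selected, ascending, with ties broken
by instrument (macro-to-micro) order so ties favor the broader environmental
domain; the tie-break is deterministic and verified against a brute-force
sort oracle over the whole score space. Lead and air both derive from the
ZIP code but are independent candidate domains. Texts for lead, plastics and
personal care are the launched tool's wording verbatim; the other five are
authored stand-ins in the same register, marked `canonical: false` in the
packaged resource. All texts must pass a small fear-framing blocklist and
end with a factsheet pointer whose link slot defaults to the literal
placeholder `(link to factsheets)`; a configurable base URL substitutes it.
The optional per-domain contribution table (subscore and distance to the
domain's best attainable value, largest gap first) is an extension beyond
the launched tool, added because pilot users asked which exposures drive
their score.

## Exhaustive verification

Because the score factors through the lead and air *bands*, the
score-relevant response space is the finite product
5 × 3 × 4 × 3 × 3 × 4 × 3 × 3 × 3 = 58,320 combinations (lead band, air
band, Q3–Q9 options). The analyzer enumerates all of them with a numpy
broadcast over a 9-axis integer array (milliseconds of CPU) and reports the
exact minimum, maximum, score histogram and single-option monotonicity
violations: along every axis, options are ordered worst-ward, so the rounded
score must be non-increasing; any increase is a violation. The certified
results — min 1.3, max 9.4, zero violations, no 1.0 or 10.0 in the
histogram — are recomputed, never hard-coded.

## Synthetic county fixtures

Real deployments resolve ZIP → county → (pre-1980 housing %, PM2.5) from CDC
Environmental Public Health Tracking Network and EPA surveillance tables.
The fixture generator emulates those tables deterministically per seed:
counties cycle through the 15 lead-band × air-band combinations (so ≥15
counties cover every band), measures are drawn uniformly strictly inside
each band's interval (so rounding to two decimals cannot cross a
threshold), and each county receives 1–3 unique 5-digit ZIP codes. What the
fixtures do **not** emulate: the real joint distribution of housing age and
PM2.5, population weighting, multi-county ZIP codes (each ZIP maps to one
county — a documented simplification), or data vintage drift (a vintage
comment is carried in the CSV header but ignored by scoring). Passing tests
therefore certify the scoring algebra and the I/O contract, not the
representativeness of any real county table. An unknown ZIP is a hard
error; no national median is imputed, since a silent default would corrupt
the index.

CSV dialect: `counties.csv` with header
`county_id,pct_pre1980_housing,pm25_annual` and `crosswalk.csv` with
`postal_code,county_id`; UTF-8, dot decimal separator, `#` comment lines
permitted; postal codes are read as strings to preserve leading zeros.

## CLI

`betternest` exposes `score`, `interactive`, `enumerate`, `gen-fixtures` and
`validate`. Exit codes: 0 success, 2 response validation, 3 geodata
(unknown ZIP, malformed CSV), 4 I/O (including an interrupted interactive
session, which produces no partial report). Interactive and batch scoring
share one code path, so a saved interactive session re-scored in batch
yields a byte-identical report. Configuration precedence is CLI flag >
YAML config file > built-in default; logs go to stderr, reports to stdout
or `--out`.

## Known limitations

- County-level banding can mask hyper-local exposure differences within a
  ZIP code; census-tract granularity is out of scope.
- The index is an informational screening score, not a clinical diagnostic
  or calibrated exposure-dose estimate; domains are unweighted by design.
- Self-reported behaviors (Q3–Q9) carry the usual reporting biases; nothing
  in the score validates answers against biomarkers.
- Only two wording variants exist (pregnancy / child at home); no broader
  localization.
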