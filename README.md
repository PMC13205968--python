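# betternest

Library and CLI implementing the **BetterNest Score**, a nine-question
household environmental-exposure screening instrument for pregnant women and
parents. The perinatal period is a critical window of susceptibility —
endocrine-disrupting chemicals (BPA, phthalates), lead, tobacco smoke and
PM2.5 can all affect fetal and child development — and it is also a teachable
moment when parents are unusually motivated to act. The instrument converts a
short survey plus county-level surveillance data into a single **positive
health index** (higher = lower risk) with the three highest-priority
behavioral recommendations, framed in motivational-interviewing language
(non-judgmental, autonomy-supportive, never fear-based).

## The score

Eight domains each receive an integer subscore in [1, 10]:

- **lead** — the county's percentage of pre-1980 housing (a lead paint/plumbing
  proxy), banded into ACS-2020-anchored quintiles:
  <41.05 → 9, 41.05–<50.3 → 7, 50.3–<58.8 → 5, 58.8–<69.3 → 3, ≥69.3 → 1;
- **air** — annual-average PM2.5 (µg/m³), banded at the 2020 NAAQS anchors:
  <12 → 9, 12–15 → 5, >15 → 1;
- **tobacco, cleaning, pesticides, plastics, produce** — the raw score of the
  selected survey option;
- **personal care** — a 3×3 lookup in which the daily product count (Q8)
  modifies the credit for ingredient-checking behavior (Q9); Q8 itself never
  enters the mean.

The final score is the unweighted arithmetic mean of the eight subscores,

```
S = round_half_up( (s_lead + s_air + ... + s_personal_care) / 8 , 1 decimal )
```

computed in exact integer arithmetic. By construction the attainable range is
**1.3–9.4**: no respondent can receive a perfect 10.0 (room for improvement
always remains) or a demoralizing 1.0. The three lowest-scoring domains drive
the recommendations.

County data are supplied as two small CSVs (`counties.csv`, `crosswalk.csv`);
a seeded synthetic fixture generator emulates the federal surveillance tables
(CDC housing-age data, EPA PM2.5) so nothing needs downloading.

## Worked example

```sh
betternest gen-fixtures --n-counties 15 --seed 7 --out demo-geo
betternest score responses.json --geodata demo-geo --contributions
```

with `responses.json`:

```json
{
  "life_stage": "currently_pregnant",
  "postal_code": "04915",
  "Q3": "never_public",
  "Q4": "weekly",
  "Q5": "sometimes_unsure",
  "Q6": "few_times_week",
  "Q7": "sometimes",
  "Q8": "ten_to_18",
  "Q9": "sometimes"
}
```

prints:

```
BetterNest Score: 5.9 / 10
(higher scores mean lower environmental risk)

Domain subscores:
  lead            7
  air             5
  tobacco        10
  cleaning        6
  pesticides      5
  plastics        3
  produce         5
  personal_care   6

Your top three recommendations:
  1. [plastics] Try to reduce ingestion of plastics. Avoid heating food or drinks in plastic, ...
  2. [air] Outdoor air quality in your county can reach levels worth planning around. ...
  3. [pesticides] Consider non-spray pest prevention first: sealing entry points, ...

What contributes most to your score (largest room to improve first):
  plastics       subscore  3, room to improve 7
  air            subscore  5, room to improve 4
  ...
```

ZIP 04915 maps (in this synthetic fixture) to a county with 45% pre-1980
housing (lead band 7) and PM2.5 in the 12–15 µg/m³ band (air 5); the survey
answers supply the other six subscores; 47/8 = 5.875 rounds to 5.9. The
respondent's weakest domain — plastics at 3 — leads the recommendations.

The same answers can be collected at the terminal with
`betternest interactive --geodata demo-geo` (Q1's life stage selects the
pregnancy or child-at-home wording of Q4 and Q6), and
`betternest enumerate` prints the exhaustive score-space summary. As a
library:

```python
import betternest as bn

instrument = bn.load_instrument()
geo = bn.generate_fixture(n_counties=15, seed=7)
responses = bn.validate_responses(instrument, record)  # the JSON dict above
result = bn.score(responses, geo, instrument)          # result.value == 5.9
recs = bn.select_recommendations(result.subscores)     # 3 lowest domains
```

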