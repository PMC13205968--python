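{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "BetterNest responses record",
  "description": "Flat record of one respondent's answers to the nine-question instrument. Q1 is captured as life_stage, Q2 as postal_code; Q3-Q9 carry option ids from the packaged instrument definition.",
  "type": "object",
  "additionalProperties": false,
  "required": ["life_stage", "postal_code", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9"],
  "properties": {
    "life_stage": {
      "enum": ["considering_pregnancy", "currently_pregnant", "child_at_home"]
    },
    "postal_code": {
      "type": "string",
      "pattern": "^[0-9]{5}$"
    },
    "Q3": {"enum": ["never_public", "sometimes_outdoors", "frequently_home", "daily_smoker"]},
    "Q4": {"enum": ["green_only", "weekly", "daily"]},
    "Q5": {"enum": ["never_rarely", "sometimes_unsure", "regularly"]},
    "Q6": {"enum": ["almost_never", "few_times_month", "few_times_week", "daily"]},
    "Q7": {"enum": ["always_dirty_dozen", "sometimes", "never_cheapest"]},
    "Q8": {"enum": ["less_than_10", "ten_to_18", "more_than_18"]},
    "Q9": {"enum": ["all_the_time", "sometimes", "never"]}
  }
}
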