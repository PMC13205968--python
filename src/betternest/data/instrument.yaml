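# BetterNest instrument definition (version 1.0, Spring 2024 launch wording).
# Nine questions; option order is the on-screen top-to-bottom order and raw
# scores are non-increasing in that order (less protective answers score lower).
# Scoring kinds: na (captured, never scored), geo (scored from county data),
# raw (option's raw_score enters the eight-domain mean), modifier (Q8: feeds
# the Q8->Q9 personal-care lookup matrix, contributes no ninth domain),
# matrix (Q9: personal-care subscore looked up from the Q8 modifier and the
# selected Q9 option in the scoring module).
version: "1.0"
questions:
  - qid: Q1
    domain_key: life_stage
    kind: na
    prompt: "Are you considering pregnancy, currently pregnant, or have a baby or young children at home?"
    options:
      - option_id: considering_pregnancy
        text: "I’m considering pregnancy"
      - option_id: currently_pregnant
        text: "I’m currently pregnant"
      - option_id: child_at_home
        text: "I have a baby or young children at home"
  - qid: Q2
    domain_key: location
    kind: geo
    prompt: "Where do you live? Enter your zipcode. This is to help determine risk of air pollution and lead exposure in your area."
    options: []
  - qid: Q3
    domain_key: tobacco
    kind: raw
    prompt: "How often are you exposed to tobacco or other smoke?"
    options:
      - option_id: never_public
        text: "Never, or only by passing smokers outdoors in public places"
        raw_score: 10
      - option_id: sometimes_outdoors
        text: "Sometimes, I’m around smokers a few times a week, mostly outdoors"
        raw_score: 6
      - option_id: frequently_home
        text: "Frequently, someone in my home smokes"
        raw_score: 3
      - option_id: daily_smoker
        text: "Daily, I smoke"
        raw_score: 1
  - qid: Q4
    domain_key: cleaning
    kind: raw
    prompt: "How often are you exposed to conventional cleaning products (consider home and at work)?"
    prompt_child_at_home: "How often are conventional cleaning products used in your home?"
    options:
      - option_id: green_only
        text: "Almost never, I only use “green” products with minimal chemical ingredients"
        raw_score: 9
      - option_id: weekly
        text: "Weekly, or a few times a month"
        raw_score: 6
      - option_id: daily
        text: "Daily, or a few times a week"
        raw_score: 2
  - qid: Q5
    domain_key: pesticides
    kind: raw
    prompt: "How often are pesticides sprayed in or around your home or building?"
    options:
      - option_id: never_rarely
        text: "Never or rarely"
        raw_score: 9
      - option_id: sometimes_unsure
        text: "Sometimes, or I’m not sure"
        raw_score: 5
      - option_id: regularly
        text: "Regularly, monthly or more frequently"
        raw_score: 1
  - qid: Q6
    domain_key: plastics
    kind: raw
    prompt: "How often do you drink from, eat from, or heat food or drink in plastic containers?"
    prompt_child_at_home: "How often does your child drink or eat from plastic containers, drink or eat items heated in plastic, or chew on plastic toys?"
    options:
      - option_id: almost_never
        text: "Almost never"
        raw_score: 10
      - option_id: few_times_month
        text: "A few times a month"
        raw_score: 7
      - option_id: few_times_week
        text: "A few times a week"
        raw_score: 3
      - option_id: daily
        text: "Daily"
        raw_score: 1
  - qid: Q7
    domain_key: produce
    kind: raw
    prompt: "How often do you buy organic produce for you or your family, or check the pesticide level on the DirtyDozen list?"
    options:
      - option_id: always_dirty_dozen
        text: "Always, or at least the ones recommended by DirtyDozen"
        raw_score: 9
      - option_id: sometimes
        text: "Sometimes"
        raw_score: 5
      - option_id: never_cheapest
        text: "Never, I buy what’s available or cheapest"
        raw_score: 2
  - qid: Q8
    domain_key: product_volume
    kind: modifier
    prompt: "Roughly how many personal care products do you use on a daily basis? Walk through your day and count them up, consider body and hair wash, other cleansers, toothpaste, skin and hair products, deodorant, cosmetics, nail products, etc."
    options:
      - option_id: less_than_10
        text: "Less than 10"
        modifier: 9
      - option_id: ten_to_18
        text: "10–18"
        modifier: 5
      - option_id: more_than_18
        text: ">18"
        modifier: 1
  - qid: Q9
    domain_key: ingredient_check
    kind: matrix
    prompt: "How often do you check the ingredients of your or your child’s personal care products on a tool like SkinDeep, Think Dirty, or Clearya?"
    options:
      - option_id: all_the_time
        text: "All the time, for all the products I can"
      - option_id: sometimes
        text: "Sometimes"
      - option_id: never
        text: "Never"
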