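{
  "_comment": "Independent transcription of the instrument's printed question/response/score table, used as the golden reference. Scores are keyed by option display order (top to bottom). null = unscored option.",
  "lead_bands": [[41.05, 9], [50.3, 7], [58.8, 5], [69.3, 3], [null, 1]],
  "air_bands": {"below": [12, 9], "middle": [12, 15, 5], "above": [15, 1]},
  "questions": {
    "Q1": {
      "prompt": "Are you considering pregnancy, currently pregnant, or have a baby or young children at home?",
      "options": [
        ["I’m considering pregnancy", null],
        ["I’m currently pregnant", null],
        ["I have a baby or young children at home", null]
      ]
    },
    "Q2": {
      "prompt": "Where do you live? Enter your zipcode. This is to help determine risk of air pollution and lead exposure in your area.",
      "options": []
    },
    "Q3": {
      "prompt": "How often are you exposed to tobacco or other smoke?",
      "options": [
        ["Never, or only by passing smokers outdoors in public places", 10],
        ["Sometimes, I’m around smokers a few times a week, mostly outdoors", 6],
        ["Frequently, someone in my home smokes", 3],
        ["Daily, I smoke", 1]
      ]
    },
    "Q4": {
      "prompt": "How often are you exposed to conventional cleaning products (consider home and at work)?",
      "prompt_child_at_home": "How often are conventional cleaning products used in your home?",
      "options": [
        ["Almost never, I only use “green” products with minimal chemical ingredients", 9],
        ["Weekly, or a few times a month", 6],
        ["Daily, or a few times a week", 2]
      ]
    },
    "Q5": {
      "prompt": "How often are pesticides sprayed in or around your home or building?",
      "options": [
        ["Never or rarely", 9],
        ["Sometimes, or I’m not sure", 5],
        ["Regularly, monthly or more frequently", 1]
      ]
    },
    "Q6": {
      "prompt": "How often do you drink from, eat from, or heat food or drink in plastic containers?",
      "prompt_child_at_home": "How often does your child drink or eat from plastic containers, drink or eat items heated in plastic, or chew on plastic toys?",
      "options": [
        ["Almost never", 10],
        ["A few times a month", 7],
        ["A few times a week", 3],
        ["Daily", 1]
      ]
    },
    "Q7": {
      "prompt": "How often do you buy organic produce for you or your family, or check the pesticide level on the DirtyDozen list?",
      "options": [
        ["Always, or at least the ones recommended by DirtyDozen", 9],
        ["Sometimes", 5],
        ["Never, I buy what’s available or cheapest", 2]
      ]
    },
    "Q8": {
      "prompt": "Roughly how many personal care products do you use on a daily basis? Walk through your day and count them up, consider body and hair wash, other cleansers, toothpaste, skin and hair products, deodorant, cosmetics, nail products, etc.",
      "options": [
        ["Less than 10", 9],
        ["10–18", 5],
        [">18", 1]
      ]
    },
    "Q9": {
      "prompt": "How often do you check the ingredients of your or your child’s personal care products on a tool like SkinDeep, Think Dirty, or Clearya?",
      "options": [
        ["All the time, for all the products I can", null],
        ["Sometimes", null],
        ["Never", null]
      ]
    }
  },
  "q9_matrix_by_option_order": [
    [10, 7, 5],
    [8, 6, 3],
    [7, 3, 1]
  ],
  "recommendation_texts": {
    "lead": "There might be a risk of lead exposure in your home. Consider testing your tap water, and look into ways to reduce lead in the home. Get recommendations here (link to factsheets).",
    "plastics": "Try to reduce ingestion of plastics. Avoid heating food or drinks in plastic, and switch to metal, glass or other materials for products where possible. Get more recommendations here (link to factsheets).",
    "personal_care": "Keep trying to reduce the number of personal care products you use daily, or check their ingredients and swap out for safer products based on your priorities. Get more recommendations here (link to factsheets)."
  }
}
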