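# Recommendation templates keyed by domain. The lead, plastics and
# personal_care texts are the launched tool's wording, verbatim; the other
# five (canonical: false) are authored stand-ins in the same motivational-
# interviewing register: non-judgmental, autonomy-supportive, no fear
# framing, each ending with a factsheet pointer. {factsheet_url} is the
# link slot; it defaults to the literal placeholder "link to factsheets".
lead:
  canonical: true
  text: "There might be a risk of lead exposure in your home. Consider testing your tap water, and look into ways to reduce lead in the home. Get recommendations here ({factsheet_url})."
air:
  canonical: false
  text: "Outdoor air quality in your county can reach levels worth planning around. Consider improving indoor ventilation, using a HEPA filter if you can, and checking the daily air quality forecast before long outdoor stretches. Get more recommendations here ({factsheet_url})."
tobacco:
  canonical: false
  text: "Reducing time around tobacco smoke is one of the most protective changes available. Consider asking household smokers to smoke outside away from doors and windows, and explore quit supports whenever you feel ready. Get more recommendations here ({factsheet_url})."
cleaning:
  canonical: false
  text: "Consider swapping conventional cleaning products for fragrance-free or third-party-verified alternatives, and open windows while you clean. Small swaps count. Get more recommendations here ({factsheet_url})."
pesticides:
  canonical: false
  text: "Consider non-spray pest prevention first: sealing entry points, storing food in closed containers, and asking your landlord or applicator about reduced-spray options. Get more recommendations here ({factsheet_url})."
plastics:
  canonical: true
  text: "Try to reduce ingestion of plastics. Avoid heating food or drinks in plastic, and switch to metal, glass or other materials for products where possible. Get more recommendations here ({factsheet_url})."
produce:
  canonical: false
  text: "When it fits your budget, consider choosing organic versions of the produce on the DirtyDozen list, and rinse all fruits and vegetables well before eating. Get more recommendations here ({factsheet_url})."
personal_care:
  canonical: true
  text: "Keep trying to reduce the number of personal care products you use daily, or check their ingredients and swap out for safer products based on your priorities. Get more recommendations here ({factsheet_url})."
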