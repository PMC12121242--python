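# Default short-item FFQ schema: one question per scored food group plus the
# quality questions (wholegrain, plain water, healthy fats). Response options
# are serve ranges; a range maps to its midpoint, an open-top option ("5
# serves or more") to its floor. Options with lo == hi are point values.
# frequency_basis per_fortnight divides the mapped value by 14 to get
# serves/day. This is a faithful skeleton of the instrument's described
# structure (ranged serve options, combined meat question, multiple-choice
# SSB question), not a facsimile of its full 32-item list.
schema_version: 1
questions:
  - question_id: q_vegetables
    kind: serves
    food_group: vegetables
    frequency_basis: per_day
    prompt: "How many serves of vegetables do you usually eat per day?"
    options:
      - {label: "0.5 serves or less", lo: 0.0, hi: 0.5}
      - {label: "0.5-1 serve", lo: 0.5, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4-5 serves", lo: 4.0, hi: 5.0}
      - {label: "5 serves or more", lo: 5.0, hi: 5.0}
  - question_id: q_fruit
    kind: serves
    food_group: fruit
    frequency_basis: per_day
    prompt: "How many serves of fruit do you usually eat per day?"
    options:
      - {label: "0.5 serves or less", lo: 0.0, hi: 0.5}
      - {label: "0.5-1 serve", lo: 0.5, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4-5 serves", lo: 4.0, hi: 5.0}
      - {label: "5 serves or more", lo: 5.0, hi: 5.0}
  - question_id: q_breads_cereals
    kind: serves
    food_group: breads_cereals
    frequency_basis: per_day
    prompt: "How many serves of breads and cereals do you usually eat per day?"
    options:
      - {label: "1 serve or less", lo: 0.0, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4-5 serves", lo: 4.0, hi: 5.0}
      - {label: "5-6 serves", lo: 5.0, hi: 6.0}
      - {label: "6-7 serves", lo: 6.0, hi: 7.0}
      - {label: "7-8 serves", lo: 7.0, hi: 8.0}
      - {label: "8 serves or more", lo: 8.0, hi: 8.0}
  - question_id: q_meat
    kind: serves
    food_group: meat
    frequency_basis: per_day
    prompt: "How many serves of fresh or frozen land animals and/or birds do you usually eat per day?"
    options:
      - {label: "0.5 serves or less", lo: 0.0, hi: 0.5}
      - {label: "0.5-1 serve", lo: 0.5, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4-5 serves", lo: 4.0, hi: 5.0}
      - {label: "5 serves or more", lo: 5.0, hi: 5.0}
  - question_id: q_dairy
    kind: serves
    food_group: dairy
    frequency_basis: per_day
    prompt: "How many serves of milk, cheese or yoghurt do you usually have per day?"
    options:
      - {label: "0.5 serves or less", lo: 0.0, hi: 0.5}
      - {label: "0.5-1 serve", lo: 0.5, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4 serves or more", lo: 4.0, hi: 4.0}
  - question_id: q_ssb
    kind: serves
    food_group: ssb
    frequency_basis: per_fortnight
    prompt: "How many serves of sugary drinks have you had over the last fortnight?"
    options:
      - {label: "none", lo: 0.0, hi: 0.0}
      - {label: "1-3 serves", lo: 1.0, hi: 3.0}
      - {label: "4-7 serves", lo: 4.0, hi: 7.0}
      - {label: "8-14 serves", lo: 8.0, hi: 14.0}
      - {label: "15-28 serves", lo: 15.0, hi: 28.0}
      - {label: "more than 28 serves", lo: 28.0, hi: 28.0}
  - question_id: q_discretionary
    kind: serves
    food_group: discretionary
    frequency_basis: per_day
    prompt: "How many serves of packaged snacks, takeaway or other sometimes foods do you usually eat per day?"
    options:
      - {label: "0.5 serves or less", lo: 0.0, hi: 0.5}
      - {label: "0.5-1 serve", lo: 0.5, hi: 1.0}
      - {label: "1-2 serves", lo: 1.0, hi: 2.0}
      - {label: "2-3 serves", lo: 2.0, hi: 3.0}
      - {label: "3-4 serves", lo: 3.0, hi: 4.0}
      - {label: "4-5 serves", lo: 4.0, hi: 5.0}
      - {label: "5-6 serves", lo: 5.0, hi: 6.0}
      - {label: "6 serves or more", lo: 6.0, hi: 6.0}
  - question_id: q_wholegrain
    kind: fraction
    target: wholegrain_fraction
    frequency_basis: per_day
    prompt: "How often are the breads and cereals you eat wholegrain or wholemeal?"
    options:
      - {label: "never", lo: 0.0, hi: 0.0}
      - {label: "some of the time", lo: 0.3, hi: 0.3}
      - {label: "most of the time", lo: 0.7, hi: 0.7}
      - {label: "always", lo: 1.0, hi: 1.0}
  - question_id: q_water
    kind: boolean
    target: plain_water
    frequency_basis: per_day
    prompt: "Do you drink plain water?"
    options:
      - {label: "no", lo: 0.0, hi: 0.0}
      - {label: "yes", lo: 1.0, hi: 1.0}
  - question_id: q_healthy_fats
    kind: fraction
    target: healthy_fats
    frequency_basis: per_day
    prompt: "How often do you use healthy fats and oils (olive/canola oil, avocado, nuts)?"
    options:
      - {label: "never", lo: 0.0, hi: 0.0}
      - {label: "sometimes", lo: 0.33, hi: 0.33}
      - {label: "usually", lo: 0.67, hi: 0.67}
      - {label: "always", lo: 1.0, hi: 1.0}
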