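# Default age/life-stage taxonomy with recommended daily serves per food group,
# following the Australian Dietary Guidelines foundation-diet serve counts.
# Ages are months, intervals half-open [age_lo_months, age_hi_months).
# The taxonomy is editable config: swap this file to score under a different
# reference table. dairy_applicable must be false exactly for under-2 groups.
schema_version: 1
groups:
  - group_id: child_6_24m
    label: "Child 6-<24 months"
    age_lo_months: 6
    age_hi_months: 24
    sex: any
    life_stage: child
    dairy_applicable: false
    recommended_serves: {vegetables: 2.5, fruit: 0.5, breads_cereals: 4.0, meat: 1.0, dairy: 1.0}
    discretionary_limit: 2.5
    ssb_limit: 1.0
  - group_id: child_2_4y
    label: "Child 2-<4 years"
    age_lo_months: 24
    age_hi_months: 48
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 2.5, fruit: 1.0, breads_cereals: 4.0, meat: 1.0, dairy: 1.5}
    discretionary_limit: 2.5
    ssb_limit: 1.0
  - group_id: child_4_6y
    label: "Child 4-<6 years"
    age_lo_months: 48
    age_hi_months: 72
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 4.5, fruit: 1.5, breads_cereals: 4.0, meat: 1.5, dairy: 2.0}
    discretionary_limit: 2.5
    ssb_limit: 1.0
  - group_id: child_6_9y
    label: "Child 6-<9 years"
    age_lo_months: 72
    age_hi_months: 108
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 4.5, fruit: 1.5, breads_cereals: 4.0, meat: 1.5, dairy: 2.0}
    discretionary_limit: 2.5
    ssb_limit: 1.0
  - group_id: child_9_12y
    label: "Child 9-<12 years"
    age_lo_months: 108
    age_hi_months: 144
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 5.0, meat: 2.5, dairy: 3.0}
    discretionary_limit: 2.5
    ssb_limit: 1.0
  - group_id: child_12_14y
    label: "Child 12-<14 years"
    age_lo_months: 144
    age_hi_months: 168
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 5.5, fruit: 2.0, breads_cereals: 6.0, meat: 2.5, dairy: 3.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: child_14_19y
    label: "Child 14-<19 years"
    age_lo_months: 168
    age_hi_months: 228
    sex: any
    life_stage: child
    dairy_applicable: true
    recommended_serves: {vegetables: 5.5, fruit: 2.0, breads_cereals: 7.0, meat: 2.5, dairy: 3.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: male_19_50
    label: "Male 19-50"
    age_lo_months: 228
    age_hi_months: 612
    sex: male
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 6.0, fruit: 2.0, breads_cereals: 6.0, meat: 3.0, dairy: 2.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: female_19_50
    label: "Female 19-50"
    age_lo_months: 228
    age_hi_months: 612
    sex: female
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 6.0, meat: 2.5, dairy: 2.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: male_51_70
    label: "Male 51-70"
    age_lo_months: 612
    age_hi_months: 852
    sex: male
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 5.5, fruit: 2.0, breads_cereals: 6.0, meat: 2.5, dairy: 2.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: female_51_70
    label: "Female 51-70"
    age_lo_months: 612
    age_hi_months: 852
    sex: female
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 4.0, meat: 2.0, dairy: 4.0}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: male_70_plus
    label: "Male 70+"
    age_lo_months: 852
    age_hi_months: 1440
    sex: male
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 4.5, meat: 2.5, dairy: 3.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: female_70_plus
    label: "Female 70+"
    age_lo_months: 852
    age_hi_months: 1440
    sex: female
    life_stage: adult
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 3.0, meat: 2.0, dairy: 4.0}
    discretionary_limit: 3.0
    ssb_limit: 1.0
  - group_id: pregnant_breastfeeding
    label: "Pregnant and/or breastfeeding female"
    age_lo_months: 228
    age_hi_months: 852
    sex: female
    life_stage: pregnant_breastfeeding
    dairy_applicable: true
    recommended_serves: {vegetables: 5.0, fruit: 2.0, breads_cereals: 8.5, meat: 3.5, dairy: 2.5}
    discretionary_limit: 3.0
    ssb_limit: 1.0
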