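# Base-case inputs of the IPMN cost-effectiveness model (US healthcare
# perspective).  Any scalar key may carry a "_percent" suffix, in which case
# its value is divided by 100 on load.
ctmri:
  sensitivity_percent: 80.9
  specificity_percent: 76.2
pet:
  sensitivity_percent: 96.8
  specificity_percent: 91.1
costs:
  mri_exam: 492
  pet_exam: 1551
  pancreatoduodenectomy: 28623
  distal_resection: 13900
  head_resection_fraction_percent: 78
  distal_resection_fraction_percent: 21
  recurrence_cost: 78630
  readmission_cost: 1930
utilities:
  healthy_ipmn: 1.00
  resection_year: 0.818
  post_resection_longterm: 0.896
  recurrence: 0.65
  death: 0.00
transitions:
  malignant_transformation_percent: 2.23
  death_malignant_ipmn_percent: 2.7
  death_recurrence_percent: 28.3
  perioperative_mortality_percent: 4.6
  recurrence_probability_percent: 16.7
  pet_recurrence_risk_reduction_percent: 10
economics:
  wtp: 100000
  discount_rate_percent: 3.00
  horizon: 15
  cycle_length: 1
  starting_age: 64.3
  pretest_probability_percent: 52
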