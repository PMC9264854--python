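# Cervical-cancer-screening path model over NFHS-4 women's-file variables.
# Reference categories follow the published contrasts: age 15-34, BMI
# underweight, facility barrier "not a big problem", contraception none,
# children none, autonomy "decides alone", one sex partner, STI awareness no,
# religion Hindu, wealth poorest.  Schooling is the sole continuous predictor.
variables:
  - {name: screening, role: outcome, family: bernoulli,
     levels: [not_screened, screened], reference: not_screened}
  - {name: age, role: covariate, family: bernoulli,
     levels: ["15-34", "35-49"], reference: "15-34"}
  - {name: bmi, role: covariate, family: multinomial,
     levels: [underweight, normal, overweight, obese], reference: underweight}
  - {name: facility_barrier, role: covariate, family: multinomial,
     levels: [not_a_big_problem, distance_only, transport_only, transport_and_distance],
     reference: not_a_big_problem}
  - {name: contraception, role: mediator, family: multinomial,
     levels: [none, condom, others], reference: none}
  - {name: children, role: mediator, family: multinomial,
     levels: [none, one_two, three_four, more_than_four], reference: none}
  - {name: autonomy, role: covariate, family: multinomial,
     levels: [alone, with_husband, husband_family], reference: alone}
  - {name: sex_partners, role: covariate, family: multinomial,
     levels: [one, two, more_than_two], reference: one}
  - {name: sti_awareness, role: mediator, family: bernoulli,
     levels: ["no", "yes"], reference: "no"}
  - {name: schooling, role: covariate, family: continuous}
  - {name: religion, role: covariate, family: multinomial,
     levels: [hindu, muslim, christian, others], reference: hindu}
  - {name: wealth, role: covariate, family: multinomial,
     levels: [poorest, poorer, middle, richer, richest], reference: poorest}
equations:
  - response: screening
    family: bernoulli
    baseline: not_screened
    predictors: [age, bmi, facility_barrier, contraception, children, autonomy,
                 sex_partners, sti_awareness, schooling, religion, wealth]
  - response: contraception
    family: multinomial
    baseline: none
    predictors: [religion, schooling]
  - response: children
    family: multinomial
    baseline: none
    predictors: [wealth, religion]
  - response: sti_awareness
    family: bernoulli
    baseline: "no"
    predictors: [schooling]
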