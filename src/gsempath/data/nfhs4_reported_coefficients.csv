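equation,contrast,term,estimate,ci_low,ci_high,n
screening,screened,age[35-49],0.148,0.112,0.183,82533
screening,screened,bmi[normal],0.022,-0.022,0.066,82533
screening,screened,bmi[overweight],0.125,0.071,0.180,82533
screening,screened,bmi[obese],0.187,0.112,0.261,82533
screening,screened,facility_barrier[distance_only],0.012,-0.048,0.073,82533
screening,screened,facility_barrier[transport_only],0.010,-0.063,0.082,82533
screening,screened,facility_barrier[transport_and_distance],0.006,-0.033,0.046,82533
screening,screened,contraception[condom],0.046,-0.018,0.110,82533
screening,screened,contraception[others],0.169,0.135,0.203,82533
screening,screened,children[one_two],0.221,0.162,0.280,82533
screening,screened,children[three_four],0.126,0.060,0.192,82533
screening,screened,children[more_than_four],0.009,-0.071,0.089,82533
screening,screened,autonomy[with_husband],0.016,-0.034,0.066,82533
screening,screened,autonomy[husband_family],0.016,-0.040,0.072,82533
screening,screened,sex_partners[two],-0.002,-0.117,0.114,82533
screening,screened,sex_partners[more_than_two],-0.209,-0.367,-0.052,82533
screening,screened,sti_awareness[yes],0.327,0.285,0.370,82533
screening,screened,schooling,-0.014,-0.017,-0.010,82533
screening,screened,religion[muslim],0.161,0.117,0.206,82533
screening,screened,religion[christian],0.015,-0.053,0.083,82533
screening,screened,religion[others],0.224,0.015,0.295,82533
screening,screened,wealth[poorer],0.309,0.254,0.364,82533
screening,screened,wealth[middle],0.528,0.472,0.584,82533
screening,screened,wealth[richer],0.698,0.639,0.757,82533
screening,screened,wealth[richest],0.916,0.851,0.981,82533
contraception,condom,religion[muslim],0.197,0.165,0.229,699686
contraception,condom,religion[christian],-1.719,-1.807,-1.631,699686
contraception,condom,religion[others],0.506,0.461,0.551,699686
contraception,condom,schooling,0.065,0.062,0.067,699686
contraception,others,religion[muslim],-0.636,-0.653,-0.620,699686
contraception,others,religion[christian],-0.773,-0.796,-0.751,699686
contraception,others,religion[others],0.029,0.005,0.054,699686
contraception,others,schooling,-0.065,-0.067,-0.062,699686
children,one_two,wealth[poorer],0.104,0.084,0.123,699686
children,one_two,wealth[middle],0.190,0.171,0.209,699686
children,one_two,wealth[richer],0.302,0.283,0.321,699686
children,one_two,wealth[richest],0.383,0.365,0.403,699686
children,one_two,religion[muslim],-0.518,-0.535,-0.500,699686
children,one_two,religion[christian],-0.399,-0.421,-0.377,699686
children,one_two,religion[others],-0.032,-0.058,-0.005,699686
children,three_four,wealth[poorer],-0.134,-0.154,-0.114,699686
children,three_four,wealth[middle],-0.287,-0.307,-0.267,699686
children,three_four,wealth[richer],-0.440,-0.460,-0.419,699686
children,three_four,wealth[richest],-0.692,-0.714,-0.671,699686
children,three_four,religion[muslim],-0.165,-0.183,-0.146,699686
children,three_four,religion[christian],-0.192,-0.216,-0.168,699686
children,three_four,religion[others],-0.079,-0.110,-0.048,699686
children,more_than_four,wealth[poorer],-0.518,-0.543,-0.494,699686
children,more_than_four,wealth[middle],-0.994,-1.020,-0.967,699686
children,more_than_four,wealth[richer],-1.470,-1.501,-1.439,699686
children,more_than_four,wealth[richest],-2.098,-2.137,-2.058,699686
children,more_than_four,religion[muslim],0.507,0.484,0.531,699686
children,more_than_four,religion[christian],0.262,0.229,0.294,699686
children,more_than_four,religion[others],-0.306,-0.361,-0.250,699686
sti_awareness,yes,schooling,0.197,0.194,0.200,699686
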