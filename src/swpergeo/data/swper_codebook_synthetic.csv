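# source: synthetic stand-in codebook; follows the published SWPER global domain structure (5 attitude-to-violence, 6 social-independence, 3 decision-making items) but NOT the published principal-component weights, which are not redistributed here
# version: 0.1.0
# note: recodes map the synthetic ordinal categories to signed scores; higher recoded value and positive weight mean higher empowerment
item_id,domain,raw_value,recoded_value,weight
item_1,attitude_to_violence,0,-1,0.40
item_1,attitude_to_violence,1,1,0.40
item_2,attitude_to_violence,0,-1,0.41
item_2,attitude_to_violence,1,1,0.41
item_3,attitude_to_violence,0,-1,0.39
item_3,attitude_to_violence,1,1,0.39
item_4,attitude_to_violence,0,-1,0.42
item_4,attitude_to_violence,1,1,0.42
item_5,attitude_to_violence,0,-1,0.38
item_5,attitude_to_violence,1,1,0.38
item_6,social_independence,0,0,0.30
item_6,social_independence,1,1,0.30
item_6,social_independence,2,2,0.30
item_6,social_independence,3,3,0.30
item_7,social_independence,0,0,0.28
item_7,social_independence,1,1,0.28
item_7,social_independence,2,2,0.28
item_7,social_independence,3,3,0.28
item_8,social_independence,0,0,0.26
item_8,social_independence,1,1,0.26
item_8,social_independence,2,2,0.26
item_8,social_independence,3,3,0.26
item_9,social_independence,0,0,0.32
item_9,social_independence,1,1,0.32
item_9,social_independence,2,2,0.32
item_9,social_independence,3,3,0.32
item_10,social_independence,0,0,0.24
item_10,social_independence,1,1,0.24
item_10,social_independence,2,2,0.24
item_10,social_independence,3,3,0.24
item_11,social_independence,0,0,0.22
item_11,social_independence,1,1,0.22
item_11,social_independence,2,2,0.22
item_11,social_independence,3,3,0.22
item_12,decision_making,0,-1,0.60
item_12,decision_making,1,0,0.60
item_12,decision_making,2,1,0.60
item_13,decision_making,0,-1,0.62
item_13,decision_making,1,0,0.62
item_13,decision_making,2,1,0.62
item_14,decision_making,0,-1,0.58
item_14,decision_making,1,0,0.58
item_14,decision_making,2,1,0.58
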