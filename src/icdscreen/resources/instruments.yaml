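# Instrument definitions for the International Depression Questionnaire (IDQ)
# and the International Anxiety Questionnaire (IAQ), the ICD-11-aligned
# screening scales this package scores, plus the published normal-ogive 2PL
# item parameters and observed item-response distributions used as reference
# values and as defaults for the synthetic cohort generator.
anchors:
  0: Never
  1: Only a few days
  2: Half the days
  3: Most days
  4: Every day
endorsement_threshold: 3

impairment_question: >
  Have these experiences caused problems in personal, family, social,
  educational, occupational, or other important areas of your life?

idq:
  name: IDQ
  full_name: International Depression Questionnaire
  disorder: ICD-11 Depressive Episode
  core_items: [1, 2]          # affective cluster: depressed mood / anhedonia
  min_endorsed: 5
  items:
    - Felt down or depressed for most of the day?
    - Experienced less interest or pleasure from normal activities for most of the day?
    - Have had difficulty concentrating?
    - Had feelings of worthlessness or guilt?
    - Felt hopeless?
    - Had recurrent thoughts of death or suicide?
    - Have had changes in appetite or sleep?
    - Moved slower or felt more restless?
    - Experienced reduced energy or fatigue?
  # Published 2PL estimates (probit metric, theta ~ N(0,1)): a = discrimination,
  # b = difficulty, with standard errors.
  params_2pl:
    a:    [2.864, 3.127, 2.408, 2.911, 3.159, 2.035, 1.972, 2.256, 2.204]
    se_a: [0.225, 0.252, 0.176, 0.232, 0.266, 0.162, 0.141, 0.171, 0.147]
    b:    [1.190, 1.121, 1.204, 1.154, 1.159, 1.511, 1.267, 1.307, 0.980]
    se_b: [0.040, 0.038, 0.042, 0.039, 0.039, 0.054, 0.046, 0.045, 0.038]
  # Observed response-category percentages (categories 0-4) per item.
  category_pct:
    - [50.2, 26.6, 10.1, 8.5, 4.6]
    - [49.6, 26.1, 10.0, 9.7, 4.6]
    - [51.1, 24.7, 10.9, 8.7, 4.6]
    - [60.3, 17.2, 8.8, 8.7, 5.0]
    - [60.0, 17.4, 9.1, 7.8, 5.6]
    - [74.9, 9.6, 6.8, 5.8, 3.0]
    - [53.0, 23.4, 10.7, 8.5, 4.5]
    - [61.3, 17.4, 9.7, 8.4, 3.2]
    - [42.6, 27.0, 11.8, 11.3, 7.3]
  pct_endorsed: [13.1, 14.3, 13.3, 13.8, 13.5, 8.7, 12.9, 11.6, 18.6]

iaq:
  name: IAQ
  full_name: International Anxiety Questionnaire
  disorder: ICD-11 Generalized Anxiety Disorder
  core_items: [1, 2]          # essential features: apprehension / excessive worry
  min_endorsed: 4
  items:
    - Felt nervous or anxious?
    - Worried a lot about different things?
    - Felt physically tense or agitated?
    - Felt your heart racing, difficulty breathing, stomach discomfort, or dry mouth?
    - Felt "on edge"?
    - Had difficulty concentrating?
    - Been easily annoyed by different things?
    - Experienced sleep disturbances?
  params_2pl:
    a:    [3.369, 3.291, 3.364, 2.237, 3.489, 2.433, 2.298, 1.571]
    se_a: [0.295, 0.279, 0.295, 0.177, 0.307, 0.180, 0.168, 0.102]
    b:    [1.044, 0.977, 1.107, 1.359, 1.117, 1.143, 1.174, 1.077]
    se_b: [0.036, 0.035, 0.037, 0.047, 0.037, 0.040, 0.042, 0.045]
  category_pct:
    - [37.5, 35.9, 10.7, 9.8, 6.1]
    - [37.3, 34.7, 10.5, 10.9, 6.6]
    - [47.3, 27.6, 10.7, 9.8, 4.7]
    - [61.1, 18.9, 9.2, 7.0, 3.7]
    - [49.6, 25.4, 10.8, 9.1, 5.1]
    - [49.4, 25.8, 10.3, 9.3, 5.2]
    - [43.1, 30.8, 12.0, 9.3, 4.8]
    - [39.3, 31.0, 11.6, 11.8, 6.4]
  pct_endorsed: [15.8, 17.5, 14.4, 10.7, 14.1, 14.5, 14.1, 18.2]

phq9:
  name: PHQ-9
  n_items: 9
  max_per_item: 3
  cutoff: 10
gad7:
  name: GAD-7
  n_items: 7
  max_per_item: 3
  cutoff: 10
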