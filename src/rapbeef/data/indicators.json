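[
  {"id": "PE1", "level": "farm", "dimension": "economic", "name": "Economic growth - added value per farm", "unit": "USD", "polarity": "higher-is-better", "orientation": "ascending", "edges": [1162.43, 1929.75, 2697.05, 3464.35, 4231.65, 4998.96, null]},
  {"id": "PE2", "level": "farm", "dimension": "economic", "name": "Income distribution - share of large-scale farms", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 8.0, 16.0, 24.0, 32.0, 40.0, null]},
  {"id": "PE3", "level": "farm", "dimension": "economic", "name": "Self-sufficiency - beef supply vs demand", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "PE4", "level": "farm", "dimension": "economic", "name": "Investment cost - share of insured cattle", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "PS1", "level": "farm", "dimension": "social", "name": "Employees per enterprise - farmers per farm", "unit": "ratio", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.51, 0.96, 1.41, 1.87, 2.32, 2.77, null]},
  {"id": "PS2", "level": "farm", "dimension": "social", "name": "Gender equality - share of female farmers", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, null]},
  {"id": "PS3", "level": "farm", "dimension": "social", "name": "Education level - farmers above senior high school", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "PS4", "level": "farm", "dimension": "social", "name": "Animal welfare - share of infected cattle", "unit": "%", "polarity": "lower-is-better", "orientation": "descending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "PL1", "level": "farm", "dimension": "environmental", "name": "Water consumption cost for livestock activities", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [178440.63, 347082.94, 515725.24, 684367.55, 853009.86, 1021652.16, null]},
  {"id": "PL2", "level": "farm", "dimension": "environmental", "name": "Energy used - electricity cost for livestock activities", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [503.65, 1538.88, 2574.11, 3609.34, 4644.57, 5679.80, null]},
  {"id": "PL3", "level": "farm", "dimension": "environmental", "name": "Global warming - fuel cost of cattle transport", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [345.34, 773.96, 1122.58, 1466.55, 1811.88, 2157.22, null]},
  {"id": "RE1", "level": "slaughterhouse", "dimension": "economic", "name": "Economic growth - added value per labourer", "unit": "USD", "polarity": "higher-is-better", "orientation": "ascending", "edges": [9533.17, 14299.81, 27646.26, 40992.72, 54339.17, 67685.63, null]},
  {"id": "RE2", "level": "slaughterhouse", "dimension": "economic", "name": "Self-sufficiency - beef supply vs demand", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "RS1", "level": "slaughterhouse", "dimension": "social", "name": "Employees per enterprise - workers per slaughterhouse", "unit": "ratio", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.5, 3.8, 7.1, 10.4, 13.7, 17.0, null]},
  {"id": "RS2", "level": "slaughterhouse", "dimension": "social", "name": "Gender equality - share of female workers", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, null]},
  {"id": "RS3", "level": "slaughterhouse", "dimension": "social", "name": "Education level - workers above senior high school", "unit": "%", "polarity": "higher-is-better", "orientation": "ascending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "RS4", "level": "slaughterhouse", "dimension": "social", "name": "Animal welfare - share of infected cattle at slaughter", "unit": "%", "polarity": "lower-is-better", "orientation": "descending", "edges": [0.0, 20.0, 40.0, 60.0, 80.0, 100.0, null]},
  {"id": "RL1", "level": "slaughterhouse", "dimension": "environmental", "name": "Water consumption cost for slaughter activities", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [25.7, 103.45, 181.19, 258.94, 336.68, 414.43, null]},
  {"id": "RL2", "level": "slaughterhouse", "dimension": "environmental", "name": "Energy used - electricity cost for slaughter activities", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [0.0, 84.03, 168.06, 252.09, 336.12, 420.16, null]},
  {"id": "RL3", "level": "slaughterhouse", "dimension": "environmental", "name": "Global warming - fuel cost of cattle transport", "unit": "USD", "polarity": "lower-is-better", "orientation": "descending", "edges": [345.34, 773.96, 1122.58, 1466.55, 1811.88, 2157.22, null]}
]
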