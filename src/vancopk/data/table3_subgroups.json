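[
  {"label": "3 months-1 year, SCR 10-30", "age_band": [0.25, 1.0], "scr_band": [10.0, 30.0], "n": 1000},
  {"label": "1-4 years, SCR 10-30", "age_band": [1.0, 4.0], "scr_band": [10.0, 30.0], "n": 1000},
  {"label": "1-4 years, SCR 30-50", "age_band": [1.0, 4.0], "scr_band": [30.0, 50.0], "n": 1000},
  {"label": "4-10 years, SCR 20-40", "age_band": [4.0, 10.0], "scr_band": [20.0, 40.0], "n": 1000},
  {"label": "4-10 years, SCR 40-60", "age_band": [4.0, 10.0], "scr_band": [40.0, 60.0], "n": 1000},
  {"label": "10-16 years, SCR 30-60", "age_band": [10.0, 16.0], "scr_band": [30.0, 60.0], "n": 1000},
  {"label": "10-16 years, SCR 60-80", "age_band": [10.0, 16.0], "scr_band": [60.0, 80.0], "n": 1000},
  {"label": "16-18 years, SCR 50-80", "age_band": [16.0, 18.0], "scr_band": [50.0, 80.0], "n": 1000},
  {"label": "16-18 years, SCR 80-110", "age_band": [16.0, 18.0], "scr_band": [80.0, 110.0], "n": 1000}
]
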