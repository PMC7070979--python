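{
  "comment": "Canonical parameter registry of the 26 time-domain feature variants. Coefficients b, c and fractional d/e are dyadic (exactly representable as m/2^k, k<=8); d=6/1/16 and e=1 are integer gains. ub/lb are saturation bounds on the feature accumulator; 65535 = 2^16-1 means effectively unbounded.",
  "features": [
    {"name": "ZCR1",  "family": "ZCR", "b": 0.9961, "hyst": 0,    "lb": 0,    "ub": 65535},
    {"name": "ZCR2",  "family": "ZCR", "b": 0.9961, "hyst": 242,  "lb": 0,    "ub": 65535},
    {"name": "ZCR2S", "family": "ZCR", "b": 0.9961, "hyst": 242,  "lb": 0,    "ub": 1000},
    {"name": "MCR1",  "family": "MCR", "b": 0.9961, "c": 0.8750, "d": 6, "e": 1,      "delay": 8, "hyst": 1044, "lb": 0,    "ub": 65535},
    {"name": "MCR1S", "family": "MCR", "b": 0.9961, "c": 0.8750, "d": 6, "e": 1,      "delay": 8, "hyst": 1044, "lb": 2000, "ub": 3600},
    {"name": "MCR2",  "family": "MCR", "b": 0.9922, "c": 0.9688, "d": 1, "e": 0.0313, "delay": 8, "hyst": 0,    "lb": 0,    "ub": 65535},
    {"name": "SSC1",  "family": "SSC", "b": 0.9961, "c": 0.9922, "dmin": 0, "dmax": 65535, "lb": 0,    "ub": 65535},
    {"name": "SSC1S", "family": "SSC", "b": 0.9961, "c": 0.9922, "dmin": 0, "dmax": 65535, "lb": 2000, "ub": 5000},
    {"name": "SSC2",  "family": "SSC", "b": 0.9961, "c": 0.5,    "dmin": 0, "dmax": 65535, "lb": 0,    "ub": 65535},
    {"name": "SSC2S", "family": "SSC", "b": 0.9961, "c": 0.5,    "dmin": 0, "dmax": 65535, "lb": 0,    "ub": 14000},
    {"name": "SSC3",  "family": "SSC", "b": 0.9961, "c": 0.9961, "dmin": 5, "dmax": 65535, "lb": 0,    "ub": 65535},
    {"name": "SSC3S", "family": "SSC", "b": 0.9961, "c": 0.9961, "dmin": 5, "dmax": 65535, "lb": 900,  "ub": 2000},
    {"name": "SSC4",  "family": "SSC", "b": 0.9961, "c": 0.9961, "dmin": 0, "dmax": 1,     "lb": 0,    "ub": 65535},
    {"name": "SSC5",  "family": "SSC", "b": 0.9961, "c": 0.75,   "dmin": 3, "dmax": 200,   "lb": 0,    "ub": 65535},
    {"name": "SSC5S", "family": "SSC", "b": 0.9961, "c": 0.75,   "dmin": 3, "dmax": 200,   "lb": 1500, "ub": 3000},
    {"name": "WFL1",  "family": "WFL", "b": 0.9961, "d": 0.0078, "lb": 0, "ub": 65535},
    {"name": "WFL1S", "family": "WFL", "b": 0.9961, "d": 0.0078, "lb": 0, "ub": 1300},
    {"name": "WFL2S", "family": "WFL", "b": 0.9922, "d": 0.0156, "lb": 0, "ub": 1894},
    {"name": "MAV1",  "family": "MAV1", "b": 0.9961, "delay": 0, "lb": 0, "ub": 65535},
    {"name": "MAV1S", "family": "MAV1", "b": 0.9961, "delay": 0, "lb": 0, "ub": 600},
    {"name": "MAV2",  "family": "MAV2", "b": 0.9375, "c": 0.9961, "delay": 8, "lb": 0, "ub1": 65535, "ub2": 65535},
    {"name": "MAV2S", "family": "MAV2", "b": 0.9375, "c": 0.9961, "delay": 8, "lb": 0, "ub1": 4000,  "ub2": 6000},
    {"name": "WAM1",  "family": "WAM1", "b": 0.9922, "thresh": 44,   "lb": 0, "ub": 65535, "update_value": 100},
    {"name": "WAM2",  "family": "WAM2", "b": 0.9961, "c": 0.9922, "d": 16, "delay": 64, "thresh": 3636, "lb": 0, "ub": 65535, "update_value": 10},
    {"name": "VAR",   "family": "VAR", "b": 0.9961, "lb": 0, "ub": 65535},
    {"name": "VARS",  "family": "VAR", "b": 0.9961, "lb": 0, "ub": 4000}
  ]
}
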