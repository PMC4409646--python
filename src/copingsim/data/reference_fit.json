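{
  "best_parameters": {
    "unit:OFC/ACC:baseline": 0.0,
    "unit:OFC/ACC:tau": 5.0,
    "unit:PL:baseline": 0.0,
    "unit:PL:tau": 5.0,
    "unit:IL:baseline": 0.05,
    "unit:IL:tau": 5.0,
    "unit:ITC:baseline": 0.0,
    "unit:ITC:tau": 4.0,
    "unit:CeA:baseline": -0.44,
    "unit:CeA:tau": 5.0,
    "unit:LC:baseline": 0.3,
    "unit:LC:tau": 5.0,
    "unit:DR:baseline": 0.15,
    "unit:DR:tau": 4.0,
    "unit:mcVTA-DA:baseline": -0.05,
    "unit:mcVTA-DA:tau": 5.0,
    "unit:mlVTA-DA:baseline": 1.1,
    "unit:mlVTA-DA:tau": 5.0,
    "unit:mlVTA-GABA:baseline": 0.7,
    "unit:mlVTA-GABA:tau": 5.0,
    "conn:OFC/ACC->LC": 0.01,
    "conn:CeA->LC": 1.6984624658336032,
    "conn:PL->CeA": 2.3145499620559105,
    "conn:PL->DR": 0.3666810640872475,
    "conn:PL->mlVTA-GABA": 0.05,
    "conn:IL->ITC": 0.6017657791525004,
    "conn:ITC->CeA": 0.4,
    "conn:IL->mlVTA-GABA": 0.5724543737127228,
    "conn:CeA->mlVTA-GABA": 2.050665702645775,
    "conn:mlVTA-GABA->mlVTA-DA": 1.181590329210564,
    "conn:DR->mcVTA-DA": 1.312359174171868,
    "conn:IL->PL": 0.1,
    "pool:vmPFC-NE:tau": 6.8999999999999995,
    "pool:vmPFC-NE:reuptake_threshold": 1.05,
    "pool:vmPFC-NE:release_weight": 1.0,
    "pool:vmPFC-DA:tau": 58.456538769931406,
    "pool:vmPFC-DA:reuptake_threshold": 1.3,
    "pool:vmPFC-DA:release_weight": 1.0,
    "pool:NAcc-DA:tau": 6.714376998814253,
    "pool:NAcc-DA:reuptake_threshold": 1.3,
    "pool:NAcc-DA:release_weight": 1.0,
    "pool:vmPFC-5HT:tau": 20.0,
    "pool:vmPFC-5HT:reuptake_threshold": 1.3,
    "pool:vmPFC-5HT:release_weight": 1.0,
    "mod:vmPFC-NE->PL:mul_excit": 13.17669014600616,
    "mod:vmPFC-NE->IL:mul_inhib": 0.7376550235761103,
    "mod:vmPFC-DA->IL:mul_excit": 5.612950881039897,
    "mod:vmPFC-DA->IL:add_excit": 0.28006610429785705,
    "plastic:IL->PL:learning_rate": 1.4634910741957545,
    "plastic:IL->PL:pre_threshold": 0.03,
    "plastic:IL->PL:post_threshold": 0.3,
    "ext:OFC/ACC": 1.0,
    "ext:PL": 0.16294422477782936,
    "ext:IL": 0.01,
    "ext:CeA": 0.06913646153847475,
    "ext:DR": 0.34952056463229786
  },
  "best_error": 32424.369569333085,
  "error_history": [
    62017.71035804133,
    44082.86219858798,
    43363.90079178543,
    39718.04679122086,
    39068.22324454345,
    39068.22324454345,
    39068.22324454345,
    38767.18034738682,
    37758.29142751241,
    37014.72306770381,
    37014.72306770381,
    35808.09774391585,
    35808.09774391585,
    35771.63365181925,
    35771.63365181925,
    35474.549625559455,
    34699.10431592766,
    34529.35870490412,
    34465.254684756714,
    33822.19766534122,
    33696.97546947199,
    33696.97546947199,
    33645.14707907141,
    33225.04131071369,
    33225.04131071369,
    33225.04131071369,
    33225.04131071369,
    33013.58941060751,
    33013.58941060751,
    32919.860103848776,
    32919.860103848776,
    32915.79095250727,
    32590.709322072427,
    32590.709322072427,
    32560.080879133042,
    32560.080879133042,
    32538.70325504213,
    32538.70325504213,
    32538.70325504213,
    32454.045720534963,
    32424.369569333085
  ],
  "constraints_report": [
    {
      "condition": "sham",
      "analyte": "vmPFC-NE",
      "kind": "peak-in-window",
      "window": [
        20,
        40
      ],
      "passed": true,
      "measured": 40.0
    },
    {
      "condition": "sham",
      "analyte": "vmPFC-NE",
      "kind": "return-by",
      "window": [
        0,
        120
      ],
      "passed": true,
      "measured": 60.0
    },
    {
      "condition": "sham",
      "analyte": "vmPFC-DA",
      "kind": "second-rise-after",
      "window": [
        60,
        120
      ],
      "passed": true,
      "measured": 263.2769521507872
    },
    {
      "condition": "sham",
      "analyte": "NAcc-DA",
      "kind": "peak-in-window",
      "window": [
        20,
        40
      ],
      "passed": true,
      "measured": 40.0
    },
    {
      "condition": "sham",
      "analyte": "NAcc-DA",
      "kind": "below-baseline-after",
      "window": [
        80,
        100
      ],
      "passed": true,
      "measured": 100.0
    },
    {
      "condition": "NE-depleted",
      "analyte": "NAcc-DA",
      "kind": "no-rise",
      "window": [
        0,
        80
      ],
      "passed": true,
      "measured": 100.01440144950429
    },
    {
      "condition": "NE-depleted",
      "analyte": "NAcc-DA",
      "kind": "below-baseline-after",
      "window": [
        120,
        240
      ],
      "passed": true,
      "measured": 140.0
    },
    {
      "condition": "DA-depleted",
      "analyte": "NAcc-DA",
      "kind": "stays-at-baseline",
      "window": [
        0,
        240
      ],
      "passed": true,
      "measured": 99.99588698070781
    },
    {
      "condition": "long",
      "analyte": "NAcc-DA",
      "kind": "below-baseline-after",
      "window": [
        20,
        60
      ],
      "passed": true,
      "measured": 40.0
    },
    {
      "condition": "long",
      "analyte": "NAcc-DA",
      "kind": "no-rise",
      "window": [
        0,
        60
      ],
      "passed": true,
      "measured": 100.01323000817251
    },
    {
      "condition": "long",
      "analyte": "vmPFC-NE",
      "kind": "no-rise",
      "window": [
        0,
        240
      ],
      "passed": true,
      "measured": 102.52350944872745
    },
    {
      "condition": "IL-VTA",
      "analyte": "NAcc-DA",
      "kind": "within-band",
      "window": [
        160,
        240
      ],
      "passed": true,
      "measured": 0.7711964071255011
    }
  ],
  "config": {
    "population_size": 48,
    "generations": 40,
    "crossover_rate": 0.7,
    "mutation_rate": 0.1,
    "mutation_scale": 0.1,
    "tournament_size": 3,
    "elitism_count": 2,
    "seed": 1234,
    "parameter_bounds": {
      "ext:PL": [
        0.1275,
        0.1725
      ],
      "ext:DR": [
        0.2975,
        0.40249999999999997
      ],
      "ext:CeA": [
        0.068,
        0.092
      ],
      "conn:CeA->LC": [
        1.53,
        2.07
      ],
      "conn:PL->CeA": [
        2.21,
        2.9899999999999998
      ],
      "conn:PL->DR": [
        0.323,
        0.43699999999999994
      ],
      "conn:IL->ITC": [
        0.51,
        0.69
      ],
      "conn:ITC->CeA": [
        0.34,
        0.45999999999999996
      ],
      "conn:IL->mlVTA-GABA": [
        0.51,
        0.69
      ],
      "conn:CeA->mlVTA-GABA": [
        1.53,
        2.07
      ],
      "conn:mlVTA-GABA->mlVTA-DA": [
        1.02,
        1.38
      ],
      "conn:DR->mcVTA-DA": [
        1.02,
        1.38
      ],
      "pool:vmPFC-NE:tau": [
        5.1,
        6.8999999999999995
      ],
      "pool:vmPFC-DA:tau": [
        51.0,
        69.0
      ],
      "pool:NAcc-DA:tau": [
        5.95,
        8.049999999999999
      ],
      "mod:vmPFC-NE->PL:mul_excit": [
        10.2,
        13.799999999999999
      ],
      "mod:vmPFC-NE->IL:mul_inhib": [
        0.68,
        0.9199999999999999
      ],
      "mod:vmPFC-DA->IL:mul_excit": [
        5.1,
        6.8999999999999995
      ],
      "mod:vmPFC-DA->IL:add_excit": [
        0.255,
        0.345
      ],
      "plastic:IL->PL:learning_rate": [
        1.36,
        1.8399999999999999
      ]
    }
  }
}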