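{
  "F": {
    "HBA": {
      "a": 472.39370780643577,
      "b": 3.0087973854158245,
      "c": 1.5637056368791027,
      "max_value": 472.39370780643577,
      "o": 7.19882441069587e-23
    },
    "HBD": {
      "a": 873.7151875671516,
      "b": 0.9842196930383222,
      "c": 0.8411163417176915,
      "max_value": 874.4215510615719,
      "o": 0.7063634944203265
    },
    "LogP": {
      "a": 182.54672755040238,
      "b": 3.009067510816419,
      "c": 1.1888921731581248,
      "max_value": 183.86672130193082,
      "o": 1.3199937515284308
    },
    "MW": {
      "a": 133.80186576055942,
      "b": 279.6770076778378,
      "c": 51.95653717496917,
      "max_value": 134.82015874015005,
      "o": 1.018292979590618
    },
    "RB": {
      "a": 481.2668114930519,
      "b": 2.01772667453619,
      "c": 1.5354526634838608,
      "max_value": 481.2668114930519,
      "o": 6.716732850640819e-25
    },
    "arR": {
      "a": 894.3981413015329,
      "b": 0.9592924358546526,
      "c": 0.828982014989245,
      "max_value": 894.3981413015329,
      "o": 1.5198901208054145e-17
    }
  },
  "H": {
    "HBA": {
      "a": 478.6086075864003,
      "b": 4.0138203962433945,
      "c": 1.5427134788396806,
      "max_value": 478.6086075864003,
      "o": 4.3613981460779833e-16
    },
    "HBD": {
      "a": 888.7652640575159,
      "b": 0.9655414861476327,
      "c": 0.8352565071620099,
      "max_value": 888.7652640575159,
      "o": 2.749786170552373e-19
    },
    "LogP": {
      "a": 226.73616565127773,
      "b": 2.5264616142260503,
      "c": 1.2363706138523731,
      "max_value": 226.73616565127773,
      "o": 5.1963912078596663e-17
    },
    "MW": {
      "a": 235.30240365618013,
      "b": 298.0139656698998,
      "c": 62.79205312730336,
      "max_value": 235.30240365618013,
      "o": 1.633366726313904e-27
    },
    "RB": {
      "a": 375.8421319140404,
      "b": 5.015269909325298,
      "c": 1.9612278682369906,
      "max_value": 375.8421319140404,
      "o": 3.9924287238941874e-24
    },
    "arR": {
      "a": 866.3431246795525,
      "b": 1.9971189664109092,
      "c": 0.8536138229865452,
      "max_value": 866.3431246795525,
      "o": 9.934635046701847e-19
    }
  },
  "I": {
    "HBA": {
      "a": 474.84953766203637,
      "b": 3.013727885524264,
      "c": 1.5621785688303322,
      "max_value": 474.84953766203637,
      "o": 2.30876691059277e-22
    },
    "HBD": {
      "a": 896.1886928307746,
      "b": 0.4640589533435539,
      "c": 0.828334092692141,
      "max_value": 898.8365526414804,
      "o": 2.6478598107057425
    },
    "LogP": {
      "a": 159.83065608086326,
      "b": 4.458001826257484,
      "c": 1.5023853501819808,
      "max_value": 159.83065608086326,
      "o": 1.9447093594575093e-17
    },
    "MW": {
      "a": 259.7264247835372,
      "b": 320.93543975476194,
      "c": 70.57657193825594,
      "max_value": 260.1677261770912,
      "o": 0.441301393553992
    },
    "RB": {
      "a": 297.5077929590124,
      "b": 5.994006958082739,
      "c": 2.489793624631235,
      "max_value": 297.5077929590124,
      "o": 3.0198929662170094e-23
    },
    "arR": {
      "a": 1077.1503950291446,
      "b": 0.09755926631856035,
      "c": 0.5798684737796445,
      "max_value": 1108.6516227001198,
      "o": 31.5012276709752
    }
  }
}
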