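{
  "config": {
    "inputs": {
      "mapping": "mapping.tsv",
      "mie_list": "mies.tsv",
      "regulons": "regulons.tsv",
      "signature": "signature.tsv"
    },
    "output_dir": ".",
    "seed": 20240605,
    "simulate": {
      "chemicals": [
        {
          "class": "PFAS",
          "doses": [
            12,
            111,
            1000
          ],
          "name": "6:1 FTOH"
        },
        {
          "class": "PAH",
          "doses": [
            12,
            111,
            1000
          ],
          "name": "2,3-Benzofluorene"
        }
      ],
      "effects": [
        {
          "classes": [
            "PFAS"
          ],
          "direction": "up",
          "max_log2fc": 2.0,
          "tf": "Ppara"
        },
        {
          "direction": "down",
          "max_log2fc": 1.5,
          "sex_directions": {
            "female": "up",
            "male": "down"
          },
          "tf": "Hnf4a"
        },
        {
          "class_directions": {
            "PAH": "up",
            "PFAS": "down"
          },
          "direction": "up",
          "max_log2fc": 1.5,
          "tf": "Ahr"
        }
      ],
      "mode": "lognormal",
      "n_control": 4,
      "n_genes": 40,
      "n_treated": 3,
      "noise_sd": 0.4
    },
    "thresholds": {
      "down": -0.6,
      "min_median_corr": 0.8,
      "min_support": 1.0,
      "q": 0.1,
      "top_doses": 3,
      "trend_window": 3,
      "up": 0.6
    }
  },
  "counts": {
    "concordance_rows": 24,
    "fc_records": 480,
    "genes": 40,
    "mies": 6,
    "profile_rows": 72,
    "regulon_edges": 29,
    "response_calls": 40,
    "samples": 52,
    "samples_failed_qc": 0,
    "samples_flagged_outlier": 0
  },
  "inputs": {
    "mapping": "5675077d2b36f0cd99ae94c85776b5d6705eed5bc16531377b159a6561f082f3",
    "mie_list": "e4d20c960b508e82f29f8d14491082659672867228873b79c95724ac38b165d5",
    "regulons": "f370127cefa2b5bbfb9b6645a1025ef0607a11d7c2642ab3790fb91d1d6b4d35",
    "signature": "0efb3dc8dd133bdbf891df1903da4227c7b42960b98fd83c553c4613346b1dc2"
  },
  "seed": 20240605,
  "status": "ok",
  "warnings": []
}
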