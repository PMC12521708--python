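{
  "version": "cdc-oral-mme-2016/strengths-ch-2024",
  "_provenance": "Oral-route morphine milligram equivalent conversion factors as published by the US Centers for Disease Control and Prevention (2016 guideline edition). The 2022 edition revises some factors; this table is configuration, not code - load a replacement file to use different factors. Tablet strengths and pack sizes reflect formulations commonly marketed in Switzerland/Europe. Methadone is excluded (nonlinear conversion).",
  "opioids": [
    {
      "name": "morphine",
      "ome_factor": 1.0,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 10, "release": "immediate", "units_per_pack": 20},
        {"strength_mg": 20, "release": "immediate", "units_per_pack": 20},
        {"strength_mg": 10, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 30, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 60, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 100, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "oxycodone",
      "ome_factor": 1.5,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 5, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 10, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 20, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 5, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 10, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 20, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 40, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "hydromorphone",
      "ome_factor": 4.0,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 1.3, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 2.6, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 4, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 8, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 16, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 24, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "oxymorphone",
      "ome_factor": 3.0,
      "is_backup_suitable": false,
      "formulations": [
        {"strength_mg": 5, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 10, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 20, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "tapentadol",
      "ome_factor": 0.4,
      "is_backup_suitable": false,
      "formulations": [
        {"strength_mg": 50, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 100, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 150, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 200, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "tramadol",
      "ome_factor": 0.1,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 50, "release": "immediate", "units_per_pack": 20},
        {"strength_mg": 100, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 150, "release": "extended", "units_per_pack": 30},
        {"strength_mg": 200, "release": "extended", "units_per_pack": 30}
      ]
    },
    {
      "name": "codeine",
      "ome_factor": 0.15,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 30, "release": "immediate", "units_per_pack": 20},
        {"strength_mg": 60, "release": "immediate", "units_per_pack": 20}
      ]
    },
    {
      "name": "hydrocodone",
      "ome_factor": 1.0,
      "is_backup_suitable": true,
      "formulations": [
        {"strength_mg": 5, "release": "immediate", "units_per_pack": 30},
        {"strength_mg": 10, "release": "immediate", "units_per_pack": 30}
      ]
    }
  ]
}
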