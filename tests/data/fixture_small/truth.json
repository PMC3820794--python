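{
 "digest": "5d36688383648b5bf909fe543c78e0b40066f8c6ddf28a78dd0e1ea075710c98",
 "locus_set_hash": "9867c2aca7213322fdd5f81125c7b0c068a1923eb3ef883900843945ea17375b",
 "model": "ICS",
 "root_seed": 20130719,
 "values": {
  "N_anc": 80000.0,
  "N_coll": 60000.0,
  "N_pied": 40000.0,
  "T_split": 300000.0,
  "alpha": 3.0,
  "mu": 1e-08,
  "r": 5.3e-08
 }
}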