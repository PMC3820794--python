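{
 "dataset": {
  "fst_mean": 0.8306878306878307,
  "fst_var": 0.0020996052742084485,
  "pi_coll_mean": 0.001670854271356784,
  "pi_coll_var": 3.7223854242363885e-06,
  "pi_pied_mean": 0.000625,
  "pi_pied_var": 1.5625e-06,
  "pi_pooled_mean": 0.004538083031801625,
  "pi_pooled_var": 1.0497953886626753e-05,
  "prop_fixed": 0.5714285714285714,
  "prop_private_coll": 0.2857142857142857,
  "prop_private_pied": 0.14285714285714285,
  "prop_shared": 0.0,
  "tajd_coll_mean": 1.6329931618554543,
  "tajd_coll_var": 0.0,
  "tajd_pied_mean": -0.6123724356957968,
  "tajd_pied_var": 0.0
 },
 "per_locus": [
  {
   "fst": 0.7777777777777778,
   "locus_id": "locus_0000",
   "n_assayable": {
    "coll": 200,
    "joint": 200,
    "pied": 200
   },
   "partition": [
    0,
    1,
    1,
    0
   ],
   "pi_coll": 0.003333333333333333,
   "pi_pied": 0.0,
   "pi_pooled": 0.004809523809523809,
   "tajd_coll": 1.6329931618554543,
   "tajd_pied": NaN
  },
  {
   "fst": 0.8571428571428571,
   "locus_id": "locus_0001",
   "n_assayable": {
    "coll": 199,
    "joint": 198,
    "pied": 199
   },
   "partition": [
    0,
    2,
    1,
    0
   ],
   "pi_coll": 0.003350083752093802,
   "pi_pied": 0.0,
   "pi_pooled": 0.0075998075998075995,
   "tajd_coll": NaN,
   "tajd_pied": NaN
  },
  {
   "fst": NaN,
   "locus_id": "locus_0002",
   "n_assayable": {
    "coll": 198,
    "joint": 198,
    "pied": 200
   },
   "partition": [
    0,
    0,
    0,
    0
   ],
   "pi_coll": 0.0,
   "pi_pied": 0.0,
   "pi_pooled": 0.0,
   "tajd_coll": NaN,
   "tajd_pied": NaN
  },
  {
   "fst": 0.8571428571428572,
   "locus_id": "locus_0003",
   "n_assayable": {
    "coll": 199,
    "joint": 199,
    "pied": 200
   },
   "partition": [
    0,
    1,
    0,
    1
   ],
   "pi_coll": 0.0,
   "pi_pied": 0.0025,
   "pi_pooled": 0.005743000717875089,
   "tajd_coll": NaN,
   "tajd_pied": -0.6123724356957968
  }
 ]
}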