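{
 "snps": [
  {
   "snp_id": "rs2476601",
   "risk_allele": "A",
   "or": 2.3,
   "chromosome": "1"
  },
  {
   "snp_id": "rs3024505",
   "risk_allele": "G",
   "or": 1.1,
   "chromosome": "1"
  },
  {
   "snp_id": "rs1990760",
   "risk_allele": "T",
   "or": 1.05,
   "chromosome": "2"
  },
  {
   "snp_id": "rs3087243",
   "risk_allele": "G",
   "or": 1.15,
   "chromosome": "2"
  },
  {
   "snp_id": "rs11711054",
   "risk_allele": "A",
   "or": 0.86,
   "chromosome": "3"
  },
  {
   "snp_id": "rs17388568",
   "risk_allele": "A",
   "or": 1.05,
   "chromosome": "4"
  },
  {
   "snp_id": "rs11755527",
   "risk_allele": "G",
   "or": 0.94,
   "chromosome": "6"
  },
  {
   "snp_id": "rs1738074",
   "risk_allele": "C",
   "or": 1.12,
   "chromosome": "6"
  },
  {
   "snp_id": "rs1574285",
   "risk_allele": "G",
   "or": 1.1,
   "chromosome": "9"
  },
  {
   "snp_id": "rs12722495",
   "risk_allele": "T",
   "or": 1.58,
   "chromosome": "10"
  },
  {
   "snp_id": "rs2104286",
   "risk_allele": "T",
   "or": 1.78,
   "chromosome": "10"
  },
  {
   "snp_id": "rs689",
   "risk_allele": "T",
   "or": 2.35,
   "chromosome": "11"
  },
  {
   "snp_id": "rs2292239",
   "risk_allele": "T",
   "or": 1.25,
   "chromosome": "12"
  },
  {
   "snp_id": "rs10877012",
   "risk_allele": "G",
   "or": 1.07,
   "chromosome": "12"
  },
  {
   "snp_id": "rs653178",
   "risk_allele": "C",
   "or": 1.3,
   "chromosome": "12"
  },
  {
   "snp_id": "rs3825932",
   "risk_allele": "C",
   "or": 1.0,
   "chromosome": "15"
  },
  {
   "snp_id": "rs4788084",
   "risk_allele": "C",
   "or": 1.3,
   "chromosome": "16"
  },
  {
   "snp_id": "rs7202877",
   "risk_allele": "G",
   "or": 1.56,
   "chromosome": "16"
  },
  {
   "snp_id": "rs2290400",
   "risk_allele": "C",
   "or": 1.09,
   "chromosome": "17"
  },
  {
   "snp_id": "rs7221109",
   "risk_allele": "T",
   "or": 1.05,
   "chromosome": "17"
  },
  {
   "snp_id": "rs1893217",
   "risk_allele": "G",
   "or": 1.28,
   "chromosome": "18"
  },
  {
   "snp_id": "rs763361",
   "risk_allele": "T",
   "or": 1.3,
   "chromosome": "18"
  },
  {
   "snp_id": "rs2304256",
   "risk_allele": "C",
   "or": 1.07,
   "chromosome": "19"
  },
  {
   "snp_id": "rs602662",
   "risk_allele": "A",
   "or": 0.99,
   "chromosome": "19"
  },
  {
   "snp_id": "rs2281808",
   "risk_allele": "C",
   "or": 0.99,
   "chromosome": "20"
  },
  {
   "snp_id": "rs11203203",
   "risk_allele": "A",
   "or": 1.21,
   "chromosome": "21"
  },
  {
   "snp_id": "rs229541",
   "risk_allele": "G",
   "or": 1.15,
   "chromosome": "22"
  },
  {
   "snp_id": "rs2664170",
   "risk_allele": "G",
   "or": 0.89,
   "chromosome": "X"
  }
 ],
 "haplotype_or": {
  "non_dq6": 7.52,
  "a24": 0.72,
  "non_b57": 2.91
 },
 "hla_diplotype_or": {
  "DR3_DR4": 9.95,
  "DR4_DR4": 2.3,
  "DR3_DR3": 30.56,
  "DR4_X": 1.69,
  "DR3_X": 0.75,
  "X_X": 0.14
 },
 "hla_tags": {
  "dr3": "rs2187668",
  "dr4": "rs7454108",
  "dq6": "rs3129889",
  "a24": "rs1264813",
  "b57": "rs2395029"
 },
 "tag_alleles": {
  "rs2187668": "T",
  "rs7454108": "C",
  "rs3129889": "G",
  "rs1264813": "A",
  "rs2395029": "G"
 },
 "protective_tags": [
  "rs3129889",
  "rs2395029"
 ]
}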