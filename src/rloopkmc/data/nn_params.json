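{
  "dna_dna": {
    "AA": -1.0,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45,
    "GT": -1.44,
    "CT": -1.28,
    "GA": -1.3,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84
  },
  "rna_dna": {
    "AA": -1.0,
    "AC": -2.1,
    "AG": -1.8,
    "AU": -0.9,
    "CA": -0.9,
    "CC": -2.1,
    "CG": -1.7,
    "CU": -0.9,
    "GA": -1.3,
    "GC": -2.7,
    "GG": -2.9,
    "GU": -1.1,
    "UA": -0.6,
    "UC": -1.5,
    "UG": -1.6,
    "UU": -0.2
  },
  "mismatch": {
    "GA/GT": -1.05,
    "AG/TG": -1.05,
    "GC/GG": -1.35,
    "CG/GG": -1.35,
    "GG/GC": -1.35,
    "GG/CG": -1.35,
    "GU/GA": -1.05,
    "UG/AG": -1.05,
    "UA/TT": -0.35,
    "AU/TT": -0.35,
    "UC/TG": -0.65,
    "CU/GT": -0.65,
    "UG/TC": -0.65,
    "GU/CT": -0.65,
    "UU/TA": -0.35,
    "UU/AT": -0.35,
    "AA/AT": 0.0,
    "AA/TA": 0.0,
    "AC/AG": -0.3,
    "CA/GA": -0.3,
    "AG/AC": -0.3,
    "GA/CA": -0.3,
    "AU/AA": 0.0,
    "UA/AA": 0.0,
    "CA/CT": 0.25,
    "AC/TC": 0.25,
    "CC/CG": -0.05,
    "CC/GC": -0.05,
    "CG/CC": -0.05,
    "GC/CC": -0.05,
    "CU/CA": 0.25,
    "UC/AC": 0.25
  },
  "dg_init": -3.1,
  "temperature_K": 310.15,
  "gas_constant_kcal_per_mol_K": 0.001987,
  "salt_label": "1 M NaCl",
  "provenance": {
    "dna_dna": "SantaLucia (1998) PNAS 95:1460, unified DNA:DNA nearest-neighbour dG37, 1 M NaCl; 10 unique doublets, others by reverse-complement identity",
    "rna_dna": "Sugimoto et al. (1995) Biochemistry 34:11211, RNA/DNA hybrid nearest-neighbour dG37, 1 M NaCl; keys are the RNA strand doublet 5'->3'",
    "mismatch": "Representative doublet values for single rG.dG/rC.dC/rA.dA/rU.dT mismatches in RNA/DNA hybrids, constructed to reproduce published summary trends (mean Tm depression ~1.7 C; context-dependent rG.dG stabilization); replace with measured sequence-context parameters if available. Keys: guide RNA doublet 5'->3' '/' bound DNA-strand bases aligned antiparallel opposite each guide base.",
    "dg_init": "duplex initiation correction, kcal/mol, applied once per duplex (note: negative sign, opposite to common initiation penalties; configurable)"
  }
}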