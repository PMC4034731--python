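{
  "intercept": 14.911,
  "coefficients": {
    "ES_Count_aaCH": 80.578,
    "ES_Count_sOH": -27.224,
    "ES_Sum_aaCH": -44.517,
    "ES_Sum_sssN": 16.799,
    "Num_Rings6": -27.187,
    "Molecular_PolarSurfaceArea": 0.90601,
    "CHI_2": -9.6615,
    "Jurs_TPSA": -0.13155,
    "Minimized_Energy": -1.1131,
    "Shadow_Ylength": 13.232
  },
  "r_squared": 0.9402,
  "metadata": {
    "source": "bundled GFA linear scoring equation for FKBP52 pIC50",
    "note": "usable without retraining; training ligands are not distributed"
  }
}
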