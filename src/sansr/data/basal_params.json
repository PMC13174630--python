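{
 "format": "sansr-cell-params-v1",
 "note": "Basal parameter set of the common-pool coupled-clock cell model (versioned fixture).",
 "params": {
  "CM_tot": 0.045,
  "CQ_tot": 10.0,
  "C_m": 32.0,
  "Ca_o": 2.0,
  "EC50_SR": 0.45,
  "E_CaL": 45.0,
  "E_CaT": 45.0,
  "E_st": 37.4,
  "H_SR": 2.5,
  "I_NaK_max": 2.88,
  "K_i": 140.0,
  "K_o": 5.4,
  "K_up": 0.001,
  "Max_SR": 15.0,
  "Mg_i": 2.5,
  "Min_SR": 1.0,
  "Na_i": 10.0,
  "Na_o": 140.0,
  "P_up": 12.0,
  "TC_tot": 0.031,
  "TMC_tot": 0.062,
  "V_If_shift": 0.0,
  "V_i": 1.58345,
  "V_jSR": 0.0042231,
  "V_nSR": 0.040815,
  "V_sub": 0.035098,
  "g_CaL": 0.464,
  "g_CaT": 0.1832,
  "g_If": 0.15,
  "g_KACh": 0.0,
  "g_Kr": 0.08113973,
  "g_Ks": 0.0259,
  "g_bNa": 0.000486,
  "g_st": 0.021,
  "g_sus": 0.02,
  "g_to": 0.252,
  "k_NCX": 187.5,
  "k_iCa": 500.0,
  "k_im": 5.0,
  "k_oCa": 10000.0,
  "k_om": 60.0,
  "k_s": 30000000.0,
  "kb_CM": 542.0,
  "kb_CQ": 445.0,
  "kb_TC": 446.0,
  "kb_TMC": 7.51,
  "kb_TMM": 751.0,
  "kf_CM": 227700.0,
  "kf_CQ": 534.0,
  "kf_TC": 88800.0,
  "kf_TMC": 227700.0,
  "kf_TMM": 2277.0,
  "lcr_duration": 0.02,
  "lcr_flux": 1.0,
  "lcr_rate": 5.0,
  "tau_dif_Ca": 4e-05,
  "tau_tr": 0.04,
  "temperature": 310.15
 }
}
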