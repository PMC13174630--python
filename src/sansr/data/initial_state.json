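{
 "format": "sansr-cell-state-v1",
 "note": "Late-diastolic state of the basal model after a 25 s settling run (fixture).",
 "state": {
  "Ca_i": 0.00020621381603039933,
  "Ca_jSR": 0.41645484595474525,
  "Ca_nSR": 1.4275237724336547,
  "Ca_sub": 0.00012797527076769538,
  "RyR_I": 1.1794167401778509e-07,
  "RyR_O": 2.5105098373708927e-07,
  "RyR_R": 0.6803632526638714,
  "RyR_RI": 0.31963837834342046,
  "V_m": -60.63216243638641,
  "d_L": 0.0003812515886718524,
  "d_T": 0.003250236747765376,
  "f_CMi": 0.08030490108269474,
  "f_CMs": 0.05111293784650948,
  "f_CQ": 0.33042095396586724,
  "f_Ca": 0.6696629743321197,
  "f_L": 0.7308297181512126,
  "f_T": 0.3468994287882078,
  "f_TC": 0.039821868348596044,
  "f_TMC": 0.5146157024548534,
  "f_TMM": 0.42864730054213496,
  "n": 0.025335171126676284,
  "p_i": 0.867556855335423,
  "pa_F": 0.2873697050713224,
  "pa_S": 0.49912966500421807,
  "q": 0.624776971975606,
  "q_a": 0.3169022458390374,
  "q_i": 0.417602648675379,
  "r": 0.004766429950406243,
  "y": 0.08030096255525615
 }
}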