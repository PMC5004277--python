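# Ultrafine grinding corn stover (UGCS) reference system.
# Units: cm, min, mg, mL, g; compositions in % dry matter.
composition:
  M_c: 33.38
  M_h: 17.47
  M_l: 24.35
  M_o: 24.80
  rho_c: 1.52
  rho_h: 1.56
  rho_l: 1.39
  rho_o: 2.50
particle:
  R: 0.18e-2
  V_p: 0.024
  V_pa: 0.023
batch:
  m: 0.1
  V_L: 5.0
  C_0: 0.133
langmuir:
  q_m: 5.61
  K_a: 11.5
transport:
  K_L: 0.14
  D_p: 6.04e-6
  D_s: 1.02e-8
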