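# Sieve-based grinding corn stover (SGCS) reference system.
# Units: cm, min, mg, mL, g; compositions in % dry matter.
composition:
  M_c: 33.44
  M_h: 17.58
  M_l: 25.21
  M_o: 23.77
  rho_c: 1.52
  rho_h: 1.56
  rho_l: 1.39
  rho_o: 2.50
particle:
  R: 2.18e-2
  V_p: 0.009
  V_pa: 0.008
batch:
  m: 0.1
  V_L: 5.0
  C_0: 0.133
langmuir:
  q_m: 2.83
  K_a: 6.22
transport:
  K_L: 1.53
  D_p: 9.45e-7
  D_s: 3.42e-5
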