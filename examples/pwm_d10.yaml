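format_version: 1
name: repressilator+shaper
species:
- name: p_lacI
  initial: 0.7
- name: p_tetR
  initial: 1.2
- name: p_cI
  initial: 1.7
- name: p1
  initial: 0.0
- name: p2
  initial: 0.0
- name: p3
  initial: 0.0
- name: p4
  initial: 0.0
- name: p5
  initial: 0.0
- name: p6
  initial: 0.0
gates:
- output: p_lacI
  kind: NOT
  kinetics:
    rho: 0.34255
    gamma: 0.1165
    rho0: 0.0
  regulators:
  - source: p_cI
    K: 1.0
    n: 4.0
- output: p_tetR
  kind: NOT
  kinetics:
    rho: 0.34255
    gamma: 0.1165
    rho0: 0.0
  regulators:
  - source: p_lacI
    K: 1.0
    n: 4.0
- output: p_cI
  kind: NOT
  kinetics:
    rho: 0.34255
    gamma: 0.1165
    rho0: 0.0
  regulators:
  - source: p_tetR
    K: 1.0
    n: 4.0
- output: p1
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p_cI
    K: 1.76
    n: 4.0
- output: p2
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p1
    K: 0.5
    n: 4.0
- output: p3
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p2
    K: 0.5
    n: 4.0
- output: p4
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p3
    K: 0.5
    n: 4.0
- output: p5
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p4
    K: 0.5
    n: 4.0
- output: p6
  kind: BUFFER
  kinetics:
    rho: 1.0872
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p5
    K: 0.5
    n: 4.0
solver:
  t_end: 500.0
  dt_output: 0.01
  rel_tol: 1.0e-08
  abs_tol: 1.0e-10
  stiff: true
provenance:
  duty_target: 0.1
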