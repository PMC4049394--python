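format_version: 1
name: repressilator+shaper+shaper+mod3_counter
species:
- name: p_lacI
  initial: 0.7
- name: p_tetR
  initial: 1.2
- name: p_cI
  initial: 1.7
- name: clkA_1
  initial: 0.0
- name: clkA_2
  initial: 0.0
- name: clkA_3
  initial: 0.0
- name: clkA_4
  initial: 0.0
- name: clkA_5
  initial: 0.0
- name: clkA_6
  initial: 0.0
- name: clkB_1
  initial: 0.0
- name: clkB_2
  initial: 0.0
- name: clkB_3
  initial: 0.0
- name: clkB_4
  initial: 0.0
- name: clkB_5
  initial: 0.0
- name: clkB_6
  initial: 0.0
- name: ff1.W
  initial: 0.0
- name: ff1.V
  initial: 0.0
- name: ff1.R
  initial: 0.0
- name: ff1.S
  initial: 0.0
- name: ff1.Q
  initial: 0.0
- name: ff1.Qbar
  initial: 1.0
- name: ff2.W
  initial: 0.0
- name: ff2.V
  initial: 0.0
- name: ff2.R
  initial: 0.0
- name: ff2.S
  initial: 0.0
- name: ff2.Q
  initial: 0.0
- name: ff2.Qbar
  initial: 1.0
- name: ff3.W
  initial: 0.0
- name: ff3.V
  initial: 0.0
- name: ff3.R
  initial: 0.0
- name: ff3.S
  initial: 0.0
- name: ff3.Q
  initial: 0.0
- name: ff3.Qbar
  initial: 1.0
- name: G1
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
- output: clkA_1
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p_cI
    K: 1.76
    n: 4.0
- output: clkA_2
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkA_1
    K: 0.5
    n: 4.0
- output: clkA_3
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkA_2
    K: 0.5
    n: 4.0
- output: clkA_4
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkA_3
    K: 0.5
    n: 4.0
- output: clkA_5
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkA_4
    K: 0.5
    n: 4.0
- output: clkA_6
  kind: BUFFER
  kinetics:
    rho: 1.0872
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkA_5
    K: 0.5
    n: 4.0
- output: clkB_1
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: p_cI
    K: 0.6761
    n: 4.0
- output: clkB_2
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkB_1
    K: 0.5
    n: 4.0
- output: clkB_3
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkB_2
    K: 0.5
    n: 4.0
- output: clkB_4
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkB_3
    K: 0.5
    n: 4.0
- output: clkB_5
  kind: BUFFER
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkB_4
    K: 0.5
    n: 4.0
- output: clkB_6
  kind: BUFFER
  kinetics:
    rho: 1.1083
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: clkB_5
    K: 0.5
    n: 4.0
- output: ff1.W
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: one
    K: 0.5
    n: 4.0
  - source: clkA_6
    K: 0.5
    n: 4.0
- output: ff1.V
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.Qbar
    K: 0.5
    n: 4.0
  - source: clkA_6
    K: 0.5
    n: 4.0
- output: ff1.R
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff1.W
    K: 0.5
    n: 4.0
  - source: ff1.Q
    K: 0.5
    n: 4.0
- output: ff1.S
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff1.V
    K: 0.5
    n: 4.0
  - source: ff1.Qbar
    K: 0.5
    n: 4.0
- output: ff1.Q
  kind: NOR
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff1.R
    K: 0.5
    n: 4.0
  - source: ff1.Qbar
    K: 0.5
    n: 4.0
- output: ff1.Qbar
  kind: NOR
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff1.S
    K: 0.5
    n: 4.0
  - source: ff1.Q
    K: 0.5
    n: 4.0
- output: ff2.W
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: one
    K: 0.5
    n: 4.0
  - source: clkA_6
    K: 0.5
    n: 4.0
- output: ff2.V
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff1.Q
    K: 0.5
    n: 4.0
  - source: clkA_6
    K: 0.5
    n: 4.0
- output: ff2.R
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.W
    K: 0.5
    n: 4.0
  - source: ff2.Q
    K: 0.5
    n: 4.0
- output: ff2.S
  kind: AND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.V
    K: 0.5
    n: 4.0
  - source: ff2.Qbar
    K: 0.5
    n: 4.0
- output: ff2.Q
  kind: NOR
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.R
    K: 0.5
    n: 4.0
  - source: ff2.Qbar
    K: 0.5
    n: 4.0
- output: ff2.Qbar
  kind: NOR
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.S
    K: 0.5
    n: 4.0
  - source: ff2.Q
    K: 0.5
    n: 4.0
- output: ff3.W
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.Qbar
    K: 0.5
    n: 4.0
  - source: clkB_6
    K: 0.5
    n: 4.0
- output: ff3.V
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.Q
    K: 0.5
    n: 4.0
  - source: clkB_6
    K: 0.5
    n: 4.0
- output: ff3.R
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff3.W
    K: 0.5
    n: 4.0
  - source: ff3.Q
    K: 0.5
    n: 4.0
- output: ff3.S
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff3.V
    K: 0.5
    n: 4.0
  - source: ff3.Qbar
    K: 0.5
    n: 4.0
- output: ff3.Q
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff3.S
    K: 0.5
    n: 4.0
  - source: ff3.Qbar
    K: 0.5
    n: 4.0
- output: ff3.Qbar
  kind: NAND
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff3.R
    K: 0.5
    n: 4.0
  - source: ff3.Q
    K: 0.5
    n: 4.0
- output: G1
  kind: OR
  kinetics:
    rho: 1.0
    gamma: 1.0
    rho0: 0.0
  regulators:
  - source: ff2.Q
    K: 0.5
    n: 4.0
  - source: ff3.Q
    K: 0.5
    n: 4.0
sources:
- id: one
  level: 1.0
solver:
  t_end: 900.0
  dt_output: 0.01
  rel_tol: 1.0e-08
  abs_tol: 1.0e-10
  stiff: true
provenance:
  counter:
    kind: mod3
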