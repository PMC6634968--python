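# Physicochemical constants used by the feature engine. Config data, not code:
# swap this file (or pass an alternative table) to change pKa values or scales.

# EMBOSS iep pKa set
pka:
  n_terminus: 8.6
  c_terminus: 3.6
  side_chains:
    K: 10.8
    R: 12.5
    H: 6.5
    D: 3.9
    E: 4.1
    C: 8.5
    Y: 10.1

hydropathy_scales:
  kyte_doolittle:
    A: 1.8
    R: -4.5
    N: -3.5
    D: -3.5
    C: 2.5
    Q: -3.5
    E: -3.5
    G: -0.4
    H: -3.2
    I: 4.5
    L: 3.8
    K: -3.9
    M: 1.9
    F: 2.8
    P: -1.6
    S: -0.8
    T: -0.7
    W: -0.9
    Y: -1.3
    V: 4.2
  hopp_woods:
    A: -0.5
    R: 3.0
    N: 0.2
    D: 3.0
    C: -1.0
    Q: 0.2
    E: 3.0
    G: 0.0
    H: -0.5
    I: -1.8
    L: -1.8
    K: 3.0
    M: -1.3
    F: -2.5
    P: 0.0
    S: 0.3
    T: -0.4
    W: -3.4
    Y: -2.3
    V: -1.5
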