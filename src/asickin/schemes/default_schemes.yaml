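# Default kinetic schemes for acid-sensing ion channel gating.
#
# Rates are per-second, listed per discrete pH level as {source: {target: rate}}.
# Diagonals are closed automatically.  The branching scheme (resting R,
# protonated-closed C, open O, desensitized D; desensitization entered from
# the closed state) is calibrated so that at pH 5 macroscopic desensitization
# proceeds with tau ~ 0.18 s and at pH 8 recovery from desensitization with
# tau ~ 0.84 s, the wild-type values.  The linear scheme connects the
# desensitized state solely to the open state.
schemes:
  branching:
    states: [R, C, O, D]
    conducting: [O]
    rates:
      8.0:
        R: {C: 0.01}
        C: {R: 5000.0, O: 0.01, D: 0.001}
        O: {C: 2000.0}
        D: {C: 1.19}
      5.0:
        R: {C: 300.0}
        C: {R: 1.0, O: 600.0, D: 16.6}
        O: {C: 300.0}
        D: {C: 0.002}
  linear:
    states: [R, O, D]
    conducting: [O]
    rates:
      8.0:
        R: {O: 0.01}
        O: {R: 5000.0, D: 0.001}
        D: {O: 1.19}
      5.0:
        R: {O: 600.0}
        O: {R: 50.0, D: 6.0}
        D: {O: 0.002}
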