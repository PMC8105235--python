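# EXAMPLE flow-capacity thresholds -- PLACEHOLDER VALUES.
#
# These cutoffs are illustrative numbers for phantom experiments and demos.
# They are NOT clinically validated; real analyses must supply a config with
# population-derived (CFR, stress perfusion) cutoffs.
#
# Classes are listed most severe -> normal. A point gets the best class whose
# cfr_min AND stress_min it meets (worst-axis-governs staircase).
classes:
  - name: scar
    cfr_min: 0.0
    stress_min: 0.0
    color: black
  - name: definite ischemia
    cfr_min: 0.6
    stress_min: 0.4
    color: blue
  - name: moderately reduced
    cfr_min: 1.1
    stress_min: 0.8
    color: green
  - name: mildly reduced
    cfr_min: 1.6
    stress_min: 1.2
    color: yellow
  - name: minimally reduced
    cfr_min: 2.1
    stress_min: 1.7
    color: orange
  - name: normal
    cfr_min: 2.6
    stress_min: 2.1
    color: red
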