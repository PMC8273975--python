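# Degree-of-misclassification sweep: non-differential mechanisms with the
# diagonal at 1 - d, for d from 0 (no misclassification) to 0.5 (half of the
# population misclassified).  The sweep reuses the scenario's designs and
# methods at every degree and reports the empirical-SE ratio DSS / SRS.
seed: 20210711
scenarios:
  - name: sweep_base
    reps: 2000
    designs:
      - {kind: srs, n: 2500, methods: [design_agnostic]}
      - {kind: dss, quotas: [500, 500, 500, 500, 500]}
    methods: [design_agnostic, model_based, design_based]
sweep:
  degrees: [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
  pattern: uniform
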