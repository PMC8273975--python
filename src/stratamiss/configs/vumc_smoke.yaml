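# Smoke-test profile of the main simulation: same scenarios, 50 replicates.
seed: 20210711
scenarios:
  - name: nondifferential
    reps: 50
    misclassification: {kind: empirical_overall, interpretation: bayes_inverted}
    designs:
      - {kind: full_cohort}
      - {kind: srs, n: 2500, methods: [design_agnostic]}
      - {kind: dss, quotas: [500, 500, 500, 500, 500]}
    methods: [design_agnostic, model_based, design_based]
  - name: differential
    reps: 50
    misclassification: {kind: empirical_differential, interpretation: bayes_inverted}
    designs:
      - {kind: full_cohort}
      - {kind: srs, n: 2500, methods: [design_agnostic]}
      - {kind: dss, quotas: [500, 500, 500, 500, 500]}
    methods: [design_agnostic, model_based, design_based]
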