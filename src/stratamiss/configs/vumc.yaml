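# Main simulation: empirical misclassification mechanisms at full replication.
# Population and coefficient defaults are the study conditions (N = 100,000;
# trust model (-0.75, -0.25, -0.50, 1.25, -1.50, 1.00); income model
# (-2.00, 1.25, 0.25, 1.75, 0.50); race proportions (0.82, 0.10, 0.01, 0.05, 0.02)).
seed: 20210711
scenarios:
  - name: nondifferential
    reps: 10000
    misclassification: {kind: empirical_overall, interpretation: bayes_inverted}
    designs:
      - {kind: full_cohort}
      - {kind: srs, n: 2500, methods: [design_agnostic]}
      - {kind: dss, quotas: [500, 500, 500, 500, 500]}
    methods: [design_agnostic, model_based, design_based]
  - name: differential
    reps: 10000
    misclassification: {kind: empirical_differential, interpretation: bayes_inverted}
    designs:
      - {kind: full_cohort}
      - {kind: srs, n: 2500, methods: [design_agnostic]}
      - {kind: dss, quotas: [500, 500, 500, 500, 500]}
    methods: [design_agnostic, model_based, design_based]
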