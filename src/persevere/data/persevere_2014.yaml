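# Updated PERSEVERE decision-tree configuration (2014 model structure).
#
# Structure follows the published updated model: 6 biomarker-based decision
# rules, 1 age-based decision rule, 14 daughter nodes, 8 terminal nodes;
# TN2/TN4/TN7 are low risk (mortality probability 0.000-0.025), TN1/TN3/TN5
# intermediate (0.182-0.267), TN6/TN8 high (0.472-0.625); GZMB is reused on
# two branches.  The numeric split thresholds and the interior node
# probabilities are SYNTHETIC placeholders chosen to be physiologically
# plausible (biomarker concentrations in pg/ml, age in years): the published
# figure prints the exact values but they are not machine-readable here.
# Replace the thresholds with a verbatim transcription of the figure before
# using this config on real patients.
name: persevere-2014-updated-synthetic
root: N1
splits:
  - node_id: N1
    variable: ccl3
    threshold: 160.0
    op: "<="
    low_child: N2
    high_child: N3
  - node_id: N2
    variable: hspa1b
    threshold: 3300000.0
    op: "<="
    low_child: N4
    high_child: N5
  - node_id: N4
    variable: gzmb
    threshold: 55.0
    op: "<="
    low_child: TN1
    high_child: TN2
  - node_id: N5
    variable: age
    threshold: 0.5
    op: "<="
    low_child: TN3
    high_child: TN4
  - node_id: N3
    variable: mmp8
    threshold: 47000.0
    op: "<="
    low_child: N6
    high_child: N7
  - node_id: N6
    variable: il8
    threshold: 830.0
    op: "<="
    low_child: TN5
    high_child: TN6
  - node_id: N7
    variable: gzmb
    threshold: 18.0
    op: "<="
    low_child: TN7
    high_child: TN8
terminals:
  - node_id: TN1
    mortality_probability: 0.182
    risk_class: intermediate
  - node_id: TN2
    mortality_probability: 0.000
    risk_class: low
  - node_id: TN3
    mortality_probability: 0.267
    risk_class: intermediate
  - node_id: TN4
    mortality_probability: 0.010
    risk_class: low
  - node_id: TN5
    mortality_probability: 0.200
    risk_class: intermediate
  - node_id: TN6
    mortality_probability: 0.472
    risk_class: high
  - node_id: TN7
    mortality_probability: 0.025
    risk_class: low
  - node_id: TN8
    mortality_probability: 0.625
    risk_class: high
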