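# Packaged run configurations, one per risk group in base-case and
# micro-costing variants.  Event incidences and unit costs come from the
# shared events.csv / costs.csv (percent-scale probabilities, euro costs).
#
# NYHA transition matrices and health-state utilities are NOT packaged: the
# published supplementary tables carrying them are unavailable, so each
# fixture declares a synthetic stand-in configuration (see tavicea.synthetic_data)
# unless the user supplies utilities.csv / nyha_transitions.csv paths.
#
# The micro-costing variants replace the tariff-based index procedure costs
# with bottom-up micro-costing estimates and add post-procedure
# rehabilitation.  The rehabilitation unit cost is a configurable
# placeholder (no published tariff value); override it for real analyses.
defaults: &defaults
  events: events.csv
  costs: costs.csv
  percent: true
  settings:
    horizon_cycles: 180
    annual_discount_rate: 0.03
  synthetic:
    seed: 0

scenario_defaults: &scenario_defaults
  index_costs:
    tavi: 26985.0
    savr: 14802.0
  rehabilitation:
    uptake:
      tavi: 0.062
      savr: 0.64
      medical: 0.0
    unit_cost: 5000.0   # placeholder; the source tariff value is not published

fixtures:
  intermediate_base:
    <<: *defaults
    risk_group: intermediate
  high_base:
    <<: *defaults
    risk_group: high
  inoperable_base:
    <<: *defaults
    risk_group: inoperable
  intermediate_micro:
    <<: *defaults
    risk_group: intermediate
    scenario: *scenario_defaults
  high_micro:
    <<: *defaults
    risk_group: high
    scenario: *scenario_defaults
  inoperable_micro:
    <<: *defaults
    risk_group: inoperable
    scenario: *scenario_defaults
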