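# The 12-rung model ladder, from a parameter-free null to the winning
# delta-rule model with four learning rates (valence x volatility) and a
# shared temperature.  Edit or override this manifest to change the
# ladder without touching code.
models:
  - model_id: M0
    family: "null"
    lr_split: none
    temperature_split: none
    parameter_names: []
    description: random responding, p(red) = 0.5
  - model_id: M1
    family: "null"
    lr_split: none
    temperature_split: none
    parameter_names: [bias]
    description: biased coin, constant p(red) = bias
  - model_id: M2
    family: wsls
    lr_split: none
    temperature_split: none
    parameter_names: [stay_after_win, shift_after_loss]
    description: probabilistic win-stay/lose-shift on the previous outcome
  - model_id: M3
    family: delta_rule
    lr_split: fixed_one
    temperature_split: shared
    parameter_names: [temperature]
    description: single-trial memory; delta rule with learning rate fixed at 1
  - model_id: M4
    family: delta_rule
    lr_split: single
    temperature_split: shared
    parameter_names: [temperature, alpha]
    description: one learning rate, one temperature
  - model_id: M5
    family: delta_rule
    lr_split: single
    temperature_split: by_condition
    parameter_names: [temperature_stable, temperature_volatile, alpha]
    description: one learning rate, condition-specific temperature
  - model_id: M6
    family: delta_rule
    lr_split: by_valence
    temperature_split: shared
    parameter_names: [temperature, alpha_pos, alpha_neg]
    description: learning rate split by prediction-error valence
  - model_id: M7
    family: delta_rule
    lr_split: by_condition
    temperature_split: shared
    parameter_names: [temperature, alpha_stable, alpha_volatile]
    description: learning rate split by volatility condition
  - model_id: M8
    family: delta_rule
    lr_split: by_valence
    temperature_split: by_condition
    parameter_names: [temperature_stable, temperature_volatile, alpha_pos, alpha_neg]
    description: valence-split learning rate, condition-specific temperature
  - model_id: M9
    family: delta_rule
    lr_split: by_condition
    temperature_split: by_condition
    parameter_names: [temperature_stable, temperature_volatile, alpha_stable, alpha_volatile]
    description: condition-split learning rate and temperature
  - model_id: M10
    family: delta_rule
    lr_split: by_valence_and_condition
    temperature_split: by_condition
    parameter_names: [temperature_stable, temperature_volatile, alpha_pos_stable, alpha_neg_stable, alpha_pos_volatile, alpha_neg_volatile]
    description: four learning rates, condition-specific temperature
  - model_id: M11
    family: delta_rule
    lr_split: by_valence_and_condition
    temperature_split: shared
    parameter_names: [temperature, alpha_pos_stable, alpha_neg_stable, alpha_pos_volatile, alpha_neg_volatile]
    description: four learning rates (valence x volatility), shared temperature
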