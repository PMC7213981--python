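# Robustness sweep for the duration-sensitivity conclusion: each variant
# overrides one rate/abundance of the duration-default set, with k_p
# re-derived from the same measured normalized slope under the variant.
base_preset: duration-default
variants:
  - label: low-abundance
    overrides: {NICD0: 200}
  - label: high-abundance
    overrides: {NICD0: 20000}
  - label: fast-basal-decay
    overrides: {Gamma_up: 1/30}
  - label: slow-basal-decay
    overrides: {Gamma_up: 1/1000}
  - label: fast-phospho-decay
    overrides: {Gamma_p: 1/4}
  - label: slow-phospho-decay
    overrides: {Gamma_p: 1/30}
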