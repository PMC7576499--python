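# Demo run: two strains (an aquaglyceroporin and a weaker glycerol channel)
# simulated at the standard 1.4 -> 2.1 osmol/L shock, then analysed
# end-to-end.  Run with:
#   nipflow pipeline --config examples/demo_config.yaml --out runs/demo
seed: 42
mode: exponential
noise_sd: 0.01
replicates: 3
temperatures: [10, 15, 20, 25, 30, 35]
t_ref: 23.0
osm_in: 1.4
osm_out: 2.1
strains:
  - name: NIP1_1
    pf: 6.78e-4
    pgly: 24.5e-8
    ea_water: 9.80
    ea_glycerol: 6.93
  - name: NIP6_1
    pf: 5.25e-4
    pgly: 12.8e-8
    ea_water: 11.30
    ea_glycerol: 8.60
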