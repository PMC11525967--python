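# Demo run: wild-type regime, 4 embryos, one simulated smFISH stack with the
# MSpaap / MSpaapp cell pair and 180 DAPI nuclei, plus a staged concentration
# series for the time-course stage.
#
#   lineagefish run --config examples/demo_config.yaml --seed 1 --out demo_out
seed: 1
regime: wild_type
n_embryos: 4
nuclei_count: 180
channel: egl-1
true_counts:
  MSpaap: 14
  MSpaapp: 11
cell_diameters:
  MSpaap: 6.0
  MSpaapp: 3.5
series_cell: MSpaapp
series_diameter_um: 3.5
series_stage_range: [182, 197]
series_conc_start: 0.2
series_conc_end: 0.6
series_n_embryos: 20
window_order: 5
division_landmark: 180
block_threshold_factor: 2.0
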