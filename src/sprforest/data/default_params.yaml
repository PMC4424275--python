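# Calibrated generator defaults: 750 plots of 400 m^2 whose AGB panel
# matches the study population's occasion means (120.3 / 132.5 t/ha),
# tree counts (8650 / 8191) and between-occasion correlation (0.804).
# Produced by sprforest.population.calibrate (tol 1%, 30 seeds).
n_plots: 750
plot_area_m2: 400.0
trees_per_plot_mean: 11.533333333333333
dbh_min: 15.0
dbh_scale: 15.146563385779864
mortality_prob: 0.05306358381502885
growth_mean: 2.308865635788365
growth_sd: 1.5
plot_growth_sd: 2.2542901335237095
plot_growth_max: 8.0
seed: 0
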