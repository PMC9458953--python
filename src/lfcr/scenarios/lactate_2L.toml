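# 2 L lactate-fed channel reactor, temperature staged 30 -> 10 degC.
[scenario]
name = "lactate_2L"
volume_l = 2.0
dt = 0.1
seed = 0

[feed]
sulphate_g_l = 1.0
carbon_source = "lactate"
carbon_mmol_l = 10.94
yeast_acetate_mmol_l_h = 0.02

[kinetics]
k_max = 0.144
k_s = 0.05
t_ref = 303.15
ea_above = 19000.0
ea_below = 65700.0
t_crit = 288.15
k_ox_max = 2.0
k_hs = 0.5
biofilm_regrowth = 0.1
eta_s0 = 0.30
ferm_fraction = 0.25
k_donor = 0.05
aux_donor_frac = 0.5

[schedule]
hrt = 48.0
stages = [[30.0, 6.0], [25.0, 6.0], [20.0, 6.0], [15.0, 6.0], [10.0, 6.0]]
disruption_interval = 3.0
harvest_interval = 6.0
sample_interval = 24.0
burn_in = 6.0

[noise]
cv = 0.05

[asv]
read_depth = 35000
overdispersion = 200.0
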