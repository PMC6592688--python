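# Scenario presets: each is fully self-contained and runnable with no
# external files.  Geometry dimensions in mm; moduli in units of the skin
# shear modulus.  Resolutions are desk-scale defaults chosen so every
# preset relaxes in minutes on one CPU core.

[semicylinder_growth_sweep]
description = "Semicylindrical single sheet, T/L = 0.02, uniform growth sweep"
expected = "ridge count nondecreasing in g; >= 2 ridges by g = 1.2"
[semicylinder_growth_sweep.geometry]
kind = "SEMICYLINDER"
thickness_T = 0.02
boundary_length_L = 1.0
resolution = [12, 30]
through_thickness_layers = 2
[semicylinder_growth_sweep.growth]
g_surface = 1.2
uniform = true
[semicylinder_growth_sweep.material]
nu = 0.45
[semicylinder_growth_sweep.solver]
mode = "SINGLE_SHEET"
rng_seed = 0
profile = "fast"
[semicylinder_growth_sweep.sweep]
parameter = "g_surface"
values = [1.05, 1.1, 1.2, 1.3]

[thickness_sweep]
description = "Semicylindrical single sheet, g = 1.2, relative-thickness sweep"
expected = "ridge count nonincreasing in T/L"
[thickness_sweep.geometry]
kind = "SEMICYLINDER"
thickness_T = 0.02
boundary_length_L = 1.0
resolution = [12, 30]
through_thickness_layers = 2
[thickness_sweep.growth]
g_surface = 1.2
uniform = true
[thickness_sweep.material]
nu = 0.45
[thickness_sweep.solver]
mode = "SINGLE_SHEET"
rng_seed = 0
profile = "fast"
[thickness_sweep.sweep]
parameter = "thickness_T"
values = [0.01, 0.02, 0.04]

[lobe_single_sheet]
description = "Curved single-lobe sheet with crease, T/L = 0.014, homogeneous growth"
expected = "two ridges per lobe near g = 1.10, three by g = 1.20"
[lobe_single_sheet.geometry]
kind = "CURVED_LOBE"
thickness_T = 0.047
boundary_length_L = 3.357142857142857
resolution = [28, 56]
through_thickness_layers = 2
[lobe_single_sheet.growth]
g_surface = 1.2
uniform = true
crease_equals_surface = true
[lobe_single_sheet.material]
nu = 0.45
[lobe_single_sheet.solver]
mode = "SINGLE_SHEET"
rng_seed = 0
profile = "fast"

[pdms_analog]
description = "Swelling PDMS analog: semicylindrical sheet, T/L = 0.01, g = 1.3"
expected = "three pleats with wavelength increasing toward the free edge"
[pdms_analog.geometry]
kind = "SEMICYLINDER"
thickness_T = 0.8462
boundary_length_L = 84.62
resolution = [16, 40]
through_thickness_layers = 2
[pdms_analog.growth]
g_surface = 1.3
uniform = true
[pdms_analog.material]
nu = 0.45
[pdms_analog.solver]
mode = "SINGLE_SHEET"
rng_seed = 0
profile = "fast"

[bilayer_ratio_sweep]
description = "Bilayer frill lobe: skin on soft substrate, g(s) = 1.3, g(c) = 2.2"
expected = "ridge count nonincreasing in the skin-to-substrate stiffness ratio; 3 ridges at ratio 100"
[bilayer_ratio_sweep.geometry]
kind = "BILAYER_FRILL"
thickness_T = 0.047
boundary_length_L = 3.357142857142857
resolution = [20, 40]
through_thickness_layers = 2
substrate_depth_ratio = 10.0
substrate_layers = 3
[bilayer_ratio_sweep.growth]
g_surface = 1.3
g_crease = 2.2
[bilayer_ratio_sweep.material]
nu = 0.45
stiffness_ratio = 100.0
[bilayer_ratio_sweep.solver]
mode = "MULTI_LAYER"
rng_seed = 0
profile = "fast"
[bilayer_ratio_sweep.sweep]
parameter = "stiffness_ratio"
values = [20.0, 65.0, 100.0, 1000.0, 2000.0]

[bilayer_quasistatic]
description = "Bilayer frill lobe grown along the developmental schedule, stiffness ratio 100"
expected = "transition from two to three ridges along the schedule"
[bilayer_quasistatic.geometry]
kind = "BILAYER_FRILL"
thickness_T = 0.047
boundary_length_L = 3.357142857142857
resolution = [20, 40]
through_thickness_layers = 2
substrate_depth_ratio = 10.0
substrate_layers = 3
[bilayer_quasistatic.growth]
g_surface = 1.3
g_crease = 2.2
[bilayer_quasistatic.material]
nu = 0.45
stiffness_ratio = 100.0
[bilayer_quasistatic.solver]
mode = "MULTI_LAYER"
rng_seed = 0
profile = "fast"
[bilayer_quasistatic.schedule]
n_steps = 10

[single_sheet_quasistatic]
description = "Curved single-lobe sheet grown stepwise to g = 1.28 (crease grows with the surface)"
expected = "passes through a two-ridge state and ends with three ridges"
[single_sheet_quasistatic.geometry]
kind = "CURVED_LOBE"
thickness_T = 0.047
boundary_length_L = 3.357142857142857
resolution = [28, 56]
through_thickness_layers = 2
[single_sheet_quasistatic.growth]
g_surface = 1.28
uniform = true
crease_equals_surface = true
[single_sheet_quasistatic.material]
nu = 0.45
[single_sheet_quasistatic.solver]
mode = "SINGLE_SHEET"
rng_seed = 0
profile = "fast"
[single_sheet_quasistatic.schedule]
n_steps = 10
final_g_surface = 1.28
uniform = true
crease_equals_surface = true
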