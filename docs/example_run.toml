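# Example run configuration for `alveofem run --config docs/example_run.toml`.
# Omitted keys fall back to the defaults (the full 6-variant x 3-load matrix
# on the default desk-scale geometry).

seed = 1
outdir = "runs/example"
optimise = true          # calibrate solid-PDL and bulk moduli before solving
write_fields = true

variants = [
    "fibrous+structure", "fibrous+bulk",
    "solid+structure", "solid+bulk",
    "none+structure", "none+bulk",
]
load_cases = ["occlusal", "orth_mesiodistal", "orth_buccolingual"]

[geometry]
corpus_width = 12.0      # buccolingual, mm
corpus_height = 30.0     # inferior border to alveolar crest, mm
n_teeth = 1              # 3 mirrors the full molar-region layout
root_length = 12.0
root_radius_crest = 3.0
pdl_thickness = 0.25
trabecular_mode = "structure"
lattice_porosity = 0.5
element_size = 1.5

[fibres]
volume_fraction = 0.60
oblique_angle = 45.0
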