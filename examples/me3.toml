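# Packaged trimethyllysine demonstration run: 10^4-frame synthetic
# rotamer-jump trajectory in the symmetric pocket, all stages enabled.
enzyme_chain = "A"
substrate_chain = "B"
head_residue = 9
fe_atom = "A:400:FE"
hbond_mode = "strict"
sphere_radii = [4.6, 4.7, 4.8]
clash_tolerance = 0.4
dielectric = 4.0
temperature = 310.0
out_dir = "methyldyn_out"
seed = 2024

[synthetic]
preset = "me3"
n_frames = 10000
dt = 2.0
seed = 2024
kappa = 0.1
barrier = 1.0
jitter_sigma = 0.05
dihedral_sigma = 10.0
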