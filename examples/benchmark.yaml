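# Standard synthetic benchmark: 60 quasi-spherical droplets planted in a
# bright tissue disc over 12 slices of 512x512, peak amplitudes log-uniform
# between 3x and 20x the background level, Gaussian read noise with
# sd = background / 5.  Identical to SyntheticSpec() defaults.
shape: [12, 512, 512]
tissue_center: [256.0, 256.0]
tissue_radius: 200.0
tissue_intensity: 30.0
background: 10.0
n_droplets: 60
droplet_radius_range: [2.0, 6.0]
droplet_intensity_range: [3.0, 20.0]
z_extent_range: [3, 5]
noise_sd: null          # null -> background / 5
poisson: false
psf_sigma: 1.0
bit_depth: 8
seed: 0
min_separation: 6.0
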