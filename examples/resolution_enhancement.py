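"""Full RE-OCT on a simulated phantom: resolution bought with earned SNR.

Runs the complete chain (coherent average -> Gaussian spectrum-model fit
-> bandwidth-expansion mask -> zero-pad upsampling -> 32-angle radial
Gaussian PSF fits) on a noisy nine-particle phantom, sweeping the BE
factor, and contrasts it with the ideal noise-free case. Efficiency is
the achieved resolution-enhancement factor divided by the applied BE
factor: 1 in the noise-free limit, decreasing with b once amplified
spatial frequencies run out of dynamic range.
"""

import reoct as r

BE_GRID = [1.0, 1.4, 1.8, 2.4]

for condition in ("noise_free", "noise_only"):
    spec = r.default_phantom_spec(condition, seed=11)
    stack = r.synthesize_stack(spec, 100)
    noise = r.synthesize_noise_stack(spec.grid_size, spec.pitch,
                                     spec.noise_sigma, 100, seed=12)
    cfg = r.RunConfig(n_frames=100 if condition != "noise_free" else 1, upsample=4)
    sweep = r.be_sweep(stack, noise, cfg, BE_GRID)
    print(f"\n{condition} (N={cfg.n_frames}):")
    print(sweep[["b", "resolution_um", "sbr_db", "efficiency"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# With noise, resolution still improves with b but efficiency drops below
# 1 and SBR falls: the mask amplifies the noise floor along with the
# signal tail. Averaging first (N=100) is what keeps the penalty small.
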