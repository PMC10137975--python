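"""Denoise a noisy brain phantom with anisotropic diffusion.

Builds a seeded tumor phantom with Gaussian noise (sigma 0.05), runs the
edge-preserving diffusion filter, and compares fidelity against the
noise-free rendering before and after.
"""

from btrkit import (DiffusionParams, PhantomSpec, anisotropic_filter,
                    generate_phantom, mse, psnr, ssim)

noisy, mask, label = generate_phantom(PhantomSpec(noise_sigma=0.05, seed=0))
clean, _, _ = generate_phantom(PhantomSpec(noise_sigma=0.0, seed=0))

result = anisotropic_filter(noisy, DiffusionParams())
filtered = result.image

print(f"diffusion stopped after {result.n_iters} sweeps "
      f"(last iteration error {result.ie_trace[-1]:.4f})")
print(f"MSE  vs clean: noisy {mse(noisy, clean):.5f}  ->  "
      f"filtered {mse(filtered, clean):.5f}")
print(f"PSNR vs clean: noisy {psnr(noisy, clean):.2f} dB  ->  "
      f"filtered {psnr(filtered, clean):.2f} dB")
print(f"SSIM vs clean: noisy {ssim(noisy, clean):.3f}  ->  "
      f"filtered {ssim(filtered, clean):.3f}")
print("Lower MSE and higher PSNR/SSIM mean the filter removed noise "
      "while keeping the anatomy: edges conduct weakly, flat noise "
      "conducts freely.")
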