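"""Extract the 11-element texture feature vector from phantoms.

Computes first-order statistics, GLCM (co-occurrence) features and
coarseness for a tumor slice and a tumor-free slice, showing the contrast
the classifier exploits.
"""

from btrkit import FEATURE_NAMES, PhantomSpec, feature_vector, \
    generate_phantom

tumor_img, _, _ = generate_phantom(PhantomSpec(seed=0, tumor=True))
normal_img, _, _ = generate_phantom(PhantomSpec(seed=0, tumor=False))

ft = feature_vector(tumor_img).as_array()
fn = feature_vector(normal_img).as_array()

print(f"{'feature':<12} {'tumor':>12} {'normal':>12}")
for name, a, b in zip(FEATURE_NAMES, ft, fn):
    print(f"{name:<12} {a:>12.5g} {b:>12.5g}")
print("The hyperintense blob raises the intensity spread (sd, skewness) "
      "and the co-occurrence contrast while lowering energy — the "
      "separation the Gaussian-kernel SVM relies on.")
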