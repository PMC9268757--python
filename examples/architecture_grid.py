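"""The compact architecture notation and the conv-layer complexity estimate.

Parses the nine-architecture comparison grid, prints each network's
multiply count for 62 × 62 inputs (k²·N²·nF^(l−1)·nF^l per conv layer,
fan_in × fan_out per dense layer) and its float32 parameter memory — the
numbers a practitioner needs to judge whether a model fits an embedded
decoder budget.
"""

from imspeech import STANDARD_ARCHS, estimate_complexity, parse_arch

print(f"{'architecture':22s} {'total ops':>15s} {'params':>12s} {'memory':>9s}")
for abbrev in STANDARD_ARCHS:
    arch = parse_arch(abbrev)
    est = estimate_complexity(arch, input_side=62)
    print(f"{abbrev:22s} {est.total_ops:>15,d} {est.parameter_count:>12,d} "
          f"{est.parameter_bytes / 1e6:>7.1f}MB")

best = parse_arch("C64-128/D64")
print("\nper-layer ops for C64-128/D64:")
for name, ops in estimate_complexity(best, 62).per_layer_ops:
    print(f"  {name:12s} {ops:>15,d}")
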