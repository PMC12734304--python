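"""Profile the default full-size network and reproduce the published
comparator arithmetic.

Prints the default architecture's parameter count (calibrated to the 0.92 M
budget), its model size, and the performance-density cells computable from
the printed (accuracy, parameters) pairs of the lightweight-model
comparison."""

from voxslim import (NetworkConfig, build_network, complexity_report,
                     performance_density)

model = build_network(NetworkConfig(), seed=0)
rep = complexity_report(model, (1, 73, 96, 96))
print(f"default network: {rep.para:,} parameters "
      f"({rep.para / 0.92e6 * 100:.1f}% of the 0.92 M budget), "
      f"{rep.flops / 1e9:.2f} GFLOPs at 1x73x96x96, {rep.model_size_mib:.2f} MiB")

# comparator table arithmetic: accuracy percent per million parameters
for name, acc, params_m in [("ResNet3D-Small", 91.5, 1.20),
                            ("MobileNet3D", 92.0, 0.60),
                            ("pruned model", (91.3 + 93.4 + 94.4) / 3, 0.49)]:
    pd = performance_density(acc, int(params_m * 1e6))
    print(f"  {name:<15} ACC {acc:5.1f}%  {params_m:.2f} M -> PD {pd:.2f}")
# PD rewards small models: halving parameters at equal accuracy doubles it.
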