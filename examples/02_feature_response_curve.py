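"""Compare two simulated assemblies with Feature-Response Curves.

Simulates a low-error and a high-error assembly over the same contigs,
computes their FRCs and ranks them by normalized area under the curve.
The assembly that reaches high genome coverage with a smaller feature
budget is the better one.
"""

from frceval import (
    ToyAssemblySpec,
    compare_frc,
    compute_frc,
    count_features,
    simulate_assembly,
)

curves = []
for label, rate in (("low_error", 0.1), ("high_error", 0.9)):
    asm, _, _ = simulate_assembly(
        ToyAssemblySpec(label=label, seed=42, error_rate=rate)
    )
    curve = compute_frc(asm, counts=count_features(asm))
    curves.append(curve)
    print(f"{label}: {len(asm.contigs)} contigs, "
          f"{int(curve.phi[-1])} total features, "
          f"max coverage {curve.coverage[-1]:.2f}")

points, ranking = compare_frc(curves)
print("\nAUC ranking (higher = better size/correctness trade-off):")
print(ranking.to_string(index=False))
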