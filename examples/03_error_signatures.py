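"""Recover a planted context-specific error signature.

A 5x mismatch multiplier on the basecall 3-mer TCG is planted in the
simulator; profiling 300 reads by 3-mer context recovers that context as
the clear argmax of the per-context mismatch rate, and its Jensen-Shannon
"randomness of error" stands far above the typical context (errors there
are anything but random).
"""

import numpy as np

import porebench as pb

planted = "TCG"
ref = pb.generate_reference(60_000, seed=42)
model = pb.ErrorModel(context_multipliers={planted: 5.0})
rng = np.random.default_rng(43)
alignments = [
    pb.simulate_read(ref, (s := int(rng.integers(0, 59_000)), s + 1000), model,
                     seed=rng, read_id=f"r{i}").truth
    for i in range(300)
]
profile = pb.error_profile(alignments)
rates = {ctx: r["mismatch"] for ctx, r in profile.context_rates().items()}
top = sorted(rates, key=rates.get, reverse=True)[:5]
print("top contexts by estimated mismatch rate:")
for ctx in top:
    print(f"  {ctx}: {rates[ctx]:.4f}")
randomness = pb.profile_randomness(profile)
print(f"\nrandomness of error: {planted}={randomness[planted]:.4f} bits, "
      f"median context={np.median(list(randomness.values())):.4f} bits")
print()
print(f"The planted context {planted} tops the table at roughly 5x the")
print("background per-context rate, and its divergence from the center-base")
print("profile confirms the bias is context-specific, not random noise.")
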