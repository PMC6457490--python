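"""Noise-free identifiability check: with zero noise and no QC flags the
pipeline must reproduce the spiked truth exactly.

Three binding sites (one biphasic) and four DE genes are spiked; the called
regions and DE lists are compared one-to-one against the truth tables.
"""

from chipchip import (
    SimConfig,
    TrueDE,
    TrueRegion,
    call_binding_regions,
    run_expression_timepoint,
    simulate_dataset,
)

config = SimConfig(genome_length=40_000, n_genes=24, noise_sd=0.0, dye_bias=0.0,
                   flag_rate=0.0, timepoints=(14.0,), rng_seed=11)
regions = [
    TrueRegion(center=6_000, amplitude=2.0, width=120.0),
    TrueRegion(center=18_000, shape="biphasic", amplitude=2.0, width=120.0,
               peak_separation=600.0, amplitude_ratio=0.5),
    TrueRegion(center=31_000, amplitude=2.0, width=120.0),
]
de = [TrueDE("SCO1003", 14.0, 1.5), TrueDE("SCO1008", 14.0, -1.5),
      TrueDE("SCO1015", 14.0, 1.5), TrueDE("SCO1020", 14.0, -1.5)]

chip, expr, annotation, truth = simulate_dataset(config, regions, de)

chip_res = call_binding_regions(chip, annotation, 14.0)
print(f"called {len(chip_res.regions)} regions for {len(regions)} spiked sites:")
for t, r in zip(truth["regions"].itertuples(), chip_res.regions):
    ok = r.start <= t.center <= r.end and r.shape == t.shape
    print(f"  center {t.center} ({t.shape:<10}) -> {r.start}-{r.end} "
          f"{r.shape:<10} {'OK' if ok else 'MISMATCH'}")

expr_res = run_expression_timepoint(expr, annotation, 14.0, n_permutations=200,
                                    seed=11, cluster_ranges={}, cluster_exclusions=set())
print(f"\nDE up:   {sorted(expr_res.de['up'])}  (truth: SCO1003, SCO1015)")
print(f"DE down: {sorted(expr_res.de['down'])}  (truth: SCO1008, SCO1020)")
print("\nIn the zero-noise limit every spiked center must fall inside a called")
print("region with the correct shape, and the DE lists must equal the truth.")
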