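"""Call SSB hotspots at three stringencies and test them against a
uniform-placement null.

A small synthetic breakome is generated with 30% of read events drawn
from a shared pool of hot positions; real tissues show exactly this
kind of reproducible nucleotide-level clustering.
"""

from breakome import (HotspotDefinition, SyntheticConfig, generate_all,
                      hotspot_fraction, pooled_positions, run_null)
from breakome.hotspots import call_hotspots

ds = generate_all(SyntheticConfig(genome_length=400_000, n_genes=40,
                                  breaks_per_sample=4000, hot_pool_size=200,
                                  rng_seed=11))
samples = ds.samples_of("tissue1")
universe = pooled_positions(samples)
print(f"tissue1: {len(samples)} samples, {len(universe)} distinct break positions")

for definition in (HotspotDefinition("sample_level", min_depth=2),
                   HotspotDefinition("sample_shared", min_depth=1, min_samples=2),
                   HotspotDefinition("sample_shared", min_depth=2, min_samples=2)):
    hs = call_hotspots(samples, definition)
    frac = hotspot_fraction(hs, universe)
    print(f"  {definition.label:24s} {len(hs):6d} hotspots "
          f"(fraction {frac:.4f} of break positions)")

res = run_null(samples, HotspotDefinition("sample_shared", 1, 2), ds.mappable,
               n_iter=100, rng_seed=1)
print(f"\nuniform null ({res.n_iterations} iterations): "
      f"mean simulated fraction {res.simulated_fractions.mean():.5f}")
print(f"real/simulated ratio {res.ratio:.2f}, t-test p = {res.p_value:.2e}")
print("A ratio well above 1 means breaks recur at the same nucleotides far "
      "more often than uniform chance allows - hotspots are real.")
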