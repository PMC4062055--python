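"""Filter MeDIP fragments and call methylation peaks with both callers.

Simulates one species' fragment library over a genome with a single
methylated island, applies the quality/pair/duplicate filters, and runs
the Poisson sliding-window caller and the mixture-posterior caller. The
consensus keeps Poisson peaks confirmed by the second caller.
"""

import numpy as np

from sdmrkit import FragmentSet, filter_fragments, rpm_track
from sdmrkit.peaks import call_peaks_poisson, call_peaks_posterior, consensus
from sdmrkit.synthetic import MethylationLandscape, simulate_medip

rng = np.random.default_rng(0)
genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 200_000))}
landscape = MethylationLandscape(
    background=0.005,
    segments={"demo": {"chr1": [(80_000, 81_000, 0.9), (150_000, 150_600, 0.9)]}},
    chrom_lengths={"demo": {"chr1": 200_000}},
)
raw = simulate_medip(genome, landscape, "demo", coverage=30, seed=1)
frags = filter_fragments(raw, species="demo")
print(f"fragments: {len(raw)} raw -> {frags.total_retained} after filtering "
      "(quality >= 10, proper pairs, duplicates collapsed)")

track = rpm_track(frags, bin_width=50, chrom_sizes={"chr1": 200_000})
poisson_peaks = call_peaks_poisson(track, fraglen=200, p_threshold=1e-3)
posterior_peaks = call_peaks_posterior(track)
cons = consensus(poisson_peaks, posterior_peaks)

print(f"poisson caller: {len(poisson_peaks)} peaks, "
      f"posterior caller: {len(posterior_peaks)} peaks, consensus: {len(cons)}")
for p in cons:
    print(f"  {p.interval.chrom}:{p.interval.start}-{p.interval.end}  "
          f"score={p.score:.1f} (-10*log10 p)  summit=+{p.summit}")
print("both methylated segments should appear; score is the transformed "
      "Poisson tail p-value of the best window")
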