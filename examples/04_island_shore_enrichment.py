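"""Island/shore densities and enrichment statistics.

Reproduces the published worked example — s-DMR density per Mb of CpG
island versus shore sequence — and demonstrates the chi-square and
shuffle-control enrichment machinery on synthetic regions drawn inside
islands.
"""

import numpy as np

from sdmrkit import FeatureSet, chi2_enrichment, density_per_mb, make_shores, shuffle_control
from sdmrkit.core import GenomicInterval

# Published counts: 77 hypo + 45 hyper s-DMRs in islands (23.8 Mb of
# island sequence), 821 + 431 in shores (89.5 Mb).
island_density = density_per_mb(77 + 45, 23.8e6)
shore_density = density_per_mb(821 + 431, 89.5e6)
print(f"island s-DMR density: {island_density:.2f} per Mb")
print(f"shore  s-DMR density: {shore_density:.1f} per Mb")
print("s-DMRs concentrate in the moderately CpG-dense shores, not in the "
      "islands themselves\n")

# shore construction + enrichment demo on a toy genome
rng = np.random.default_rng(3)
sizes = {"chr1": 500_000}
islands = [GenomicInterval("chr1", s, s + 1_000, name=f"isl{i}")
           for i, s in enumerate(range(20_000, 480_000, 25_000))]
shores = make_shores(islands, sizes, flank=2_000)
print(f"{len(islands)} islands ({FeatureSet('i', islands).total_bp} bp) -> "
      f"{len(shores.intervals)} shore segments ({shores.total_bp} bp)")

# regions planted inside islands are detected as enriched
regions = [GenomicInterval("chr1", isl.start + 200, isl.start + 500)
           for isl in islands[::2]]
ctrl = shuffle_control(regions, sizes, FeatureSet("islands", islands),
                       n_controls=200, seed=11)
print(f"shuffle control: observed {ctrl.observed} island overlaps vs "
      f"{ctrl.expected:.2f} expected; ratio {ctrl.ratio:.1f}, "
      f"empirical p = {ctrl.empirical_p:.4f}")

chi = chi2_enrichment(k_regions=30, n_regions=100, k_background=100, n_background=1_000)
print(f"chi-square 2x2 example: ratio {chi.ratio:.1f}, "
      f"chi2 = {chi.statistic:.2f}, p = {chi.p_value:.2e} ({chi.method})")
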