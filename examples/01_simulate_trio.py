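"""Generate a synthetic primate trio and inspect the planted truth.

Builds a reference genome plus two derived genomes (substitutions +
indels with exact chain files), CpG islands, gene models, and planted
methylation regions of five classes, then prints what was planted.
"""

from sdmrkit import TrioConfig, generate_trio

config = TrioConfig(
    chrom_count=1,
    chrom_length=300_000,
    island_count=14,
    gene_count=8,
    planted_counts={
        "human_hypo": 8,
        "human_hyper": 8,
        "chimp_only": 5,
        "shared_methylated": 5,
        "unmethylated_background": 4,
    },
    seed=42,
)
trio = generate_trio(config)

print(f"genomes: { {sp: sum(map(len, g.values())) for sp, g in trio.genomes.items()} } bp")
print(f"islands: {len(trio.islands)}, genes: {len(trio.genes)}, "
      f"repeats: {len(trio.repeats)}, blacklist: {len(trio.blacklist)}")
print("\nplanted regions by class (the ground truth every downstream stage"
      " is scored against):")
print(trio.truth["class"].value_counts().to_string())
print("\nfirst planted rows:")
print(trio.truth.head(5).to_string(index=False))
chain = trio.chains[("human", "chimpanzee")].chains[0]
print(f"\nhuman->chimpanzee chain chr1: {len(chain.blocks)} aligned blocks "
      f"(one more than the {len(chain.blocks) - 1} indels on that branch)")
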