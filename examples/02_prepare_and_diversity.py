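"""Prepare a count table for analysis and estimate per-sample diversity.

Rarefaction equalises sequencing effort (samples below the depth are
dropped), the Hellinger transform makes Euclidean distances sensible for
species data, and abundance filters select the taxa worth displaying.
"""

import fwdfungi as f

design = f.generate_design(n_blocks=2, n_years=6, seed=2)
taxa = f.generate_taxa(150, seed=2)
counts, _ = f.generate_community_counts(design, taxa, depth=4000, seed=2)

rar = f.rarefy(counts, depth=2000, seed=2)
print(f"rarefied to 2000 reads: {len(rar.table.sample_ids)} samples kept, "
      f"{len(rar.dropped)} dropped")

rel = f.relative_abundance(rar.table)
for preset in ("fig2", "fig5", "fig6"):
    kept = f.apply_abundance_filter(rel, preset, design)
    print(f"abundance filter {preset}: {len(kept)} of {len(rel.taxon_ids)} taxa retained")
# fig2 keeps taxa over 0.5% in >= 3 samples; fig6 additionally requires over
# 1% somewhere, so its set is always a subset of fig2's.

div = f.diversity_table(rar.table)
print("\nper-sample diversity (first 3 samples):")
print(div.head(3).round(3).to_string())
mean = div.mean()
print(f"\nmeans: richness {mean['richness']:.1f}, Chao1 {mean['chao1']:.1f}, "
      f"Shannon {mean['shannon']:.2f} nats, evenness {mean['evenness']:.2f}")
# Chao1 >= richness always: it adds an estimate of unseen taxa from the
# counts of singletons and doubletons.
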