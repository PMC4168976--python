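"""Within-gene insertion position profiles and clone fitness.

Essential genes tolerate insertions in their terminal ~2% (a truncated
protein often remains functional there), which is why the caller trims the
3' sliver from gene cores.  The positional profile makes that visible.
Clone fitness W compares a clone's frequency before and after competitive
growth; W=1 is neutral, W=0 extinct.
"""

from tifa import pipeline, synthetic
from tifa.gene_profile import clone_fitness, gene_fitness, positional_profile

art = synthetic.generate_genome(seed=23, length=600_000, ta_density=0.05,
                                n_genes=400)
essential = {g.locus_id for g in art.genes}  # all essential, to isolate shape
records, _ = synthetic.generate_library(
    art, seed=24, loc_coeffs=(0.0, 0.0, 1.0), motif_spread=1.0,
    essential_ids=essential, rho=0.05, m_colonies=40_000, non_ta_rate=0.0)
ds = pipeline.prepare(art.seq, True, art.genes, records)

prof = positional_profile(ds.genes, ds.sites, len(ds.seq), bin_width=0.01)
core = prof[prof.bin_start < 0.98]
tail = prof[prof.bin_start >= 0.98]
print(f"core insertions/TA: "
      f"{core.ins_count.sum() / core.ta_count.sum():.4f}")
print(f"last-2% insertions/TA: "
      f"{tail.ins_count.sum() / tail.ta_count.sum():.4f}")
# The terminal bins run ~20x hotter than the residual core rate here,
# the planted analogue of the elevated 3' tail seen in real libraries.

w_neutral = clone_fitness(0.01, 0.01, expansion=100)
w_sick = clone_fitness(0.01, 0.005, expansion=100)
print(f"neutral clone W = {w_neutral:.2f}; halved-frequency clone "
      f"W = {w_sick:.2f}")
print(f"gene fitness (median of clones [0.2, 1.0, 0.9]): "
      f"{gene_fitness([0.2, 1.0, 0.9]):.2f}")
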