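"""Simulate a small transposon library and call gene essentiality.

Builds a 400 kb circular genome with 300 genes (10% planted essential),
simulates an 8,000-colony miniHimar library with location and motif bias,
then runs the full analysis: filtering, bias fitting, Poisson-binomial
calling with one-false-positive calibration.
"""

from tifa import pipeline, synthetic

art = synthetic.generate_genome(seed=7, length=400_000, ta_density=0.04,
                                n_genes=300)
records, truth = synthetic.generate_library(art, seed=8, m_colonies=8000)

ds = pipeline.prepare(art.seq, circular=True, genes=art.genes,
                      records=records, operons=art.operons)
print(f"TA sites: {len(ds.sites)}, inserted after filtering: "
      f"{ds.n_inserted_sites}")
print(f"filter report: {ds.filter_report}")

result = pipeline.run_pipeline(ds)
print(f"calls: {result.call_counts}")
print(f"calibrated essential cutoff: {result.calibration.c_essential:.2e} "
      f"(naive 1/n_genes = {result.calibration.naive_cutoff:.2e})")
print(f"residual insertion ratio in essential genes rho = "
      f"{result.calibration.rho:.3f}")

called = set(result.results.loc[result.results.call == 'essential',
                                'gene_id'])
true = set(truth["essential_ids"])
print(f"planted essential: {len(true)}, called: {len(called)}, "
      f"recovered: {len(called & true)}, false: {len(called - true)}")
# With this saturating library nearly every planted essential gene is
# recovered while false calls stay near the calibrated expectation of one.
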