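# Configuration schema for the `tifa` command line.
#
#   tifa simulate config.yaml   # needs: outdir, seed, genome:, library:
#   tifa bias     config.yaml   # needs: genome, genes, insertions, bias_out
#   tifa call     config.yaml   # needs: ... , results_out
#   tifa validate config.yaml   # needs: ... , histogram_out, seed
#   tifa fba      config.yaml   # needs: model, deletions_out [, medium, calls]

# inputs
genome: out/genome.fasta        # single-record FASTA; "circular" in header
genes: out/genes.tsv            # locus_id  start  end  strand (0-based)
insertions: out/insertions.tsv  # position  unique  reads_s1..reads_s4
operons: out/operons.tsv        # operon_id  comma-separated loci

# simulate
outdir: out
seed: 5
genome_params:
library:
  m_colonies: 40000
  rho: 0.1
  motif_spread: 10.0

# analysis parameters
min_reads: 8
window: 20000
step: 2000
expected_fp: 1.0

# outputs
bias_out: out/bias.yaml
results_out: out/results.tsv
calibration_out: out/calibration.yaml
histogram_out: out/nde_histogram.tsv

# fba
model: out/model.json
medium: out/medium.tsv
deletions_out: out/deletions.tsv
calls: out/results.tsv
confusion_out: out/confusion.tsv
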