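"""End-to-end orchestration: load -> filter -> fit bias -> call -> screen.

The stages mirror how the analysis is run on real data:

1. load the genome, annotations, insertion table (and operons),
2. enumerate TA sites, attach them to genes, apply the retention filters
   (unique mapping, >= 8 reads, TA coincidence) and combine samples,
3. fit the bias model (location polynomial + motif spectrum),
4. compute per-site probabilities and run the Poisson-binomial calling
   with one-false-positive cutoff calibration on both tails,
5. flag essential calls explainable by operon polar effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tifa
from tifa import bias, essentiality, genome_io, operon_filter
from tifa.essentiality import CalibrationReport, GenePMF


@dataclass
class Dataset:
    seq: str
    circular: bool
    sites: list[genome_io.TASite]
    genes: list[genome_io.GeneRecord]
    operons: list[tuple[str, list[str]]]
    filter_report: dict
    n_inserted_sites: int


@dataclass
class PipelineResult:
    results: pd.DataFrame
    bias_model: bias.BiasModel
    calibration: CalibrationReport
    gene_pmfs: list[GenePMF] = field(repr=False)

    @property
    def call_counts(self) -> dict[str, int]:
        counts = self.results["call"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in essentiality.CALLS}


def prepare(seq: str, circular: bool, genes, records, operons=None,
            min_reads: int = 8, terminal_fraction: float = 0.02) -> Dataset:
    """Stage 2: sites, filters, sample combination, observed counts."""
    sites = genome_io.find_ta_sites(seq, circular)
    genome_io.assign_sites_to_genes(genes, sites, len(seq),
                                    terminal_fraction=terminal_fraction)
    retained, report = genome_io.filter_insertions(records, sites, seq,
                                                   min_reads=min_reads)
    n_ins = genome_io.combine_samples(retained, sites)
    genome_io.count_observed(genes, sites)
    return Dataset(seq, circular, sites, genes, operons or [], report, n_ins)


def load_dataset(genome_path, genes_path, insertions_path, operons_path=None,
                 min_reads: int = 8) -> Dataset:
    """Stage 1 + 2 from files."""
    seq, circular = genome_io.read_genome(genome_path)
    genes = genome_io.read_genes(genes_path)
    records = genome_io.read_insertions(insertions_path)
    operons = (operon_filter.read_operons(operons_path)
               if operons_path else None)
    return prepare(seq, circular, genes, records, operons, min_reads)


def run_pipeline(ds: Dataset, expected_fp: float = 1.0,
                 window: int = 20_000, step: int = 2_000) -> PipelineResult:
    """Stages 3-5 on a prepared dataset."""
    model = bias.fit_bias_model(ds.sites, ds.genes, len(ds.seq),
                                circular=ds.circular, window=window,
                                step=step)
    probs = bias.site_probability(ds.sites, model)
    results, calib, pmfs = essentiality.run_calling(ds.genes, ds.sites, probs,
                                                    expected_fp=expected_fp)
    calls = dict(zip(results.gene_id, results.call))
    polar = operon_filter.polar_filter(calls, ds.operons)
    results = results.merge(polar[["gene_id", "polar_flag"]], on="gene_id")
    return PipelineResult(results, model, calib, pmfs)


def write_results(path, result: PipelineResult) -> None:
    result.results.to_csv(path, sep="\t", index=False)


def calibration_yaml(path, result: PipelineResult) -> None:
    c = result.calibration
    doc = {
        "c_essential": float(c.c_essential),
        "expected_fp_essential": float(c.expected_fp_essential),
        "c_nonessential": None if c.c_nonessential is None
        else float(c.c_nonessential),
        "expected_fp_nonessential": None if c.expected_fp_nonessential is None
        else float(c.expected_fp_nonessential),
        "rho": None if c.rho is None else float(c.rho),
        "n_genes": int(c.n_genes),
        "naive_cutoff": float(c.naive_cutoff),
        "call_counts": result.call_counts,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def run_manifest(path, inputs: dict, params: dict, seed: int | None = None
                 ) -> None:
    """Reproducibility manifest: input hashes, parameters, seed, version."""
    hashes = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    doc = {"inputs": hashes, "params": params, "seed": seed,
           "tifa_version": tifa.__version__,
           "numpy_version": np.__version__}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
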