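"""Synthetic mariner-library generator with known ground truth.

Emulates the structure of a real insertion-sequencing experiment on a
single circular bacterial chromosome: controllable TA-dinucleotide density,
non-overlapping genes grouped into operons, a location-bias polynomial, a
flanking-motif preference spectrum with a fixed fold-spread, essential
genes whose core sites receive only a residual fraction of the insertion
rate (their terminal 3' sliver stays fully insertable), a fraction of
insertions landing outside TA sites, and log-normal per-clone read counts
split across samples.  Every draw flows from one seed and every planted
parameter is recorded in a truth manifest, so downstream estimators can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from tifa import genome_io
from tifa.bias import midpoint_distance
from tifa.genome_io import GeneRecord, InsertionRecord, TASite

PAPER_SCALE = dict(
    length=5_000_000,
    ta_density=0.03,
    n_genes=4200,
    loc_coeffs=(0.0032, 0.0081, 0.1615),
    motif_spread=10.0,
    rho=0.1,
    m_colonies=40_000,
    non_ta_rate=0.05,
)


@dataclass
class GenomeArtifacts:
    seq: str
    circular: bool
    genes: list[GeneRecord]
    operons: list[tuple[str, list[str]]]
    params: dict = field(default_factory=dict)


def generate_genome(seed: int, length: int = 200_000,
                    ta_density: float = 0.03, n_genes: int = 150,
                    mean_gene_len: float = 950.0, sd_log_len: float = 0.45,
                    min_gene_len: int = 150, max_gene_len: int = 6000,
                    operon_continue_p: float = 0.45,
                    n_overlapping_pairs: int = 0,
                    circular: bool = True) -> GenomeArtifacts:
    """Random circular genome with genes and operons.

    The sequence is drawn i.i.d. with P(T) = P(A) = sqrt(ta_density), so
    the realised TA-dinucleotide density matches the target in
    expectation.  Gene lengths are log-normal around ``mean_gene_len``;
    genes are placed without overlap (unless ``n_overlapping_pairs``
    plants overlaps for filter tests) and consecutive genes join an operon
    with probability ``operon_continue_p`` (geometric operon sizes);
    operon members share a strand and are listed in transcription order.
    """
    if n_genes and length < 10 * n_genes:
        raise ValueError("genome too short for the requested gene count")
    rng = np.random.default_rng(seed)

    pt = np.sqrt(ta_density)
    if 2 * pt >= 1:
        raise ValueError("ta_density too high")
    pcg = (1 - 2 * pt) / 2
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.choice(4, size=length, p=[pt, pcg, pcg, pt])
    seq = letters[draws].tobytes().decode()

    genes: list[GeneRecord] = []
    operons: list[tuple[str, list[str]]] = []
    if n_genes > 0:
        sigma = sd_log_len
        mu = np.log(mean_gene_len) - sigma ** 2 / 2
        lengths = np.clip(rng.lognormal(mu, sigma, n_genes).astype(int),
                          min_gene_len, max_gene_len)
        slack = length - int(lengths.sum()) - n_genes  # >=1 nt between genes
        if slack < 0:
            raise ValueError("cannot pack genes into the genome "
                             f"(need {int(lengths.sum()) + n_genes}, have {length})")
        gaps = rng.multinomial(slack, np.full(n_genes, 1 / n_genes)) + 1

        # operon memberships first, so strands are shared
        op_groups: list[list[int]] = [[0]]
        for i in range(1, n_genes):
            if rng.random() < operon_continue_p:
                op_groups[-1].append(i)
            else:
                op_groups.append([i])
        strand_of = {}
        for grp in op_groups:
            strand = "+" if rng.random() < 0.5 else "-"
            for i in grp:
                strand_of[i] = strand

        pos = 0
        for i in range(n_genes):
            pos += gaps[i]
            genes.append(GeneRecord(f"g{i:05d}", pos, pos + int(lengths[i]),
                                    strand_of[i]))
            pos += int(lengths[i])

        for k in range(min(n_overlapping_pairs, n_genes - 1)):
            a, b = genes[2 * k], genes[2 * k + 1]
            if a.end + 20 < b.end:
                a.end = b.start + 20  # plant a 20-nt overlap

        for j, grp in enumerate(op_groups):
            if len(grp) < 2:
                continue
            members = [genes[i].locus_id for i in grp]
            if strand_of[grp[0]] == "-":
                members = members[::-1]  # transcription order
            operons.append((f"op{j:04d}", members))

    params = dict(seed=seed, length=length, ta_density=ta_density,
                  n_genes=n_genes, mean_gene_len=mean_gene_len,
                  operon_continue_p=operon_continue_p,
                  n_overlapping_pairs=n_overlapping_pairs)
    return GenomeArtifacts(seq, circular, genes, operons, params)


def motif_spectrum(seed: int, spread: float = 10.0) -> dict[str, float]:
    """Planted per-class relative insertion rates with an exact fold-spread.

    Log-normal draws per canonical class, power-rescaled so the max/min
    ratio equals ``spread`` exactly, then normalised to mean one.
    """
    classes = genome_io.enumerate_motif_classes()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(classes))
    z = (z - z.min()) / (z.max() - z.min())  # [0, 1]
    rates = spread ** z
    rates /= rates.mean()
    return dict(zip(classes, rates))


def _site_rates(sites: list[TASite], genes: list[GeneRecord], length: int,
                loc_coeffs, spectrum: dict[str, float],
                essential_ids: set[str], rho: float,
                terminal_fraction: float) -> np.ndarray:
    a, b, c = loc_coeffs
    x = midpoint_distance(np.array([s.position for s in sites]), length)
    f = np.maximum(a * x ** 2 + b * np.abs(x) + c, 1e-9)
    mean_rate = float(np.mean(list(spectrum.values())))
    motif = np.array([spectrum.get(s.motif_class, mean_rate) for s in sites])
    rates = f * motif
    # residual insertion rate in essential-gene cores; terminal 3' sliver
    # keeps the full rate (insertions there do not disrupt function)
    for g in genes:
        if g.locus_id not in essential_ids:
            continue
        for i in g.ta_sites:
            frac = genome_io.fractional_position(g, sites[i].position, length)
            if frac < 1.0 - terminal_fraction:
                rates[i] *= rho
    return rates


def generate_library(artifacts: GenomeArtifacts, seed: int,
                     loc_coeffs=(0.0032, 0.0081, 0.1615),
                     motif_spread: float = 10.0,
                     essential_ids: set[str] | None = None,
                     essential_fraction: float = 0.1,
                     rho: float = 0.1,
                     m_colonies: int = 40_000,
                     non_ta_rate: float = 0.05,
                     non_unique_rate: float = 0.0,
                     read_meanlog: float = 5.0, read_sdlog: float = 1.0,
                     n_samples: int = 4,
                     terminal_fraction: float = 0.02,
                     ) -> tuple[list[InsertionRecord], dict]:
    """Simulate a transposon library over a synthetic genome.

    Colonies are placed multinomially over TA sites with rate proportional
    to motif preference times the location polynomial; core sites of
    essential genes are down-weighted by the residual ratio ``rho``.  A
    ``non_ta_rate`` fraction of colonies lands at non-TA positions, and a
    ``non_unique_rate`` fraction of output records is flagged as
    non-uniquely mapped.  Per-clone read counts are log-normal
    (median exp(read_meanlog)), split evenly-at-random across samples.

    Returns the insertion records and a truth manifest with every planted
    parameter, the per-class spectrum and the realised per-site rates'
    normalisation.
    """
    rng = np.random.default_rng(seed)
    seq, L = artifacts.seq, len(artifacts.seq)
    sites = genome_io.find_ta_sites(seq, artifacts.circular)
    genome_io.assign_sites_to_genes(artifacts.genes, sites, L,
                                    terminal_fraction=terminal_fraction)
    # undo analysis-side exclusions: the transposon does not care
    for s in sites:
        s.excluded = False

    if essential_ids is None:
        n_ess = int(round(essential_fraction * len(artifacts.genes)))
        chosen = rng.choice(len(artifacts.genes), size=n_ess, replace=False)
        essential_ids = {artifacts.genes[i].locus_id for i in sorted(chosen)}

    spectrum = motif_spectrum(seed + 1, motif_spread)
    rates = _site_rates(sites, artifacts.genes, L, loc_coeffs, spectrum,
                        essential_ids, rho, terminal_fraction)

    m_non_ta = int(round(m_colonies * non_ta_rate))
    m_ta = m_colonies - m_non_ta
    counts = rng.multinomial(m_ta, rates / rates.sum()) if m_ta else np.zeros(
        len(sites), dtype=int)

    positions = np.repeat([s.position for s in sites], counts)
    if m_non_ta:
        ta_starts = {s.position for s in sites}
        bad = []
        while len(bad) < m_non_ta:
            cand = rng.integers(0, L, size=2 * m_non_ta)
            for p in cand:
                p = int(p)
                if p not in ta_starts and (p - 1) % L not in ta_starts:
                    bad.append(p)
                    if len(bad) == m_non_ta:
                        break
        positions = np.concatenate([positions, np.array(bad, dtype=int)])

    reads = np.maximum(rng.lognormal(read_meanlog, read_sdlog,
                                     len(positions)), 1.0).astype(np.int64)
    per_pos_reads: dict[int, np.ndarray] = {}
    for p, r in zip(positions, reads):
        split = rng.multinomial(r, np.full(n_samples, 1 / n_samples))
        if int(p) in per_pos_reads:
            per_pos_reads[int(p)] += split
        else:
            per_pos_reads[int(p)] = split

    records = []
    for p in sorted(per_pos_reads):
        unique = bool(rng.random() >= non_unique_rate)
        records.append(InsertionRecord(p, unique, per_pos_reads[p]))

    truth = dict(
        seed=seed,
        loc_coeffs=[float(v) for v in loc_coeffs],
        motif_spread=float(motif_spread),
        spectrum={k: float(v) for k, v in spectrum.items()},
        essential_ids=sorted(essential_ids),
        rho=float(rho),
        m_colonies=int(m_colonies),
        m_ta=int(m_ta),
        non_ta_rate=float(non_ta_rate),
        non_unique_rate=float(non_unique_rate),
        read_meanlog=float(read_meanlog),
        read_sdlog=float(read_sdlog),
        n_samples=int(n_samples),
        terminal_fraction=float(terminal_fraction),
        n_ta_sites=len(sites),
        unique_sites_hit=int((counts > 0).sum()),
    )
    return records, truth


def write_dataset(outdir: str | Path, artifacts: GenomeArtifacts,
                  records: list[InsertionRecord], truth: dict) -> dict:
    """Write FASTA + gene/operon/insertion TSVs + truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.tsv",
        "operons": outdir / "operons.tsv",
        "insertions": outdir / "insertions.tsv",
        "truth": outdir / "truth.yaml",
    }
    genome_io.write_genome(paths["genome"], artifacts.seq,
                           circular=artifacts.circular)
    genome_io.write_genes(paths["genes"], artifacts.genes)
    from tifa.operon_filter import write_operons

    write_operons(paths["operons"], artifacts.operons)
    genome_io.write_insertions(paths["insertions"], records)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump({**truth, "genome": artifacts.params}, fh)
    return {k: str(v) for k, v in paths.items()}
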