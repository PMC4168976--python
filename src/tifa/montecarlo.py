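"""Monte Carlo self-validation of the insertion model and calibration.

Libraries are simulated at the site-occupancy level: each TA site is
inserted independently with its model probability ``p_i = 1 - exp(-l_i)``.
This is equivalent, at the occupancy level, to placing colonies
multinomially and much cheaper; the colony-level sampler lives in
:mod:`tifa.synthetic` for end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tifa.essentiality import GenePMF, call_thresholds

#: default NDE histogram: 61 equal bins over [-6, 6]; outer bins catch overflow
DEFAULT_BIN_EDGES = np.linspace(-6.0, 6.0, 62)


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds from one master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def simulate_insertions(site_probs: np.ndarray, seed: int) -> np.ndarray:
    """Independent Bernoulli occupancy flags for every site."""
    rng = np.random.default_rng(seed)
    return rng.random(len(site_probs)) < site_probs


def sample_gene_counts(gene_pmfs: list[GenePMF], rng: np.random.Generator
                       ) -> np.ndarray:
    """Draw one simulated insertion count per gene from its site model."""
    flat = np.concatenate([g.probs for g in gene_pmfs]) if gene_pmfs else np.empty(0)
    hits = rng.random(len(flat)) < flat
    lengths = np.array([g.s for g in gene_pmfs], dtype=int)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    counts = np.zeros(len(gene_pmfs), dtype=int)
    nonzero = lengths > 0
    if hits.size:
        sums = np.add.reduceat(hits.astype(int), offsets[nonzero])
        counts[nonzero] = sums
    return counts


def nde_distribution(gene_pmfs: list[GenePMF], reps: int = 1000,
                     seed: int = 0, bin_edges: np.ndarray | None = None
                     ) -> pd.DataFrame:
    """Observed vs simulated NDE histogram.

    Simulates ``reps`` libraries under the nonessential model, computes
    each gene's NDE per replicate and histograms it on fixed bin edges
    (identical across replicates, so per-bin mean and n-1 standard
    deviation are well defined).  Values beyond the outer edges are
    clipped into the end bins.  Returns a frame with bin_center, observed,
    sim_mean, sim_sd.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates for a standard deviation")
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges)
    E = np.array([g.E for g in gene_pmfs])
    V = np.array([g.V for g in gene_pmfs])
    t_obs = np.array([g.t_obs for g in gene_pmfs])
    ok = V > 0
    eps = 1e-9

    def hist(t):
        z = (E[ok] - t[ok]) / np.sqrt(V[ok])
        z = np.clip(z, edges[0] + eps, edges[-1] - eps)
        return np.histogram(z, bins=edges)[0]

    observed = hist(t_obs)
    sims = np.empty((reps, len(edges) - 1))
    for r, s in enumerate(spawn_seeds(seed, reps)):
        rng = np.random.default_rng(int(s))
        sims[r] = hist(sample_gene_counts(gene_pmfs, rng))
    return pd.DataFrame({
        "bin_center": (edges[:-1] + edges[1:]) / 2,
        "observed": observed,
        "sim_mean": sims.mean(axis=0),
        "sim_sd": sims.std(axis=0, ddof=1),
    })


def calibration_check(gene_pmfs: list[GenePMF], cutoff: float,
                      side: str = "lower", reps: int = 200, seed: int = 0
                      ) -> np.ndarray:
    """False calls per replicate in all-nonessential simulated libraries.

    Every replicate draws insertion counts from the genes' own
    (nonessential) models and counts how many genes the calibrated cutoff
    would call.  The mean should sit near the calibration target.
    """
    thresholds = call_thresholds(gene_pmfs, cutoff, side)
    s = np.array([g.s for g in gene_pmfs])
    counts = np.zeros(reps, dtype=int)
    for r, sd in enumerate(spawn_seeds(seed, reps)):
        rng = np.random.default_rng(int(sd))
        t = sample_gene_counts(gene_pmfs, rng)
        if side == "lower":
            counts[r] = int((t <= thresholds).sum())
        else:
            called = (thresholds >= 0) & (t >= s - thresholds)
            counts[r] = int(called.sum())
    return counts
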