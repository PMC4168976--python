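"""Within-gene positional insertion profiles and clone/gene fitness."""

from __future__ import annotations

import numpy as np
import pandas as pd

from tifa.genome_io import GeneRecord, TASite, fractional_position


def positional_profile(genes: list[GeneRecord], sites: list[TASite],
                       genome_length: int, bin_width: float = 0.002
                       ) -> pd.DataFrame:
    """Relative insertion frequency along the 5'->3' gene coordinate.

    Every TA site of every gene is mapped to its fractional gene position
    in [0, 1) (strand-aware: the 3' end is always the high coordinate) and
    tallied into bins of ``bin_width``.  The per-bin insertions-per-TA
    ratio is normalised by the overall ratio of the analysed genes, so an
    unbiased library gives a flat profile near one.

    Returns a frame with bin_start, ta_count, ins_count, rel_freq.
    """
    n_bins = int(round(1.0 / bin_width))
    ta = np.zeros(n_bins, dtype=int)
    ins = np.zeros(n_bins, dtype=int)
    for g in genes:
        for i in g.ta_sites:
            s = sites[i]
            if s.exclude_reason == "context":
                continue
            frac = fractional_position(g, s.position, genome_length)
            b = min(int(frac / bin_width), n_bins - 1)
            ta[b] += 1
            ins[b] += int(s.inserted)
    total_ta, total_ins = ta.sum(), ins.sum()
    mean_rate = total_ins / total_ta if total_ta else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ta > 0, ins / np.maximum(ta, 1) / mean_rate, np.nan)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width,
        "ta_count": ta,
        "ins_count": ins,
        "rel_freq": rel,
    })


def clone_fitness(freq_before: float, freq_after: float, expansion: float
                  ) -> float:
    """Competitive fitness W of one insertion clone.

    W = ln(f_a * d / f_b) / ln((1 - f_a) * d / (1 - f_b)) for clone
    frequencies f_b before and f_a after a growth period with population
    expansion d.  Neutral clones give W = 1; clones absent after growth
    are assigned W = 0 by convention.  Undefined (``ValueError``) for
    clones absent from the initial pool.
    """
    if expansion <= 1:
        raise ValueError("expansion factor must exceed 1")
    if freq_before <= 0 or freq_before >= 1:
        raise ValueError("freq_before must lie in (0, 1)")
    if freq_after == 0:
        return 0.0
    if freq_after >= 1:
        raise ValueError("freq_after must lie in [0, 1)")
    num = np.log(freq_after * expansion / freq_before)
    den = np.log((1 - freq_after) * expansion / (1 - freq_before))
    return float(num / den)


def gene_fitness(clone_fitnesses) -> float:
    """Median fitness of the clones inserted in one gene."""
    values = np.asarray(list(clone_fitnesses), dtype=float)
    if values.size == 0:
        raise ValueError("gene has no clones with fitness values")
    return float(np.median(values))


def gene_fitness_table(clones: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a (gene_id, W) clone table to per-gene median fitness."""
    grouped = clones.groupby("gene_id")["W"]
    return pd.DataFrame({
        "gene_id": grouped.median().index,
        "n_clones": grouped.size().to_numpy(),
        "median_W": grouped.median().to_numpy(),
    })
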