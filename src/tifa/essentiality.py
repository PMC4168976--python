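"""Poisson-binomial essentiality calling.

Each gene's core TA sites carry individual insertion probabilities
``p_i`` from the bias model.  The number of inserted sites X then follows
a Poisson-binomial distribution whose probability generating function is

    G(x) = prod_i (1 - p_i + p_i x),

with P(X = t) the coefficient of ``x**t``.  A gene is called *essential*
when the lower cumulative probability P(X <= t_obs) under this
nonessential-gene model falls below a calibrated cutoff, and *nonessential*
when the upper cumulative probability P(X >= t_obs) under a scaled-down
*essential*-gene model (site probabilities multiplied by the residual
insertion ratio rho) falls below its own cutoff.  Cutoffs are calibrated so
that the expected number of false calls across the whole gene set equals a
target (one, by default), by summing each gene's marginal false-call
probability and bisecting on the cutoff.

The normalized deviation of expectation, NDE = (E - t_obs) / sqrt(V) with
E = sum p_i and V = sum p_i (1 - p_i), is reported as a standardised
depletion score (positive when a gene has fewer insertions than expected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tifa.genome_io import GeneRecord, TASite

CALLS = ("essential", "nonessential", "conflict", "unknown")


@dataclass
class GenePMF:
    """Poisson-binomial insertion-count model for one gene."""

    gene_id: str
    probs: np.ndarray
    pmf: np.ndarray = field(repr=False)
    E: float
    V: float
    t_obs: int = 0

    @property
    def s(self) -> int:
        return len(self.probs)


@dataclass
class CalibrationReport:
    """Calibrated cutoffs and the scaling of the essential-gene model."""

    c_essential: float
    expected_fp_essential: float
    c_nonessential: float | None
    expected_fp_nonessential: float | None
    rho: float | None
    n_genes: int
    naive_cutoff: float  # the 1 / n_genes heuristic, for reference


def pgf_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial pmf by iterative polynomial multiplication.

    Multiplies out ``prod_i (1 - p_i + p_i x)``; the result has length
    ``s + 1`` and reduces to the binomial pmf when all p are equal.  An
    empty probability vector yields ``[1.0]``.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.empty(len(pmf) + 1)
        nxt[0] = pmf[0] * (1 - p)
        nxt[1:-1] = pmf[1:] * (1 - p) + pmf[:-1] * p
        nxt[-1] = pmf[-1] * p
        pmf = nxt
    return pmf


def cumulative_lower(pmf: np.ndarray, t: int) -> float:
    """P(X <= t)."""
    if not 0 <= t < len(pmf):
        raise ValueError(f"t={t} outside 0..{len(pmf) - 1}")
    return float(pmf[: t + 1].sum())


def cumulative_upper(pmf: np.ndarray, t: int) -> float:
    """P(X >= t)."""
    if not 0 <= t < len(pmf):
        raise ValueError(f"t={t} outside 0..{len(pmf) - 1}")
    return float(pmf[t:].sum())


def nde(E: float, V: float, t_obs: int) -> float:
    """Normalized deviation of expectation, (E - t) / sqrt(V).

    Positive when fewer insertions were observed than expected.  Undefined
    (``ValueError``) for V = 0; callers should report such genes unknown.
    """
    if V <= 0:
        raise ValueError("NDE undefined for zero variance")
    return (E - t_obs) / np.sqrt(V)


def build_gene_pmfs(genes: list[GeneRecord], sites: list[TASite],
                    site_probs: np.ndarray,
                    scale: float | None = None) -> list[GenePMF]:
    """Per-gene Poisson-binomial models from core-site probabilities.

    ``scale`` multiplies every site probability (capped at 1), used to
    build the scaled essential-gene model.
    """
    out = []
    for g in genes:
        p = site_probs[g.core_ta_sites] if g.core_ta_sites else np.empty(0)
        if scale is not None:
            p = np.minimum(p * scale, 1.0)
        pmf = pgf_pmf(p)
        out.append(GenePMF(g.locus_id, p, pmf,
                           E=float(p.sum()),
                           V=float((p * (1 - p)).sum()),
                           t_obs=g.t_obs))
    return out


# ---------------------------------------------------------------------------
# cutoff calibration

def _cumulative_table(gene_pmfs: list[GenePMF], side: str) -> np.ndarray:
    """Padded matrix of each gene's attainable cumulative probabilities.

    Row g lists, in ascending order, every value the calling statistic can
    take for gene g (lower side: P(X<=t) for t=0..s; upper side: P(X>=t)
    for t=s..0).  Padding is +inf so ``(row < c).sum()`` indexes the
    largest attainable value below a cutoff.
    """
    rows = []
    for g in gene_pmfs:
        if side == "lower":
            vals = np.cumsum(g.pmf)
        elif side == "upper":
            vals = np.cumsum(g.pmf[::-1])
        else:
            raise ValueError("side must be 'lower' or 'upper'")
        rows.append(vals)
    width = max((len(r) for r in rows), default=1)
    table = np.full((len(rows), width), np.inf)
    for i, r in enumerate(rows):
        table[i, : len(r)] = np.maximum.accumulate(r)  # guard fp monotonicity
    return table


def _expected_false_calls(table: np.ndarray, c: float) -> float:
    """Sum over genes of the largest attainable statistic below c."""
    idx = (table < c).sum(axis=1)
    has = idx > 0
    return float(table[np.nonzero(has)[0], idx[has] - 1].sum())


def calibrate_cutoff(gene_pmfs: list[GenePMF], side: str = "lower",
                     expected_fp: float = 1.0, tol: float = 1e-12
                     ) -> tuple[float, float]:
    """Calibrate the call cutoff to a target expected false-call count.

    For a candidate cutoff c, a gene's marginal false-call probability is
    the cumulative probability at the most extreme observation that would
    still be called (statistic < c).  The sum of marginals over genes is a
    monotone non-decreasing step function of c; bisection finds the largest
    c whose sum stays <= ``expected_fp``.  Returns ``(c, achieved_sum)``.

    If no cutoff yields a positive sum (every gene too short for its most
    extreme outcome to reach any cutoff below 1), a warning is emitted and
    the machine-minimum cutoff is returned.
    """
    table = _cumulative_table(gene_pmfs, side)
    lo, hi = 0.0, 1.0
    if _expected_false_calls(table, 1.0) <= expected_fp:
        warnings.warn("expected false calls cannot reach the target below "
                      "cutoff 1; returning the largest attainable cutoff")
    for _ in range(200):
        mid = (lo + hi) / 2
        if _expected_false_calls(table, mid) <= expected_fp:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    achieved = _expected_false_calls(table, lo)
    if achieved <= 0:
        warnings.warn("no gene can be called at any cutoff; returning "
                      "machine minimum")
        return float(np.finfo(float).tiny), 0.0
    return lo, achieved


def call_thresholds(gene_pmfs: list[GenePMF], cutoff: float, side: str
                    ) -> np.ndarray:
    """Most extreme observed count still called, per gene (-1: never).

    Lower side: the largest t with P(X<=t) < cutoff (gene called when
    t_obs <= threshold).  Upper side: the count k such that any
    t_obs >= s - k + 1 is called, i.e. thresholds index from the top
    (gene called when t_obs >= s - threshold + 1); -1 means no count is
    callable.
    """
    table = _cumulative_table(gene_pmfs, side)
    return (table < cutoff).sum(axis=1) - 1


# ---------------------------------------------------------------------------
# calling

def call_essential(gene_pmfs: list[GenePMF], cutoff: float) -> pd.DataFrame:
    """Lower-tail essentiality test under the nonessential model.

    Returns a frame with p_lower, the call flag, and ``callable_ess``
    (False when even t_obs = 0 could not reach the cutoff, so essentiality
    can never be established for the gene at this library depth).
    """
    rows = []
    for g in gene_pmfs:
        if g.s == 0:
            rows.append((g.gene_id, np.nan, False, False))
            continue
        p_lower = cumulative_lower(g.pmf, g.t_obs)
        can = cumulative_lower(g.pmf, 0) < cutoff
        rows.append((g.gene_id, p_lower, p_lower < cutoff, can))
    return pd.DataFrame(rows, columns=["gene_id", "p_lower", "essential",
                                       "callable_ess"])


def essential_model_scaling(essential_ids: set[str],
                            gene_pmfs: list[GenePMF]) -> float:
    """Residual insertion ratio rho of essential genes.

    rho = (observed insertions in essential genes) / (insertions expected
    there under the nonessential model).  Raises ``ValueError`` when no
    genes were called essential.
    """
    t_sum = sum(g.t_obs for g in gene_pmfs if g.gene_id in essential_ids)
    e_sum = sum(g.E for g in gene_pmfs if g.gene_id in essential_ids)
    if e_sum == 0:
        raise ValueError("no essential genes: rho undefined")
    return t_sum / e_sum


def call_nonessential(gene_pmfs_scaled: list[GenePMF], cutoff: float
                      ) -> pd.DataFrame:
    """Upper-tail nonessentiality test under the scaled essential model."""
    rows = []
    for g in gene_pmfs_scaled:
        if g.s == 0:
            rows.append((g.gene_id, np.nan, False))
            continue
        p_upper = cumulative_upper(g.pmf, g.t_obs)
        rows.append((g.gene_id, p_upper, p_upper < cutoff))
    return pd.DataFrame(rows, columns=["gene_id", "p_upper", "nonessential"])


def merge_calls(lower: pd.DataFrame, upper: pd.DataFrame) -> pd.DataFrame:
    """Combine the two one-sided tests into the final classification."""
    df = lower.merge(upper, on="gene_id", how="left")
    df["nonessential"] = df["nonessential"].fillna(False).astype(bool)

    def classify(r):
        if r.essential and r.nonessential:
            return "conflict"
        if r.essential:
            return "essential"
        if r.nonessential:
            return "nonessential"
        return "unknown"

    df["call"] = df.apply(classify, axis=1)
    return df


def run_calling(genes: list[GeneRecord], sites: list[TASite],
                site_probs: np.ndarray, expected_fp: float = 1.0
                ) -> tuple[pd.DataFrame, CalibrationReport, list[GenePMF]]:
    """Full essentiality calling: calibrate, test both tails, merge.

    Returns the per-gene results frame (gene_id, s, t_obs, E, V, NDE,
    p_lower, p_upper, call), the calibration report, and the per-gene
    nonessential-model PMFs for reuse in Monte Carlo validation.
    """
    pmfs = build_gene_pmfs(genes, sites, site_probs)
    c_ess, fp_ess = calibrate_cutoff(pmfs, "lower", expected_fp)
    lower = call_essential(pmfs, c_ess)
    essential_ids = set(lower.loc[lower.essential, "gene_id"])

    rho = None
    c_non = fp_non = None
    if essential_ids:
        rho = essential_model_scaling(essential_ids, pmfs)
        scaled = build_gene_pmfs(genes, sites, site_probs, scale=rho)
        c_non, fp_non = calibrate_cutoff(scaled, "upper", expected_fp)
        upper = call_nonessential(scaled, c_non)
    else:
        warnings.warn("no essential calls; nonessential calling skipped")
        upper = pd.DataFrame({"gene_id": [g.gene_id for g in pmfs],
                              "p_upper": np.nan,
                              "nonessential": False})

    df = merge_calls(lower, upper)
    meta = pd.DataFrame({
        "gene_id": [g.gene_id for g in pmfs],
        "s": [g.s for g in pmfs],
        "t_obs": [g.t_obs for g in pmfs],
        "E": [g.E for g in pmfs],
        "V": [g.V for g in pmfs],
    })
    df = meta.merge(df, on="gene_id")
    df["nde"] = [
        nde(E, V, t) if V > 0 else np.nan
        for E, V, t in zip(df.E, df.V, df.t_obs)
    ]
    report = CalibrationReport(
        c_essential=c_ess, expected_fp_essential=fp_ess,
        c_nonessential=c_non, expected_fp_nonessential=fp_non,
        rho=rho, n_genes=len(genes),
        naive_cutoff=1.0 / len(genes) if genes else float("nan"),
    )
    cols = ["gene_id", "s", "t_obs", "E", "V", "nde", "p_lower", "p_upper",
            "essential", "nonessential", "callable_ess", "call"]
    return df[cols], report, pmfs
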