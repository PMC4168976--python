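"""Insertion-bias estimation for mariner transposon libraries.

Two biases are modelled.  First, a chromosomal location bias: actively
replicating circular chromosomes carry partial extra copies near the origin
of replication, so insertion frequency decays from the origin towards the
terminus.  It is summarised by the absolute-value quadratic

    f(x) = a * x**2 + b * |x| + c

where ``x`` is the signed distance from the chromosome midpoint in
megabases, so the origin (position 0 of the sequence) sits at the extremes
``x = +-L/2``.  Second, a flanking-motif bias: the insertion rate depends on
the two nucleotides on each side of the target TA, summarised per canonical
motif class.

Because the same TA locus can be hit by several independent colonies, raw
unique-site counts undercount insertion events.  Under a Poisson occupancy
model with per-site rate ``lambda = m / n`` the expected number of
*untouched* sites is ``n * exp(-m/n)``, so the event count is recovered from
the unique-site count ``u`` by the zero-truncation inversion

    m = -n * ln(1 - u / n).

All estimators here apply this multiplicity correction before computing
frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from tifa.genome_io import GeneRecord, TASite, enumerate_motif_classes, revcomp


@dataclass
class BiasModel:
    """Fitted insertion-bias model.

    ``loc_coeffs`` are (a, b, c) of the location polynomial; ``loc_stderr``
    their standard errors (overlap-corrected OLS).  ``motif_probs`` maps
    each canonical motif class to a ``(rate, variance)`` pair, where *rate*
    is the multiplicity-corrected insertion events per site for that class.
    ``mean_prob`` is the genome-wide per-site insertion probability (unique
    inserted fraction), ``norm`` the mean of f over all analysed sites (so
    location weights average to one), and ``total_events`` the estimated
    number of colonies in the library.
    """

    loc_coeffs: tuple[float, float, float]
    loc_stderr: tuple[float, float, float]
    motif_probs: dict[str, tuple[float, float]]
    mean_prob: float
    norm: float
    genome_length: int
    total_events: float
    n_sites: int = 0
    window_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean_rate(self) -> float:
        """Mean multiplicity-corrected events per site across classes."""
        rates = [r for r, _ in self.motif_probs.values()]
        return float(np.mean(rates)) if rates else float("nan")

    def to_yaml(self, path) -> None:
        doc = {
            "loc_coeffs": [float(v) for v in self.loc_coeffs],
            "loc_stderr": [float(v) for v in self.loc_stderr],
            "motif_probs": {k: [float(r), float(v)]
                            for k, (r, v) in self.motif_probs.items()},
            "mean_prob": float(self.mean_prob),
            "norm": float(self.norm),
            "genome_length": int(self.genome_length),
            "total_events": float(self.total_events),
            "n_sites": int(self.n_sites),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "BiasModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            loc_coeffs=tuple(doc["loc_coeffs"]),
            loc_stderr=tuple(doc["loc_stderr"]),
            motif_probs={k: (v[0], v[1])
                         for k, v in doc["motif_probs"].items()},
            mean_prob=doc["mean_prob"],
            norm=doc["norm"],
            genome_length=doc["genome_length"],
            total_events=doc["total_events"],
            n_sites=doc.get("n_sites", 0),
        )


# ---------------------------------------------------------------------------
# event-count estimation (Poisson zero truncation)

def estimate_event_count(n_sites: int, u_unique: int | float) -> float:
    """Estimate insertion events from the unique inserted-site count.

    Inverts the Poisson occupancy expectation ``u = n (1 - exp(-m/n))``.
    Raises ``ValueError`` at saturation (``u >= n``), where the estimate
    diverges.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if u_unique < 0:
        raise ValueError("u_unique must be non-negative")
    if u_unique >= n_sites:
        raise ValueError(
            f"saturated: {u_unique} unique sites of {n_sites}; event count "
            "undefined"
        )
    return -n_sites * math.log1p(-u_unique / n_sites)


def _polynomial(x: np.ndarray, coeffs) -> np.ndarray:
    a, b, c = coeffs
    return np.maximum(a * x ** 2 + b * np.abs(x) + c, 0.0)


def midpoint_distance(positions: np.ndarray, genome_length: int) -> np.ndarray:
    """Signed distance from the chromosome midpoint, in Mb."""
    return (np.asarray(positions, dtype=float) - genome_length / 2) / 1e6


# ---------------------------------------------------------------------------
# location bias

def fit_location_bias(sites: list[TASite], genome_length: int,
                      circular: bool = True, window: int = 20_000,
                      step: int = 2_000):
    """Fit the location polynomial from sliding-window insertion frequencies.

    A window of ``window`` nt slides by ``step`` nt; per window the
    multiplicity-corrected event estimate at the window's TA sites is
    divided by the site count, giving an events-per-site frequency.  The
    polynomial ``a x^2 + b |x| + c`` is fitted to the window-centre
    frequencies by ordinary least squares.

    Windows overlap ``window / step``-fold, so naive OLS standard errors
    are optimistic; the returned standard errors are inflated by
    ``sqrt(window / step)``.

    Returns ``(coeffs, stderr, window_table)``.
    """
    keep = [s for s in sites if s.exclude_reason != "overlap"]
    positions = np.array([s.position for s in keep])
    inserted = np.array([s.inserted for s in keep])
    order = np.argsort(positions)
    positions, inserted = positions[order], inserted[order]
    L = genome_length

    starts = np.arange(0, L - (0 if circular else window) + 1, step)
    if not circular:
        starts = starts[starts + window <= L]
    if len(starts) < 3:
        raise ValueError("need at least 3 windows to fit the location bias")

    centers, freqs = [], []
    cum_ins = np.concatenate([[0], np.cumsum(inserted)])
    for start in starts:
        end = start + window
        if end <= L:
            lo, hi = np.searchsorted(positions, [start, end])
            n_w = hi - lo
            u_w = cum_ins[hi] - cum_ins[lo]
        else:  # wrap around the origin
            lo = np.searchsorted(positions, start)
            hi = np.searchsorted(positions, end - L)
            n_w = (len(positions) - lo) + hi
            u_w = (cum_ins[-1] - cum_ins[lo]) + cum_ins[hi]
        if n_w == 0:
            warnings.warn(f"window at {start} has no TA sites; skipped")
            continue
        if u_w >= n_w:
            warnings.warn(f"window at {start} is saturated; skipped")
            continue
        centers.append(((start + window / 2) % L))
        freqs.append(estimate_event_count(n_w, u_w) / n_w)

    centers = np.array(centers)
    freqs = np.array(freqs)
    x = midpoint_distance(centers, L)
    X = np.column_stack([x ** 2, np.abs(x), np.ones_like(x)])
    coeffs, *_ = np.linalg.lstsq(X, freqs, rcond=None)
    resid = freqs - X @ coeffs
    dof = max(len(freqs) - 3, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    overlap = max(window / step, 1.0)
    stderr = np.sqrt(np.diag(cov) * overlap)

    table = pd.DataFrame({"center": centers, "x_mb": x, "frequency": freqs})
    return tuple(coeffs), tuple(stderr), table


def location_weight(positions, model: BiasModel) -> np.ndarray:
    """Normalised location weight f(x)/norm; averages to one over all sites."""
    x = midpoint_distance(np.asarray(positions), model.genome_length)
    return _polynomial(x, model.loc_coeffs) / model.norm


# ---------------------------------------------------------------------------
# motif bias

def select_unbiased_genes(genes: list[GeneRecord], mean_prob: float
                          ) -> list[GeneRecord]:
    """Genes with no fewer insertions than the binomial expectation.

    The motif spectrum must be estimated on genes whose insertion counts
    are not depressed by selection (essential genes); a gene is kept iff
    the lower binomial tail P(X <= t_obs | s, mean_prob) exceeds 0.1.
    Genes without core TA sites are excluded.
    """
    kept = []
    for g in genes:
        s = len(g.core_ta_sites)
        if s == 0:
            continue
        if stats.binom.cdf(g.t_obs, s, mean_prob) > 0.1:
            kept.append(g)
    return kept


def estimate_motif_probabilities(sites: list[TASite], site_indices=None
                                 ) -> dict[str, tuple[float, float]]:
    """Per-class multiplicity-corrected insertion rates with variances.

    For class j with ``n_j`` sites of which ``u_j`` are inserted, the event
    count is ``m_j = -n_j ln(1 - u_j/n_j)`` and the rate ``m_j / n_j``.
    The variance follows the binomial occupancy variance
    ``p(1-p)/n_j`` propagated through the zero-truncation inversion
    (delta method: times ``1/(1-p)^2``).  Classes with ``u_j = 0`` get the
    rule-of-three surrogate ``p = 3/n_j`` so chi-square weights stay
    finite; fully saturated classes are capped at ``u_j = n_j - 0.5`` with
    a warning.  Classes with no sites are absent from the result.
    """
    pool = sites if site_indices is None else [sites[i] for i in site_indices]
    counts: dict[str, list[int]] = {}
    for s in pool:
        if s.excluded or s.motif_class is None:
            continue
        n_u = counts.setdefault(s.motif_class, [0, 0])
        n_u[0] += 1
        n_u[1] += int(s.inserted)
    out: dict[str, tuple[float, float]] = {}
    for cls, (n_j, u_j) in counts.items():
        if u_j >= n_j:
            warnings.warn(f"motif class {cls} saturated ({u_j}/{n_j}); "
                          "rate capped")
            u_j = n_j - 0.5
        rate = estimate_event_count(n_j, u_j)/n_j
        p_occ = u_j / n_j if u_j > 0 else min(3.0 / n_j, 0.5)
        var = p_occ * (1 - p_occ) / n_j / (1 - p_occ) ** 2
        out[cls] = (float(rate), float(var))
    return out


def fit_independent_nucleotide_model(motif_probs: dict[str, tuple[float, float]],
                                     max_nfev: int = 20_000):
    """Test whether flanking nucleotides contribute independently.

    Models each class rate as a product of per-position nucleotide
    contributions, ``p_hat_j ~ S * prod_i q[i][nt_i]``, fitted by weighted
    least squares with weights inversely proportional to the class
    variance.  Because a class covers a context and its reverse complement,
    the product is symmetrised over the two orientations.  Contributions
    are identifiable only up to scale: each position's four contributions
    are normalised to mean one, with a single global scale ``S``.

    Returns a dict with ``contributions`` (position -> nucleotide -> factor),
    ``scale``, ``chi2``, ``dof``, ``pvalue`` and the fitted per-class
    ``predicted`` rates.  Raises ``RuntimeError`` on non-convergence (the
    best point found is attached to the exception).
    """
    classes = sorted(k for k, (r, v) in motif_probs.items() if v > 0)
    if len(classes) < 16:
        raise ValueError("need at least 16 motif classes with positive variance")
    y = np.array([motif_probs[c][0] for c in classes])
    w = 1.0 / np.sqrt(np.array([motif_probs[c][1] for c in classes]))

    nts = "ACGT"
    nt_idx = {n: i for i, n in enumerate(nts)}
    flank_cols = [0, 1, 4, 5]  # positions -2, -1, +1, +2 of the 6-mer

    def design(cls_list):
        fw = np.zeros((len(cls_list), 4), dtype=int)
        rv = np.zeros((len(cls_list), 4), dtype=int)
        for r, c in enumerate(cls_list):
            rc = revcomp(c)
            for k, col in enumerate(flank_cols):
                fw[r, k] = nt_idx[c[col]]
                rv[r, k] = nt_idx[rc[col]]
        return fw, rv

    fw, rv = design(classes)

    def unpack(theta):
        s = math.exp(theta[0])
        q = np.exp(theta[1:].reshape(4, 4))
        q = q / q.mean(axis=1, keepdims=True)
        return s, q

    def predict(theta):
        s, q = unpack(theta)
        prod_fw = np.ones(len(classes))
        prod_rv = np.ones(len(classes))
        for k in range(4):
            prod_fw *= q[k, fw[:, k]]
            prod_rv *= q[k, rv[:, k]]
        return s * 0.5 * (prod_fw + prod_rv)

    def residuals(theta):
        return (y - predict(theta)) * w

    theta0 = np.zeros(17)
    theta0[0] = math.log(max(float(np.mean(y)), 1e-12))
    sol = optimize.least_squares(residuals, theta0, max_nfev=max_nfev)
    if not sol.success:
        raise RuntimeError(f"independence fit did not converge: {sol.message}; "
                           f"best chi2={float(sol.cost * 2):.4g}")
    chi2 = float(2 * sol.cost)
    dof = len(classes) - 13  # global scale + 4 positions x (4 - 1) free factors
    pvalue = float(stats.chi2.sf(chi2, dof))
    scale, q = unpack(sol.x)
    contributions = {
        pos: {nt: float(q[k, i]) for i, nt in enumerate(nts)}
        for k, pos in enumerate((-2, -1, 1, 2))
    }
    return {
        "contributions": contributions,
        "scale": float(scale),
        "chi2": chi2,
        "dof": dof,
        "pvalue": pvalue,
        "classes": classes,
        "predicted": dict(zip(classes, predict(sol.x))),
    }


# ---------------------------------------------------------------------------
# per-site probabilities

def site_lambdas(sites: list[TASite], model: BiasModel,
                 total_events: float | None = None) -> np.ndarray:
    """Per-site expected event counts lambda_i.

    ``lambda_i`` is proportional to the motif rate times the location
    weight, scaled so the lambdas over all non-excluded sites sum to the
    library event count ``m``.  Excluded sites get lambda 0.  Sites of a
    motif class unseen during estimation fall back to the mean class rate.
    """
    if not model.motif_probs:
        raise ValueError("bias model has no motif probabilities; fit it first")
    m = model.total_events if total_events is None else total_events
    mean_rate = model.mean_rate
    rates = np.array([
        0.0 if s.exclude_reason == "overlap"
        else model.motif_probs.get(s.motif_class, (mean_rate, 0.0))[0]
        if s.motif_class is not None
        else mean_rate
        for s in sites
    ])
    positions = np.array([s.position for s in sites])
    lam = rates * location_weight(positions, model)
    total = lam.sum()
    if total <= 0:
        raise ValueError("all site rates are zero")
    return lam * (m / total)


def site_probability(sites: list[TASite], model: BiasModel,
                     total_events: float | None = None) -> np.ndarray:
    """Per-site insertion probabilities ``p_i = 1 - exp(-lambda_i)``."""
    return -np.expm1(-site_lambdas(sites, model, total_events))


# ---------------------------------------------------------------------------
# pipeline

def fit_bias_model(sites: list[TASite], genes: list[GeneRecord],
                   genome_length: int, circular: bool = True,
                   window: int = 20_000, step: int = 2_000) -> BiasModel:
    """Fit the full bias model from flagged sites and genes.

    Steps: estimate the library event count from genome-wide occupancy,
    fit the location polynomial on sliding windows, prescreen genes whose
    insertion counts are compatible with the mean rate (binomial p > 0.1),
    and estimate the motif spectrum on the core sites of those genes.
    """
    analysed = [s for s in sites if s.exclude_reason != "overlap"]
    n = len(analysed)
    u = sum(1 for s in analysed if s.inserted)
    m = estimate_event_count(n, u)
    mean_prob = u / n

    coeffs, stderr, table = fit_location_bias(
        sites, genome_length, circular=circular, window=window, step=step)
    positions = np.array([s.position for s in analysed])
    norm = float(np.mean(_polynomial(midpoint_distance(positions, genome_length),
                                     coeffs)))
    if norm <= 0:
        raise ValueError("location polynomial is non-positive over the genome")

    selected = select_unbiased_genes(genes, mean_prob)
    core_idx = [i for g in selected for i in g.core_ta_sites]
    motif_probs = estimate_motif_probabilities(sites, core_idx)

    return BiasModel(
        loc_coeffs=tuple(float(v) for v in coeffs),
        loc_stderr=tuple(float(v) for v in stderr),
        motif_probs=motif_probs,
        mean_prob=float(mean_prob),
        norm=norm,
        genome_length=genome_length,
        total_events=float(m),
        n_sites=n,
        window_table=table,
    )
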