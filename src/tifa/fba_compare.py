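"""Flux balance analysis comparator for essentiality calls.

A metabolic model is a stoichiometric network with flux bounds, boolean
gene-protein-reaction (GPR) rules and a biomass objective.  Growth is the
optimum of the linear program

    max  v_biomass   s.t.  S v = 0,  lb <= v <= ub,

solved with the HiGHS solver.  Single-gene deletions deactivate every
reaction whose GPR evaluates false with the gene removed; a gene is FBA
essential when the knockout retains less than 1% of wild-type biomass flux
(a zero-growth call at 1e-6 is reported alongside for sensitivity
analysis).  Media are imposed as uptake bounds on exchange reactions.

The model interchange format is a small JSON document (metabolites,
reactions with stoichiometry/bounds/GPR, biomass id); media are
two-column TSVs (exchange_id, uptake_bound).  Exchange reactions are
written in export convention (stoichiometry -1 on their metabolite), so
uptake is negative flux and an uptake bound b maps to lower bound -b.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

ZERO_GROWTH = 1e-6
BLOCKED_TOL = 1e-9
_REVERSIBLE_DEFAULT = 1000.0


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    gpr: str = ""

    def __post_init__(self):
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicModel:
    metabolites: list[str]
    reactions: list[Reaction]
    biomass: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        if self.biomass not in ids:
            raise ValueError(f"biomass reaction {self.biomass!r} not in model")
        known = set(self.metabolites)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ValueError(f"reaction {r.id} uses unknown metabolites "
                                 f"{sorted(missing)}")
        if not self.genes:
            self.genes = {g for r in self.reactions for g in gpr_genes(r.gpr)}

    def reaction(self, rid: str) -> Reaction:
        return next(r for r in self.reactions if r.id == rid)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            biomass=self.biomass,
            genes=set(self.genes),
        )

    def stoichiometric_matrix(self) -> np.ndarray:
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoich.items():
                S[met_idx[m], j] = coef
        return S

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        with open(path) as fh:
            doc = json.load(fh)
        reactions = [Reaction(r["id"], r["stoich"], r["lb"], r["ub"],
                              r.get("gpr", "")) for r in doc["reactions"]]
        return cls(doc["metabolites"], reactions, doc["biomass"])

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metabolites": self.metabolites,
            "biomass": self.biomass,
            "reactions": [
                {"id": r.id, "stoich": r.stoich, "lb": r.lb, "ub": r.ub,
                 "gpr": r.gpr}
                for r in self.reactions
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# GPR rules

def gpr_genes(expression: str) -> set[str]:
    """Gene identifiers appearing in a GPR string."""
    if not expression.strip():
        return set()
    from cobra.core.gene import GPR

    return set(GPR.from_string(expression).genes)


def gpr_eval(expression: str, deleted_genes: set[str]) -> bool:
    """Evaluate a boolean GPR rule with the given genes knocked out.

    Standard and/or semantics with deleted genes false and all other genes
    true; an empty rule means the reaction needs no gene product and stays
    active.  Raises ``ValueError`` on malformed rules.
    """
    if not expression.strip():
        return True
    from cobra.core.gene import GPR

    try:
        rule = GPR.from_string(expression)
    except (SyntaxError, TypeError) as exc:
        raise ValueError(f"cannot parse GPR {expression!r}: {exc}") from exc
    if not rule.genes and expression.strip():
        raise ValueError(f"cannot parse GPR {expression!r}")
    return bool(rule.eval(knockouts=set(deleted_genes)))


# ---------------------------------------------------------------------------
# linear programming

def read_medium(path: str | Path) -> dict[str, float]:
    """Medium TSV: exchange_id <tab> uptake_bound."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["exchange_id", "uptake_bound"])
    if len(df) and not _is_number(df.iloc[0]["uptake_bound"]):
        df = df.iloc[1:]
    return {str(r.exchange_id): float(r.uptake_bound) for r in df.itertuples()}


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def apply_medium(model: MetabolicModel, medium: dict[str, float]
                 ) -> MetabolicModel:
    """Limit uptake rates to the medium composition.

    Exchange reactions (single-metabolite, export convention) listed in
    the medium get lower bound ``-uptake_bound``; all other exchanges are
    closed for uptake (lower bound raised to 0).
    """
    out = model.copy()
    for r in out.reactions:
        if r.id in medium:
            r.lb = -abs(medium[r.id])
        elif len(r.stoich) == 1 and r.lb < 0:
            r.lb = 0.0
    return out


def _solve(model: MetabolicModel, objective_rid: str, maximize: bool = True):
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    c = np.zeros(n)
    j = [r.id for r in model.reactions].index(objective_rid)
    c[j] = -1.0 if maximize else 1.0
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    return res


def fba_growth(model: MetabolicModel, medium: dict[str, float] | None = None
               ) -> tuple[float, str]:
    """Optimal biomass flux and solver status.

    Infeasible problems report growth 0 with status ``"infeasible"``.
    """
    m = apply_medium(model, medium) if medium is not None else model
    res = _solve(m, m.biomass)
    if res.status != 0:
        return 0.0, "infeasible"
    return float(-res.fun), "optimal"


def single_gene_deletions(model: MetabolicModel,
                          medium: dict[str, float] | None = None,
                          threshold: float = 0.01,
                          genes=None) -> pd.DataFrame:
    """Knock out each gene in turn and classify it by residual growth.

    A gene is essential at the relative threshold (default 1% of wild
    type); the zero-growth call (< 1e-6 absolute) is reported alongside.
    Raises ``RuntimeError`` when the wild type itself cannot grow.
    """
    base = apply_medium(model, medium) if medium is not None else model.copy()
    wt, status = fba_growth(base)
    if status != "optimal" or wt < ZERO_GROWTH:
        raise RuntimeError(f"wild type does not grow (growth={wt}, "
                           f"status={status}); deletions are meaningless")
    rows = []
    for gene in sorted(genes if genes is not None else base.genes):
        ko = base.copy()
        for r in ko.reactions:
            if r.gpr and not gpr_eval(r.gpr, {gene}):
                r.lb = r.ub = 0.0
        growth, _ = fba_growth(ko)
        rows.append((gene, growth, growth < threshold * wt,
                     growth < ZERO_GROWTH))
    df = pd.DataFrame(rows, columns=["gene", "growth", "essential_1pct",
                                     "essential_zero"])
    df.attrs["wild_type_growth"] = wt
    return df


def blocked_reactions(model: MetabolicModel,
                      medium: dict[str, float] | None = None) -> set[str]:
    """Reactions that cannot carry flux in either direction."""
    m = apply_medium(model, medium) if medium is not None else model
    blocked = set()
    for r in m.reactions:
        vmax = 0.0
        for maximize in (True, False):
            res = _solve(m, r.id, maximize=maximize)
            if res.status == 0:
                vmax = max(vmax, abs(res.fun))
        if vmax < BLOCKED_TOL:
            blocked.add(r.id)
    return blocked


def relax_constraints(model: MetabolicModel, mode: str) -> MetabolicModel:
    """Relax network constraints for the comparison experiments.

    ``free_endpoints`` adds an export reaction for every metabolite, so no
    stoichiometric dead end can block flux; ``no_thermo`` removes all
    irreversibility constraints by making every reaction reversible with
    symmetric bounds; ``both`` composes the two (order-independent).
    """
    if mode not in ("free_endpoints", "no_thermo", "both"):
        raise ValueError(f"unknown relaxation mode {mode!r}")
    out = model.copy()
    if mode in ("no_thermo", "both"):
        for r in out.reactions:
            span = max(abs(r.lb), abs(r.ub))
            if span == 0:
                span = _REVERSIBLE_DEFAULT
            r.lb, r.ub = -span, span
    if mode in ("free_endpoints", "both"):
        for met in out.metabolites:
            out.reactions.append(
                Reaction(f"EXP_{met}", {met: -1.0}, 0.0, _REVERSIBLE_DEFAULT))
    return out


# ---------------------------------------------------------------------------
# confusion statistics

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero."""
    return _round_half_away(100.0 * numerator / denominator)


@dataclass
class ConfusionTable:
    """Two-row agreement table between insertion-based calls and FBA.

    Row 1: genes called essential (FBA agrees when it predicts essential);
    row 2: genes called nonessential (FBA agrees when it predicts
    nonessential).  Percentages are recomputed from the counts with
    round-half-away-from-zero to integer percent.
    """

    ess_fba_e: int
    ess_fba_n: int
    non_fba_n: int
    non_fba_e: int

    @property
    def pct_essential_true(self) -> int:
        return _round_half_away(100 * self.ess_fba_e
                                / (self.ess_fba_e + self.ess_fba_n))

    @property
    def pct_nonessential_true(self) -> int:
        return _round_half_away(100 * self.non_fba_n
                                / (self.non_fba_n + self.non_fba_e))

    @property
    def pct_overall(self) -> int:
        agree = self.ess_fba_e + self.non_fba_n
        total = (self.ess_fba_e + self.ess_fba_n
                 + self.non_fba_n + self.non_fba_e)
        return _round_half_away(100 * agree / total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [["essential", self.ess_fba_e, self.ess_fba_n,
              self.pct_essential_true],
             ["nonessential", self.non_fba_n, self.non_fba_e,
              self.pct_nonessential_true]],
            columns=["call", "fba_agree", "fba_disagree", "pct_true"],
        )


def confusion_table(tifa_calls: dict[str, str], fba_essential: dict[str, bool]
                    ) -> ConfusionTable:
    """Cross-tabulate essentiality calls against FBA predictions.

    Only genes with a definite call (essential or nonessential) *and* an
    FBA prediction are compared; unknown/conflict calls and genes outside
    the model are ignored.
    """
    ee = en = nn = ne = 0
    for gene, call in tifa_calls.items():
        if gene not in fba_essential:
            continue
        fba_e = fba_essential[gene]
        if call == "essential":
            ee, en = ee + int(fba_e), en + int(not fba_e)
        elif call == "nonessential":
            nn, ne = nn + int(not fba_e), ne + int(fba_e)
    return ConfusionTable(ee, en, nn, ne)
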