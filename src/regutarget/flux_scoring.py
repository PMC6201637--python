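"""Per-reaction product-flux slopes (nRAP) and per-gene scores (nGAP).

The idea: for each gene-associated reaction ``r``, ask how the maximal
product flux responds as ``r``'s flux is walked across its feasible range.
Concretely, with the flux polytope constrained to steady state, reaction
bounds and a minimum growth requirement
``v_biomass >= growth_fraction * v_biomass_max``, the feasible range
``[v_min, v_max]`` of each reaction is found by flux variability analysis;
the reaction flux is then fixed at ``v_r = v_min + k*(v_max - v_min)`` for
``k = 0, 0.1, ..., 1`` and the product flux is maximised at each point.
The least-squares slope of max product flux versus ``k`` is the reaction's
normalised Reaction Activity on Product flux, ``nRAP_r``: positive slopes
mark product-favouring reactions, negative slopes mark competing ones, and
zero-slope reactions do not influence the product.  The fractional
coordinate ``k`` (rather than absolute flux) keeps slopes comparable
between high-flux and low-flux reactions.

Dividing ``nRAP_r`` by a gene's GPR subunit factor gives the per-gene
``nGAP_jr = nRAP_r / GPRf_j``.

An optional extension re-scores reactions that only matter on alternative
(non-optimal) routes: the dominant scored reaction is knocked out and
zero-scored reactions are re-swept, so parallel pathways to the product
pick up slopes too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import ConfigurationError, MetabolicModel

__all__ = [
    "FluxRange",
    "RAPTable",
    "GAPTable",
    "InfeasibleModelError",
    "flux_variability",
    "compute_nrap",
    "extend_alternate_routes",
    "compute_ngap",
]

#: slopes below this magnitude are snapped to 0 to stabilise downstream signs
SLOPE_ZERO_TOL = 1e-6
#: bound relaxation used to retry numerically infeasible sweep points
SWEEP_RELAX_EPS = 1e-6


class InfeasibleModelError(RuntimeError):
    """The model cannot satisfy its constraints at all."""


@dataclass(frozen=True)
class FluxRange:
    """Feasible [v_min, v_max] of one reaction under the growth constraint."""

    reaction_id: str
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if self.v_min > self.v_max + 1e-9:
            raise ValueError(
                f"{self.reaction_id}: v_min {self.v_min} > v_max {self.v_max}"
            )

    @property
    def width(self) -> float:
        return self.v_max - self.v_min


@dataclass
class RAPTable:
    """Per-reaction sweep results: flux range, slope, provenance, status.

    ``table`` columns: reaction_id, v_min, v_max, nrap, provenance
    ("primary" | "alternate-route"), flag ("ok" | "infeasible").
    ``sweeps`` maps reaction id -> (k values, max target flux values).
    """

    table: pd.DataFrame
    sweeps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def nrap(self) -> pd.Series:
        """reaction id -> nRAP for reactions that solved cleanly."""
        ok = self.table[self.table["flag"] == "ok"]
        return ok.set_index("reaction_id")["nrap"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GAPTable:
    """Per (gene, reaction) activity scores: nGAP_jr = nRAP_r / GPRf_j."""

    table: pd.DataFrame  # columns: gene, reaction_id, gprf, ngap

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cobra plumbing
# ---------------------------------------------------------------------------

def _as_cobra(model: MetabolicModel):
    """Return (a copy of) the cobra model backing a MetabolicModel."""
    if model.cobra_model is not None:
        return model.cobra_model.copy()
    import cobra

    cm = cobra.Model("model")
    cm.add_metabolites([cobra.Metabolite(m) for m in model.metabolites])
    crs = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crs.append(cr)
    cm.add_reactions(crs)
    for r, cr in zip(model.reactions, crs):
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    return cm


def _max_biomass(cm, biomass_id: str) -> float:
    cm.objective = biomass_id
    cm.objective_direction = "max"
    value = cm.slim_optimize()
    if value is None or np.isnan(value):
        raise InfeasibleModelError(
            "model infeasible: biomass cannot be optimised under the given bounds"
        )
    return float(value)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def flux_variability(
    model: MetabolicModel,
    growth_fraction: float = 0.5,
    loopless: bool = False,
    reaction_ids: Optional[list[str]] = None,
) -> list[FluxRange]:
    """Feasible flux range of each gene-associated reaction under growth.

    Ranges are computed subject to steady state, the model bounds and
    ``v_biomass >= growth_fraction * v_biomass_max`` — the same constraint
    the sweep LPs use, so every sweep point is feasible by construction.
    With ``loopless=True`` each FVA optimum is post-corrected to a value
    attainable by a thermodynamically sensible, cycle-free flux
    distribution (this shrinks the apparent ranges of reactions that only
    reach their extremes by running an internal loop).
    """
    if not 0 <= growth_fraction <= 1:
        raise ConfigurationError(f"growth_fraction must be in [0, 1], got {growth_fraction}")
    from cobra.flux_analysis import flux_variability_analysis

    cm = _as_cobra(model)
    _max_biomass(cm, model.biomass_reaction)  # raises if infeasible
    if reaction_ids is None:
        reaction_ids = [r.id for r in model.gene_associated_reactions()]
    if not reaction_ids:
        return []
    fva = flux_variability_analysis(
        cm,
        reaction_list=reaction_ids,
        fraction_of_optimum=growth_fraction,
        loopless="cycleFreeFlux" if loopless else None,
    )
    out = []
    for rid in reaction_ids:
        r = model.reaction(rid)
        lo = float(np.clip(fva.at[rid, "minimum"], r.lower_bound, r.upper_bound))
        hi = float(np.clip(fva.at[rid, "maximum"], r.lower_bound, r.upper_bound))
        if lo > hi:  # numerical crossing of a degenerate range
            lo = hi = 0.5 * (lo + hi)
        out.append(FluxRange(rid, lo, hi))
    return out


# ---------------------------------------------------------------------------
# nRAP sweep
# ---------------------------------------------------------------------------

def _k_grid(k_step: float) -> np.ndarray:
    n = int(round(1.0 / k_step))
    if abs(n * k_step - 1.0) > 1e-9 or n < 1:
        raise ConfigurationError(f"k_step {k_step} does not divide [0, 1] evenly")
    return np.linspace(0.0, 1.0, n + 1)


def compute_nrap(
    model: MetabolicModel,
    ranges: list[FluxRange],
    growth_fraction: float = 0.5,
    k_step: float = 0.1,
    _knockouts: Optional[set[str]] = None,
) -> RAPTable:
    """Sweep each ranged reaction and fit the product-flux slope nRAP_r.

    For each reaction and each ``k`` on the grid the reaction flux is fixed
    at ``v_min + k*(v_max - v_min)``, biomass is held at or above
    ``growth_fraction`` of its maximum, and the target flux is maximised.
    ``nRAP_r`` is the ordinary least-squares slope of the resulting
    (k, max target flux) points; slopes below ``SLOPE_ZERO_TOL`` in
    magnitude snap to 0.  A sweep point that fails numerically is retried
    with the fixed bounds relaxed by ``SWEEP_RELAX_EPS``; a reaction whose
    points still fail is flagged "infeasible" and excluded downstream.
    """
    ks = _k_grid(k_step)
    cm = _as_cobra(model)
    if _knockouts:
        for rid in _knockouts:
            cm.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    vbm = _max_biomass(cm, model.biomass_reaction)
    bio = cm.reactions.get_by_id(model.biomass_reaction)
    bio.lower_bound = growth_fraction * vbm
    cm.objective = model.target_reaction
    cm.objective_direction = "max"

    rows = []
    sweeps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fr in ranges:
        rxn = cm.reactions.get_by_id(fr.reaction_id)
        orig = rxn.bounds
        vt = np.empty_like(ks)
        failed = False
        for i, k in enumerate(ks):
            v = fr.v_min + k * fr.width
            rxn.bounds = (v, v)
            val = cm.slim_optimize()
            if val is None or np.isnan(val):
                eps = SWEEP_RELAX_EPS * max(1.0, abs(v))
                rxn.bounds = (v - eps, v + eps)
                val = cm.slim_optimize()
            if val is None or np.isnan(val):
                failed = True
                break
            vt[i] = float(val)
        rxn.bounds = orig

        if failed:
            rows.append((fr.reaction_id, fr.v_min, fr.v_max, np.nan, "primary", "infeasible"))
            continue
        if fr.width == 0.0:
            slope = 0.0
        else:
            slope = float(np.polyfit(ks, vt, 1)[0])
            if abs(slope) < SLOPE_ZERO_TOL:
                slope = 0.0
        sweeps[fr.reaction_id] = (ks.copy(), vt)
        rows.append((fr.reaction_id, fr.v_min, fr.v_max, slope, "primary", "ok"))

    table = pd.DataFrame(
        rows, columns=["reaction_id", "v_min", "v_max", "nrap", "provenance", "flag"]
    )
    return RAPTable(table=table, sweeps=sweeps)


def extend_alternate_routes(
    model: MetabolicModel,
    rap: RAPTable,
    growth_fraction: float = 0.5,
    max_rounds: int = 1,
    k_step: float = 0.1,
    loopless: bool = False,
) -> RAPTable:
    """Score reactions that matter only on alternative routes to the product.

    The primary sweep sees only reactions the optimum actually needs: a
    parallel branch that could also reach the product scores 0 because the
    optimal route never uses it.  Each round knocks out (fixes to zero) the
    next-strongest product-favouring reaction — candidates in decreasing
    nRAP, positive slopes only, excluding the target and biomass reactions
    — recomputes ranges and sweeps for the reactions still scored 0 under
    that single knockout, and records any newly nonzero slopes with
    provenance "alternate-route", never overwriting a primary score.
    Knockouts are not accumulated: each candidate is probed alone, so an
    unproductive knockout (one that severs all routes) does not mask
    alternates revealed by the next candidate.  The search stops after
    ``max_rounds`` probes, when candidates run out, or as soon as no
    zero-scored reaction remains.
    """
    if max_rounds < 1:
        raise ConfigurationError(f"max_rounds must be >= 1, got {max_rounds}")
    table = rap.table.copy()
    sweeps = dict(rap.sweeps)

    scored = table[(table["flag"] == "ok") & (table["nrap"] > 0.0)]
    candidates = scored[
        (scored["reaction_id"] != model.target_reaction)
        & (scored["reaction_id"] != model.biomass_reaction)
    ]
    # strongest product-path reactions first; ties broken by id
    order = candidates.sort_values(
        by=["nrap", "reaction_id"], ascending=[False, True], kind="stable"
    )["reaction_id"].tolist()

    for knockout in order[:max_rounds]:
        zero_ids = table[(table["flag"] == "ok") & (table["nrap"] == 0.0)][
            "reaction_id"
        ].tolist()
        if not zero_ids:
            break
        sub = MetabolicModel(
            metabolites=list(model.metabolites),
            reactions=[
                r if r.id != knockout else type(r)(
                    id=r.id, stoichiometry=r.stoichiometry,
                    lower_bound=0.0, upper_bound=0.0, gpr=r.gpr,
                )
                for r in model.reactions
            ],
            biomass_reaction=model.biomass_reaction,
            target_reaction=model.target_reaction,
            genes=list(model.genes),
        )
        try:
            new_ranges = flux_variability(
                sub, growth_fraction=growth_fraction, loopless=loopless,
                reaction_ids=zero_ids,
            )
            new_rap = compute_nrap(
                sub, new_ranges, growth_fraction=growth_fraction, k_step=k_step,
            )
        except InfeasibleModelError:
            continue  # this knockout kills growth; probe the next candidate

        for _, row in new_rap.table.iterrows():
            if row["flag"] == "ok" and row["nrap"] != 0.0:
                idx = table.index[table["reaction_id"] == row["reaction_id"]][0]
                table.loc[idx, ["v_min", "v_max", "nrap", "provenance"]] = [
                    row["v_min"], row["v_max"], row["nrap"], "alternate-route",
                ]
                sweeps[row["reaction_id"]] = new_rap.sweeps[row["reaction_id"]]
    return RAPTable(table=table, sweeps=sweeps)


# ---------------------------------------------------------------------------
# nGAP
# ---------------------------------------------------------------------------

def compute_ngap(
    rap: RAPTable, gpr_factors: dict[str, dict[str, float]]
) -> GAPTable:
    """One row per (gene, reaction): nGAP_jr = nRAP_r / GPRf_j.

    Reactions without GPR factors (no gene association) and reactions
    flagged infeasible are omitted.
    """
    rows = []
    ok = rap.table[rap.table["flag"] == "ok"]
    for _, r in ok.iterrows():
        factors = gpr_factors.get(r["reaction_id"])
        if not factors:
            continue
        for gene, f in sorted(factors.items()):
            if f <= 0:
                raise AssertionError(
                    f"GPR factor for {gene} in {r['reaction_id']} is {f} <= 0"
                )
            rows.append((gene, r["reaction_id"], f, r["nrap"] / f))
    return GAPTable(
        table=pd.DataFrame(rows, columns=["gene", "reaction_id", "gprf", "ngap"])
    )
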