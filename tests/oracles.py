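"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the code paths (and the solver) the
package itself uses: LPs are assembled by hand as dense matrices and solved
with scipy's HiGHS backend, graph recursions are evaluated by exhaustive
path enumeration, and the randomisation sampler is re-implemented with
naive per-interaction loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from regutarget.core_model import MetabolicModel


def _lp_arrays(model: MetabolicModel):
    mets = {m: i for i, m in enumerate(model.metabolites)}
    rxns = [r.id for r in model.reactions]
    s = np.zeros((len(mets), len(rxns)))
    bounds = []
    for j, r in enumerate(model.reactions):
        for m, coef in r.stoichiometry.items():
            s[mets[m], j] = coef
        bounds.append((r.lower_bound, r.upper_bound))
    return s, rxns, bounds


def _solve(s, bounds, c_max_index, extra_lb=None):
    """max v[c_max_index] s.t. S v = 0, bounds, optional v[i] >= b rows."""
    n = s.shape[1]
    c = np.zeros(n)
    c[c_max_index] = -1.0  # linprog minimises
    a_ub, b_ub = None, None
    if extra_lb:
        a_ub = np.zeros((len(extra_lb), n))
        b_ub = np.zeros(len(extra_lb))
        for row, (idx, lb) in enumerate(extra_lb):
            a_ub[row, idx] = -1.0
            b_ub[row] = -lb
    res = linprog(
        c, A_ub=a_ub, b_ub=b_ub, A_eq=s, b_eq=np.zeros(s.shape[0]),
        bounds=bounds, method="highs",
    )
    if not res.success:
        return None
    return -res.fun


def brute_force_nrap(
    model: MetabolicModel, growth_fraction: float = 0.5, k_step: float = 0.1
) -> dict[str, float]:
    """nRAP for every gene-associated reaction, from first principles.

    Re-derives biomass max, FVA ranges and all sweep LPs with scipy/HiGHS
    and fits the slope by ordinary least squares.
    """
    s, rxns, bounds = _lp_arrays(model)
    idx = {rid: j for j, rid in enumerate(rxns)}
    j_bio = idx[model.biomass_reaction]
    j_tgt = idx[model.target_reaction]

    vbm = _solve(s, bounds, j_bio)
    assert vbm is not None, "oracle: model infeasible"
    growth = [(j_bio, growth_fraction * vbm)]

    n = int(round(1.0 / k_step))
    ks = np.linspace(0.0, 1.0, n + 1)
    out = {}
    for r in model.gene_associated_reactions():
        j = idx[r.id]
        # FVA min and max of reaction j under the growth requirement
        vmax = _solve(s, bounds, j, extra_lb=growth)
        c = np.zeros(len(rxns))
        c[j] = 1.0
        a_ub = np.array([[0.0] * len(rxns)])
        a_ub[0, j_bio] = -1.0
        res = linprog(
            c, A_ub=a_ub, b_ub=[-growth_fraction * vbm], A_eq=s,
            b_eq=np.zeros(s.shape[0]), bounds=bounds, method="highs",
        )
        assert res.success and vmax is not None
        vmin = res.fun
        vt = np.empty_like(ks)
        for i, k in enumerate(ks):
            v = vmin + k * (vmax - vmin)
            fixed = list(bounds)
            fixed[j] = (v, v)
            val = _solve(s, fixed, j_tgt, extra_lb=growth)
            assert val is not None, f"oracle: sweep point infeasible for {r.id}"
            vt[i] = val
        slope = 0.0 if vmax == vmin else float(np.polyfit(ks, vt, 1)[0])
        out[r.id] = slope
    return out


def path_enumeration_gtre(
    edges: list[tuple[str, str, float]],
    tre: dict[str, float],
    nodes: list[str],
) -> dict[str, float]:
    """gTRE by summing (product of edge nRS) * TRE(end) over all paths.

    Plain recursion over every directed path in the DAG — exponential, fine
    for the <= 12-node graphs it is used on.
    """
    children: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}
    for u, v, w in edges:
        children[u].append((v, w))

    def extra(node: str) -> float:
        total = 0.0
        for child, w in children[node]:
            total += w * (tre.get(child, 0.0) + extra(child))
        return total

    return {n: tre.get(n, 0.0) + extra(n) for n in nodes}


def naive_significance_q(
    gap_rows: list[tuple[str, str, float]],  # (gene, reaction, gprf)
    interactions: list[tuple[str, str, float]],  # (tr, gene, nrs)
    tre: dict[str, float],
    reaction_ids: list[str],
    lo: float,
    hi: float,
    n_draws: int,
    window: float,
    seed: int,
) -> dict[str, float]:
    """Re-implementation of the randomisation sampler with per-draw loops.

    Consumes the RNG identically (one uniform block over sorted reaction
    ids) but recomputes every random TRE by looping over interactions and
    gene-reaction rows instead of a matrix product.
    """
    rng = np.random.default_rng(seed)
    reaction_ids = sorted(reaction_ids)
    draws = rng.uniform(lo, hi, size=(n_draws, len(reaction_ids)))
    col = {rid: i for i, rid in enumerate(reaction_ids)}
    by_gene: dict[str, list[tuple[str, float]]] = {}
    for gene, rid, gprf in gap_rows:
        by_gene.setdefault(gene, []).append((rid, gprf))

    hits = {t: 0 for t in tre}
    for d in range(n_draws):
        rand_tre = dict.fromkeys(tre, 0.0)
        for tr, gene, nrs in interactions:
            for rid, gprf in by_gene.get(gene, []):
                if rid in col:
                    rand_tre[tr] += nrs * draws[d, col[rid]] / gprf
        for t, actual in tre.items():
            if abs(rand_tre[t] - actual) <= window * abs(actual):
                hits[t] += 1
    return {t: hits[t] / n_draws for t in tre}
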