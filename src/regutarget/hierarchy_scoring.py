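"""TR hierarchy, local/global regulator effects (TRE/gTRE) and ranking.

Regulators form a cascade: global regulators control other regulators,
which control metabolic genes.  A regulator's *local* effect on the
product flux is the regulon-weighted sum of its targets' gene scores,

    TRE_i = sum over regulated genes j and their reactions r of
            nRS_ij * nGAP_jr .

Its *global* effect adds, recursively, the effects of the downstream
regulators it controls:

    gTRE(i) = TRE(i) + sum over retained TR->TR edges (i -> c) of
              nRS_ic * gTRE(c) ,

evaluated bottom-up over the hierarchy levels.  Self-regulating edges and
edges inside feedback loops are excluded before levelling: a negative
feedback loop would cancel to zero and a positive one would blow up
geometrically, so either way the recursion is only meaningful on the
acyclic remainder.  Levels are assigned by longest path from the roots, so
every retained edge points strictly downward.

A randomisation filter guards TRE against chance: reaction slopes are
redrawn uniformly within the observed slope range ~1000 times, TRE is
recomputed for each draw, and a regulator whose actual TRE is frequently
matched (within +-10%) by random draws is deemed non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import ConfigurationError
from .flux_scoring import GAPTable, RAPTable
from .regulatory import RegulatoryInteraction

__all__ = [
    "Hierarchy",
    "build_hierarchy",
    "compute_tre",
    "significance_filter",
    "compute_gtre",
    "rank_targets",
]

#: |TRE| below this is treated as exactly zero for the significance window
TRE_ZERO_TOL = 1e-9


@dataclass
class Hierarchy:
    """Levelled, acyclic TR->TR graph with the excluded-edge log.

    ``level`` maps each TR to an integer level p (1 = top, i.e. not
    regulated by any retained TR); ``h`` is the total number of levels.
    Retained edges always run from a lower-numbered to a strictly
    higher-numbered level.
    """

    level: dict[str, int]
    h: int
    retained_edges: list[tuple[str, str, float]]  # (regulator, target, nRS)
    excluded_edges: list[tuple[str, str, str]] = field(default_factory=list)  # +reason

    def to_tsv(self, edge_path, level_path=None) -> None:
        edges = pd.DataFrame(
            [
                (u, v, nrs, self.level[u], self.level[v], "retained")
                for u, v, nrs in self.retained_edges
            ]
            + [
                (u, v, np.nan, self.level.get(u, -1), self.level.get(v, -1), reason)
                for u, v, reason in self.excluded_edges
            ],
            columns=["regulator", "target", "nrs", "level_regulator", "level_target", "status"],
        )
        edges.to_csv(edge_path, sep="\t", index=False)
        if level_path is not None:
            pd.DataFrame(
                sorted(self.level.items()), columns=["tr_id", "level"]
            ).to_csv(level_path, sep="\t", index=False)


def build_hierarchy(interactions: Iterable[RegulatoryInteraction]) -> Hierarchy:
    """Level the TR->TR graph after pruning self-loops and feedback loops.

    All edges internal to a strongly connected component of size > 1 are
    excluded (the component's TRs stay as nodes, keeping their regulons in
    play).  On the remaining DAG, level(v) = 1 for TRs with no retained
    incoming edge, else 1 + max level over retained regulators — longest-
    path layering, which makes every retained edge strictly downward.
    """
    interactions = list(interactions)
    g = nx.DiGraph()
    excluded: list[tuple[str, str, str]] = []
    for ia in interactions:
        g.add_node(ia.regulator)
        g.add_node(ia.target)
        if ia.regulator == ia.target:
            excluded.append((ia.regulator, ia.target, "self-loop"))
            continue
        g.add_edge(ia.regulator, ia.target, nrs=ia.nrs)

    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            for u, v in list(g.edges()):
                if u in scc and v in scc:
                    excluded.append((u, v, "cycle"))
                    g.remove_edge(u, v)

    level: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        level[node] = 1 if not preds else 1 + max(level[p] for p in preds)
    h = max(level.values(), default=0)
    retained = [(u, v, g.edges[u, v]["nrs"]) for u, v in g.edges()]
    return Hierarchy(level=level, h=h, retained_edges=retained, excluded_edges=excluded)


def compute_tre(
    gap: GAPTable,
    interactions: Iterable[RegulatoryInteraction],
    tr_ids: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Local effect TRE_i = sum of nRS_ij * nGAP_jr over the regulon.

    The sum runs over every interaction i -> j whose target gene j appears
    in the gene-score table, and over every reaction r carrying j.  TRs in
    ``tr_ids`` (default: all regulators seen in ``interactions``) that
    regulate no scored metabolic gene get TRE = 0.
    """
    interactions = [ia for ia in interactions if ia.nrs is not None]
    trs = set(tr_ids) if tr_ids is not None else {ia.regulator for ia in interactions}
    trs |= {ia.regulator for ia in interactions}
    tre = dict.fromkeys(trs, 0.0)
    if not gap.table.empty:
        gene_scores = gap.table.groupby("gene")["ngap"].sum()
        for ia in interactions:
            if ia.target in gene_scores.index:
                tre[ia.regulator] += ia.nrs * float(gene_scores[ia.target])
    return pd.Series(tre, dtype=float).sort_index()


def _tre_coefficients(
    gap: GAPTable,
    interactions: list[RegulatoryInteraction],
    tr_ids: list[str],
    reaction_ids: list[str],
) -> np.ndarray:
    """Matrix C with TRE_i = sum_r C[i, r] * nRAP_r.

    C[i, r] = sum over interactions i->j and gap rows (j, r) of
    nRS_ij / GPRf_jr — TRE is linear in the slope vector, which lets the
    randomisation filter evaluate all draws as one matrix product.
    """
    tr_index = {t: i for i, t in enumerate(tr_ids)}
    rxn_index = {r: i for i, r in enumerate(reaction_ids)}
    c = np.zeros((len(tr_ids), len(reaction_ids)))
    if gap.table.empty:
        return c
    by_gene = {
        gene: list(zip(sub["reaction_id"], sub["gprf"]))
        for gene, sub in gap.table.groupby("gene")
    }
    for ia in interactions:
        if ia.nrs is None or ia.target not in by_gene:
            continue
        i = tr_index[ia.regulator]
        for rid, gprf in by_gene[ia.target]:
            if rid in rxn_index:
                c[i, rxn_index[rid]] += ia.nrs / gprf
    return c


def significance_filter(
    gap: GAPTable,
    rap: RAPTable,
    interactions: Iterable[RegulatoryInteraction],
    tre: pd.Series,
    n_draws: int = 1000,
    window: float = 0.10,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomisation test of each TRE against chance-level slope sets.

    For each of ``n_draws`` draws, every scored reaction receives a random
    slope sampled uniformly from the global [min, max] of the observed
    nRAP values; gene scores and TREs are recomputed.  ``q_i`` is the
    fraction of draws whose random TRE_i falls within ``+-window * |TRE_i|``
    of the actual TRE_i; a TR is significant when ``q_i < alpha``.  TRs
    with |TRE| below the zero tolerance are never significant (the window
    collapses to a point).  Draws are consumed in sorted-reaction-id order,
    so a fixed seed reproduces q bit-identically.

    Returns a DataFrame indexed by TR id with columns ``q``, ``significant``.
    """
    if n_draws < 1:
        raise ConfigurationError(f"n_draws must be >= 1, got {n_draws}")
    interactions = [ia for ia in interactions if ia.nrs is not None]
    tr_ids = list(tre.index)
    observed = rap.nrap()
    reaction_ids = sorted(observed.index)
    rng = np.random.default_rng(seed)

    if reaction_ids:
        lo = float(observed.min())
        hi = float(observed.max())
        draws = rng.uniform(lo, hi, size=(n_draws, len(reaction_ids)))
        c = _tre_coefficients(gap, interactions, tr_ids, reaction_ids)
        random_tre = draws @ c.T  # (n_draws, n_tr)
    else:
        random_tre = np.zeros((n_draws, len(tr_ids)))

    actual = tre.reindex(tr_ids).to_numpy()
    within = np.abs(random_tre - actual) <= window * np.abs(actual)
    q = within.mean(axis=0)
    near_zero = np.abs(actual) < TRE_ZERO_TOL
    q = np.where(near_zero, 1.0, q)
    significant = (q < alpha) & ~near_zero
    return pd.DataFrame({"q": q, "significant": significant}, index=tr_ids)


def compute_gtre(
    hierarchy: Hierarchy,
    tre: pd.Series,
    significant: Optional[Mapping[str, bool]] = None,
    strict: bool = False,
) -> pd.Series:
    """Propagate effects bottom-up: gTRE(i) = TRE(i) + sum nRS_ic * gTRE(c).

    Evaluated from the bottom level (h) to the top (1); TRs without
    retained TR children keep gTRE = TRE.  A TR that failed the
    significance filter contributes 0 of its own TRE but still conducts
    its children's gTRE upward; with ``strict=True`` such TRs are removed
    outright, severing the paths through them.
    """
    nodes = sorted(set(hierarchy.level) | set(tre.index))
    sig = dict.fromkeys(nodes, True)
    if significant is not None:
        sig.update({k: bool(v) for k, v in significant.items()})

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v, nrs in hierarchy.retained_edges:
        g.add_edge(u, v, nrs=0.0 if nrs is None else nrs)
    if strict:
        dead = [n for n in nodes if not sig[n]]
        g.remove_nodes_from(dead)
        nodes = [n for n in nodes if sig[n]]

    try:
        order = list(reversed(list(nx.topological_sort(g))))
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - contract guard
        raise RuntimeError("hierarchy contains a cycle; build_hierarchy must prune it") from exc

    gtre: dict[str, float] = {}
    for node in order:
        own = float(tre.get(node, 0.0)) if sig[node] else 0.0
        acc = own
        for _, child, data in g.out_edges(node, data=True):
            acc += data["nrs"] * gtre[child]
        gtre[node] = acc
    return pd.Series(gtre, dtype=float).sort_index()


def rank_targets(scores: pd.DataFrame) -> pd.DataFrame:
    """Sort TRs by gTRE (descending) into an engineering-target report.

    Positive-gTRE TRs are upregulation candidates, negative ones
    downregulation candidates, exact zeros neutral.  Ties break by |TRE|
    (descending) then TR id.  Expects columns ``tre`` and ``gtre`` indexed
    by TR id; returns the frame with ``rank`` and ``direction`` added,
    sorted.
    """
    df = scores.copy()
    df.index.name = "tr_id"
    df["_abs_tre"] = df["tre"].abs()
    df = (
        df.reset_index()
        .sort_values(
            by=["gtre", "_abs_tre", "tr_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("tr_id")
        .drop(columns=["_abs_tre"])
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["direction"] = np.select(
        [df["gtre"] > 0, df["gtre"] < 0], ["upregulate", "downregulate"], "neutral"
    )
    return df
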