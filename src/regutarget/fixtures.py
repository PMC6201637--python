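"""Self-contained toy instance with planted ground truth, plus evaluation metrics.

The toy instance stands in for a genome-scale model + curated TRN +
transcriptome triple, small enough that every number in the pipeline can
be checked by hand:

* **Metabolism** (9 reactions): carbon uptake ``UPT`` (-> A), a 3-step
  product path ``PP1`` (A->B), ``PP2`` (B->C), ``PP3`` (C->P, catalysed by
  the two-subunit complex ``gP3a and gP3b``), a 2-step biomass-precursor
  path ``BM1`` (A->E), ``BM2`` (E->F), a competing drain ``DRN`` (B->),
  the biomass sink ``BIOMASS`` (F->) and the product exchange ``EX_P``
  (P->).  With 10 units of uptake and the default 50% growth requirement,
  product-path reactions have slope +5, and the drain and biomass-path
  reactions slope -5.

* **Regulation** (7 TRs, 13 file rows): an activator of the product-path
  genes (``t_act``, the planted overexpression target), an activator of
  the drain and a biomass gene (``t_drain``, the planted downregulation
  target), a repressor of a product-path gene (``t_rep``), a 3-level
  cascade ``t_top -> {t_act, t_mid}``, ``t_mid -| t_drain``, a 2-TR
  feedback loop ``t_c1 <-> t_c2`` and one self-loop on ``t_act`` — so the
  loop-exclusion rules run inside every end-to-end test.

* **Expression**: integer intensities; each id's producer/non-producer
  pair is multiplied by a seed-dependent integer, which changes the
  magnitudes but leaves every nRS (a ratio of relative changes) exactly
  invariant — different seeds therefore keep the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import MetabolicModel, Reaction, parse_gpr
from .regulatory import ExpressionTable, RegulatoryInteraction

__all__ = [
    "ToyInstance",
    "ClassificationCounts",
    "make_toy_instance",
    "classification_metrics",
]

BIG = 1000.0

# (id, stoichiometry, lb, ub, gpr)
_TOY_REACTIONS = [
    ("UPT", {"A": 1}, 0.0, 10.0, None),
    ("PP1", {"A": -1, "B": 1}, 0.0, BIG, "gP1"),
    ("PP2", {"B": -1, "C": 1}, 0.0, BIG, "gP2"),
    ("PP3", {"C": -1, "P": 1}, 0.0, BIG, "gP3a and gP3b"),
    ("BM1", {"A": -1, "E": 1}, 0.0, BIG, "gB1"),
    ("BM2", {"E": -1, "F": 1}, 0.0, BIG, "gB2"),
    ("DRN", {"B": -1}, 0.0, BIG, "gD"),
    ("BIOMASS", {"F": -1}, 0.0, BIG, None),
    ("EX_P", {"P": -1}, 0.0, BIG, None),
]

# (regulator, target, effect token) — file order; includes one self-loop
_TOY_TRN_ROWS = [
    ("t_act", "gP1", "+"),
    ("t_act", "gP2", "+"),
    ("t_act", "gP3a", "+"),
    ("t_rep", "gP3a", "-"),
    ("t_drain", "gD", "+"),
    ("t_drain", "gB1", "+"),
    ("t_top", "t_act", "+"),
    ("t_top", "t_mid", "+"),
    ("t_mid", "t_drain", "-"),
    ("t_c1", "t_c2", "+"),
    ("t_c2", "t_c1", "+"),
    ("t_c1", "gB2", "-"),
    ("t_act", "t_act", "+"),  # self-loop, dropped by the reader
]

# id -> (nonproducer, producer) base intensities; chosen so every edge's
# nRS sign matches its curated effect and the planted ordering holds
_TOY_EXPRESSION = {
    "t_act": (100, 200),
    "t_rep": (200, 100),
    "t_drain": (100, 50),
    "t_top": (50, 300),
    "t_mid": (100, 150),
    "t_c1": (100, 150),
    "t_c2": (100, 150),
    "gP1": (100, 300),
    "gP2": (100, 250),
    "gP3a": (100, 200),
    "gP3b": (120, 120),
    "gB1": (200, 100),
    "gB2": (100, 80),
    "gD": (100, 40),
}


@dataclass
class ToyInstance:
    """In-memory toy inputs plus the planted ground truth."""

    model: MetabolicModel
    trn: list[RegulatoryInteraction]  # self-loop already pruned, as read_trn returns
    expression: ExpressionTable
    ground_truth: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)  # set when files written


def _build_cobra_model():
    import cobra

    cm = cobra.Model("toy")
    mets = {
        mid: cobra.Metabolite(mid, compartment="c")
        for mid in ("A", "B", "C", "P", "E", "F")
    }
    cm.add_metabolites(list(mets.values()))
    reactions = []
    for rid, stoich, lb, ub, gpr in _TOY_REACTIONS:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        reactions.append(r)
    cm.add_reactions(reactions)
    for (rid, stoich, lb, ub, gpr), r in zip(_TOY_REACTIONS, reactions):
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if gpr:
            r.gene_reaction_rule = gpr
    cm.objective = "BIOMASS"
    return cm


def make_toy_instance(
    seed: int = 1, outdir: Optional[str | Path] = None
) -> ToyInstance:
    """Build the toy instance; optionally write SBML + TSV inputs to ``outdir``.

    Deterministic for a given seed.  The seed only rescales expression
    magnitudes (per-id integer factor in {1, 2, 3}); topology, signs and
    the planted ranking are identical across seeds.
    """
    cm = _build_cobra_model()
    model = MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=[
            Reaction(rid, dict(stoich), lb, ub, parse_gpr(gpr) if gpr else None)
            for rid, stoich, lb, ub, gpr in _TOY_REACTIONS
        ],
        biomass_reaction="BIOMASS",
        target_reaction="EX_P",
        genes=sorted(g.id for g in cm.genes),
        cobra_model=cm,
    )

    vocab = {"+": 1, "-": -1}
    trn = [
        RegulatoryInteraction(reg, tgt, vocab[eff])
        for reg, tgt, eff in _TOY_TRN_ROWS
        if reg != tgt
    ]

    rng = np.random.default_rng(seed)
    ids = sorted(_TOY_EXPRESSION)
    scale = {i: int(rng.integers(1, 4)) for i in ids}
    expr_df = pd.DataFrame(
        {
            "producer": {i: _TOY_EXPRESSION[i][1] * scale[i] for i in ids},
            "nonproducer": {i: _TOY_EXPRESSION[i][0] * scale[i] for i in ids},
        },
        dtype=float,
    )
    expr_df.index.name = "id"
    expression = ExpressionTable(values=expr_df)

    ground_truth = {
        "nrap_sign": {
            "PP1": 1, "PP2": 1, "PP3": 1, "BM1": -1, "BM2": -1, "DRN": -1,
        },
        "levels": {
            "t_top": 1, "t_c1": 1, "t_c2": 1, "t_act": 2, "t_mid": 2, "t_drain": 3,
        },
        "h": 3,
        "top_tr": "t_act",
        "bottom_tr": "t_drain",
    }

    instance = ToyInstance(
        model=model, trn=trn, expression=expression, ground_truth=ground_truth
    )
    if outdir is not None:
        instance.paths = _write_instance(instance, Path(outdir), expr_df)
    return instance


def _write_instance(
    instance: ToyInstance, outdir: Path, expr_df: pd.DataFrame
) -> dict[str, Path]:
    from cobra.io import write_sbml_model

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": outdir / "toy_model.xml",
        "trn": outdir / "toy_trn.tsv",
        "expression": outdir / "toy_expression.tsv",
    }
    write_sbml_model(instance.model.cobra_model, str(paths["model"]))
    pd.DataFrame(
        _TOY_TRN_ROWS, columns=["regulator", "target", "effect"]
    ).to_csv(paths["trn"], sep="\t", index=False)
    out = pd.DataFrame(
        {
            "id": expr_df.index,
            "producer_1": expr_df["producer"].to_numpy(),
            "nonproducer_1": expr_df["nonproducer"].to_numpy(),
        }
    )
    out.to_csv(paths["expression"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Binary-classification evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationCounts:
    """TP/FP/FN counts and the derived literature-validation metrics.

    True negatives are deliberately absent: when validation rests on
    published evidence, the universe of confirmed non-targets is unknown,
    so only TP/FP/FN-based measures are meaningful.
    """

    tp: int
    fp: int
    fn: int
    tpr: float  # sensitivity, TP/(TP+FN)
    ppv: float  # precision, TP/(TP+FP)
    fnr: float  # 1 - TPR
    fdr: float  # 1 - PPV
    f1: float  # harmonic mean of PPV and TPR
    fp_fn_ratio: float


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classification_metrics(
    tp: int, fp: int, fn: int, decimals: int = 3
) -> ClassificationCounts:
    """Sensitivity, precision, FNR, FDR, F1 and FP/FN from raw counts.

    All derived values are computed from the unrounded intermediates and
    rounded half-up to ``decimals`` at the end.  Zero denominators raise,
    naming the metric they would break.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("TP+FN = 0: sensitivity (TPR) undefined")
    if tp + fp == 0:
        raise ValueError("TP+FP = 0: precision (PPV) undefined")
    if fn == 0 and fp > 0:
        raise ValueError("FN = 0 with FP > 0: FP/FN ratio undefined")
    tpr = tp / (tp + fn)
    ppv = tp / (tp + fp)
    f1 = 2 * ppv * tpr / (ppv + tpr) if (ppv + tpr) > 0 else 0.0
    fp_fn = fp / fn if fn > 0 else 0.0
    return ClassificationCounts(
        tp=tp,
        fp=fp,
        fn=fn,
        tpr=_round_half_up(tpr, decimals),
        ppv=_round_half_up(ppv, decimals),
        fnr=_round_half_up(1 - tpr, decimals),
        fdr=_round_half_up(1 - ppv, decimals),
        f1=_round_half_up(f1, decimals),
        fp_fn_ratio=_round_half_up(fp_fn, decimals),
    )
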