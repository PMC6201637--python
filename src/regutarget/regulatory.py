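"""Signed regulatory network, two-condition expression, and nRS scores.

A transcriptional regulatory network (TRN) is a signed directed graph of
regulator -> target interactions: effect +1 (activation), -1 (repression)
or 0 (dual/unknown, printed "+-").  Combined with expression intensities
measured in a producing and a non-producing condition, each interaction
receives a normalised regulatory strength

    nRS_ij = ((Gene_j,prod - Gene_j,nprod) / (TR_i,prod - TR_i,nprod))
             * (TR_i,nprod / Gene_j,nprod)

— the ratio of the gene's relative expression change to the regulator's
relative change.  The normalisation factor (second term) stops lowly
expressed regulators from collecting inflated strengths purely because
their absolute change is small.  Interactions whose empirical nRS sign
contradicts the curated effect (an "activator" with negative nRS, or a
repressor with positive nRS) are filtered out; dual-effect interactions
pass either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "RegulatoryInteraction",
    "ExpressionTable",
    "ExclusionLog",
    "TRNParseError",
    "read_trn",
    "read_expression",
    "compute_nrs",
    "filter_sign_consistency",
]

logger = logging.getLogger(__name__)

#: |TR_prod - TR_nprod| below this multiple of TR_nprod counts as "unchanged"
DELTA_TR_REL_TOL = 1e-8

_EFFECT_VOCAB = {
    "regulondb": {
        "+": 1, "-": -1, "+-": 0, "-+": 0, "?": 0, "activator": 1,
        "repressor": -1, "dual": 0,
    },
    "abasy": {
        "activator": 1, "repressor": -1, "dual": 0, "unknown": 0,
        "+": 1, "-": -1, "+-": 0, "-+": 0,
    },
    "generic": {
        "+": 1, "-": -1, "+-": 0, "-+": 0, "0": 0, "1": 1, "-1": -1,
        "activator": 1, "repressor": -1, "dual": 0,
        "activation": 1, "repression": -1,
    },
}


class TRNParseError(ValueError):
    """A TRN file row could not be interpreted."""


@dataclass(frozen=True)
class RegulatoryInteraction:
    """One signed regulator -> target edge, optionally scored with nRS."""

    regulator: str
    target: str
    effect: int  # +1 activator, -1 repressor, 0 dual/unknown
    nrs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect not in (-1, 0, 1):
            raise ValueError(f"effect must be -1, 0 or +1, got {self.effect}")


@dataclass
class ExclusionLog:
    """Accounting of interactions removed at each stage, with reasons."""

    self_loop: list[RegulatoryInteraction]
    missing_expression: list[RegulatoryInteraction]
    zero_denominator: list[RegulatoryInteraction]
    sign_conflict: list[RegulatoryInteraction]

    def __init__(self) -> None:
        self.self_loop = []
        self.missing_expression = []
        self.zero_denominator = []
        self.sign_conflict = []

    def counts(self) -> dict[str, int]:
        return {
            "self_loop": len(self.self_loop),
            "missing_expression": len(self.missing_expression),
            "zero_denominator": len(self.zero_denominator),
            "sign_conflict": len(self.sign_conflict),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for reason in ("self_loop", "missing_expression", "zero_denominator", "sign_conflict"):
            for ia in getattr(self, reason):
                rows.append((ia.regulator, ia.target, ia.effect, reason))
        return pd.DataFrame(rows, columns=["regulator", "target", "effect", "reason"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_trn(
    path: str | Path,
    dialect: str = "generic",
    log: Optional[ExclusionLog] = None,
) -> list[RegulatoryInteraction]:
    """Read a 3-column TSV (regulator, target, effect) into signed edges.

    ``dialect`` selects the effect vocabulary ("regulondb", "abasy" or
    "generic").  Self-interactions are dropped (and counted in ``log``);
    duplicate regulator->target edges collapse to one, and conflicting
    signs collapse to effect 0 (dual).  Unknown effect tokens raise
    :class:`TRNParseError` with the offending line number.
    """
    try:
        vocab = _EFFECT_VOCAB[dialect]
    except KeyError:
        raise TRNParseError(
            f"unknown TRN dialect {dialect!r}; choose from {sorted(_EFFECT_VOCAB)}"
        ) from None
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise TRNParseError(f"{path}: expected 3 columns (regulator, target, effect)")
    df = df.iloc[:, :3]
    df.columns = ["regulator", "target", "effect"]

    seen: dict[tuple[str, str], int] = {}
    n_self = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        token = str(row.effect).strip().lower()
        if token not in vocab:
            raise TRNParseError(
                f"{path}, line {line_no}: unknown effect token {row.effect!r} "
                f"for dialect {dialect!r}"
            )
        effect = vocab[token]
        reg, tgt = str(row.regulator).strip(), str(row.target).strip()
        if reg == tgt:
            n_self += 1
            if log is not None:
                log.self_loop.append(RegulatoryInteraction(reg, tgt, effect))
            continue
        key = (reg, tgt)
        if key in seen and seen[key] != effect:
            seen[key] = 0  # conflicting curation -> dual
        else:
            seen[key] = effect
    if n_self:
        logger.info("read_trn: dropped %d self-regulating interaction(s)", n_self)
    return [RegulatoryInteraction(r, t, e) for (r, t), e in seen.items()]


@dataclass
class ExpressionTable:
    """Per-id producer / non-producer intensities (replicates averaged)."""

    values: pd.DataFrame  # index: id; columns: producer, nonproducer
    n_producer_reps: int = 1
    n_nonproducer_reps: int = 1

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def producer(self, gene_id: str) -> float:
        return float(self.values.at[gene_id, "producer"])

    def nonproducer(self, gene_id: str) -> float:
        return float(self.values.at[gene_id, "nonproducer"])


def read_expression(path: str | Path) -> ExpressionTable:
    """Read an expression TSV: id column plus producer_*/nonproducer_* columns.

    Replicate columns are averaged per condition.  Rows with a missing or
    nonpositive mean in either condition are excluded (logged): nRS is a
    ratio of ratios, so a zero denominator would be meaningless.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    id_col = df.columns[0]
    prod_cols = [c for c in df.columns if c.lower().startswith("producer")]
    nprod_cols = [c for c in df.columns if c.lower().startswith("nonproducer")]
    if not prod_cols or not nprod_cols:
        raise ValueError(
            f"{path}: need >=1 'producer_*' and >=1 'nonproducer_*' column, "
            f"got {list(df.columns)}"
        )
    out = pd.DataFrame(
        {
            "producer": df[prod_cols].mean(axis=1).to_numpy(),
            "nonproducer": df[nprod_cols].mean(axis=1).to_numpy(),
        },
        index=pd.Index(df[id_col].astype(str), name="id"),
    )
    n_before = len(out)
    out = out.dropna()
    out = out[(out["producer"] > 0) & (out["nonproducer"] > 0)]
    n_dropped = n_before - len(out)
    if n_dropped:
        logger.info(
            "read_expression: excluded %d row(s) with missing/nonpositive values",
            n_dropped,
        )
    dup = out.index.duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate ids {sorted(set(out.index[dup]))}")
    return ExpressionTable(
        values=out,
        n_producer_reps=len(prod_cols),
        n_nonproducer_reps=len(nprod_cols),
    )


def compute_nrs(
    interactions: Iterable[RegulatoryInteraction],
    expression: ExpressionTable,
    log: Optional[ExclusionLog] = None,
) -> list[RegulatoryInteraction]:
    """Attach nRS to every interaction whose regulator and target are measured.

    Interactions with missing expression, an (effectively) unchanged
    regulator, or a nonpositive gene baseline are excluded and logged —
    never clamped, since a pseudocount would invent regulation.  Raises if
    no interaction overlaps the expression table at all (the pipeline
    would be vacuous).
    """
    interactions = list(interactions)
    if log is None:
        log = ExclusionLog()
    any_overlap = any(
        ia.regulator in expression or ia.target in expression for ia in interactions
    )
    if interactions and not any_overlap:
        raise ValueError(
            "no overlap between expression ids and TRN ids; "
            "check that the two inputs use the same gene identifiers"
        )
    scored = []
    for ia in interactions:
        if ia.regulator not in expression or ia.target not in expression:
            log.missing_expression.append(ia)
            continue
        t_p, t_n = expression.producer(ia.regulator), expression.nonproducer(ia.regulator)
        g_p, g_n = expression.producer(ia.target), expression.nonproducer(ia.target)
        dt = t_p - t_n
        if abs(dt) < DELTA_TR_REL_TOL * abs(t_n) or g_n <= 0:
            log.zero_denominator.append(ia)
            continue
        nrs = ((g_p - g_n) / dt) * (t_n / g_n)
        scored.append(replace(ia, nrs=nrs))
    return scored


def filter_sign_consistency(
    interactions: Iterable[RegulatoryInteraction],
    per_tr: bool = False,
    log: Optional[ExclusionLog] = None,
) -> list[RegulatoryInteraction]:
    """Drop interactions whose nRS sign contradicts the curated effect.

    An activator (+1) with negative nRS, or a repressor (-1) with positive
    nRS, is inconsistent.  Dual interactions (effect 0) always pass.  With
    ``per_tr=True`` a single inconsistent edge disqualifies the regulator's
    entire edge set (the stricter reading); the default removes only the
    offending edges.
    """
    interactions = list(interactions)

    def inconsistent(ia: RegulatoryInteraction) -> bool:
        if ia.nrs is None:
            return False
        return (ia.effect == 1 and ia.nrs < 0) or (ia.effect == -1 and ia.nrs > 0)

    if per_tr:
        bad_trs = {ia.regulator for ia in interactions if inconsistent(ia)}
        kept = [ia for ia in interactions if ia.regulator not in bad_trs]
        removed = [ia for ia in interactions if ia.regulator in bad_trs]
    else:
        kept = [ia for ia in interactions if not inconsistent(ia)]
        removed = [ia for ia in interactions if inconsistent(ia)]
    if log is not None:
        log.sign_conflict.extend(removed)
    return kept
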