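"""Consensus interactions across tools and relative accuracy metrics.

Because no experimental ground truth exists for cell-cell interactions, a
*relative* reference can be built from the predictions themselves: an
interaction predicted for the same directed cell-type pair by at least
``min_tools`` distinct tools (3 by default) joins the consensus set.  Each
tool is then scored against the consensus — or against simulated ground
truth — with precision, recall and F1:

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall).

Metrics are computed per cell-type pair and macro-averaged over pairs with a
non-empty reference; pooled (micro) totals are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .des import PredictionTable, canonical_interaction_key
from .lr_database import LRDatabase

__all__ = [
    "ConsensusSet",
    "AccuracyMetrics",
    "build_consensus",
    "accuracy_vs_reference",
    "lr_product_baseline",
]

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]  # ordered (source, target)
LRKey = tuple[str, str]  # canonical (ligand, receptor)


@dataclass
class ConsensusSet:
    """Interactions shared by at least ``min_tools`` tools, per directed pair."""

    per_pair: dict[PairKey, set[LRKey]]
    min_tools: int
    contributing_tools: list[str]

    def reference_for(self, pair: PairKey) -> set[LRKey]:
        return self.per_pair.get(pair, set())

    @property
    def pairs(self) -> list[PairKey]:
        return sorted(self.per_pair)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source_celltype": s,
                "target_celltype": t,
                "ligand": lig,
                "receptor": rec,
            }
            for (s, t), inters in sorted(self.per_pair.items())
            for lig, rec in sorted(inters)
        ]
        return pd.DataFrame(
            rows, columns=["source_celltype", "target_celltype", "ligand", "receptor"]
        )


def build_consensus(
    tables: Sequence[PredictionTable], min_tools: int = 3
) -> ConsensusSet:
    """Consensus of interactions predicted by >= ``min_tools`` distinct tools.

    Multiplicity counts distinct tools per ordered (source, target) pair;
    a tool predicting the same interaction twice counts once.
    """
    if len(tables) < min_tools:
        raise ValueError(
            f"need at least min_tools={min_tools} prediction tables, got {len(tables)}"
        )
    counts: dict[PairKey, dict[LRKey, set[str]]] = {}
    for table in tables:
        for pair, inters in table.directed_interactions().items():
            bucket = counts.setdefault(pair, {})
            for key in inters:
                bucket.setdefault(key, set()).add(table.tool_name)
    per_pair = {
        pair: {key for key, tools in bucket.items() if len(tools) >= min_tools}
        for pair, bucket in counts.items()
    }
    per_pair = {pair: inters for pair, inters in per_pair.items() if inters}
    return ConsensusSet(
        per_pair=per_pair,
        min_tools=min_tools,
        contributing_tools=[t.tool_name for t in tables],
    )


@dataclass
class AccuracyMetrics:
    """Precision / recall / F1 of one tool against a reference set."""

    tool_name: str
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    micro_precision: float = 0.0
    micro_recall: float = 0.0
    micro_f1: float = 0.0
    per_pair: pd.DataFrame | None = field(default=None, repr=False)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _as_reference_map(reference) -> Mapping[PairKey, set[LRKey]]:
    if isinstance(reference, ConsensusSet):
        return reference.per_pair
    if isinstance(reference, pd.DataFrame):
        out: dict[PairKey, set[LRKey]] = {}
        for row in reference.itertuples(index=False):
            pair = (str(row.source_celltype), str(row.target_celltype))
            out.setdefault(pair, set()).add(
                canonical_interaction_key(row.ligand, row.receptor)
            )
        return out
    return dict(reference)


def accuracy_vs_reference(pred: PredictionTable, reference) -> AccuracyMetrics:
    """Score one tool against a consensus set or ground-truth table.

    ``reference`` may be a :class:`ConsensusSet`, a DataFrame with
    ``source_celltype, target_celltype, ligand, receptor`` columns, or a
    mapping from ordered pair to interaction-key set.  Macro metrics average
    per-pair precision/recall/F1 over pairs with a non-empty reference;
    micro metrics pool TP/FP/FN counts over the same pairs.
    """
    ref_map = _as_reference_map(reference)
    ref_map = {pair: inters for pair, inters in ref_map.items() if inters}
    if not ref_map:
        raise ValueError("reference is empty for every cell-type pair")
    predicted = pred.directed_interactions()

    rows = []
    for pair, ref in sorted(ref_map.items()):
        hits = predicted.get(pair, set())
        tp = len(hits & ref)
        fp = len(hits - ref)
        fn = len(ref - hits)
        precision, recall, f1 = _prf(tp, fp, fn)
        rows.append(
            {
                "source_celltype": pair[0],
                "target_celltype": pair[1],
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    per_pair = pd.DataFrame(rows)
    tp, fp, fn = int(per_pair.tp.sum()), int(per_pair.fp.sum()), int(per_pair.fn.sum())
    micro = _prf(tp, fp, fn)
    return AccuracyMetrics(
        tool_name=pred.tool_name,
        precision=float(per_pair.precision.mean()),
        recall=float(per_pair.recall.mean()),
        f1=float(per_pair.f1.mean()),
        tp=tp,
        fp=fp,
        fn=fn,
        micro_precision=micro[0],
        micro_recall=micro[1],
        micro_f1=micro[2],
        per_pair=per_pair,
    )


def lr_product_baseline(
    sc_counts: pd.DataFrame,
    cell_annotation: pd.Series | Mapping[str, str],
    db: LRDatabase,
    top_n: int = 10,
) -> PredictionTable:
    """Baseline predictor: rank interactions by the ligand x receptor
    mean-expression product.

    For every ordered (sender, receiver) cell-type pair, each database
    interaction is scored by (mean ligand expression in sender) x (mean
    receptor expression in receiver), with complexes taking the minimum
    subunit mean on each side; the ``top_n`` positive-scoring interactions
    per direction are emitted.

    ``sc_counts`` is a gene x cell DataFrame; ``cell_annotation`` maps cell
    id to cell type.
    """
    ann = pd.Series(cell_annotation)
    ann = ann.loc[[c for c in sc_counts.columns if c in ann.index]]
    types = sorted(ann.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")

    # mean expression per gene per type
    type_means = {}
    for ct in types:
        cells = ann.index[ann == ct]
        type_means[ct] = sc_counts[cells].mean(axis=1)

    def side_mean(means: pd.Series, subunits) -> float:
        vals = [float(means.get(g, 0.0)) for g in subunits]
        return min(vals)

    rows = []
    for sender in types:
        for receiver in types:
            if sender == receiver:
                continue
            scored = []
            for inter in db.interactions:
                lig = side_mean(type_means[sender], inter.ligand_subunits)
                rec = side_mean(type_means[receiver], inter.receptor_subunits)
                score = lig * rec
                if score > 0:
                    scored.append((score, inter))
            scored.sort(key=lambda t: (-t[0], t[1].name))
            for score, inter in scored[:top_n]:
                rows.append(
                    {
                        "source_celltype": sender,
                        "target_celltype": receiver,
                        "ligand": inter.ligand,
                        "receptor": inter.receptor,
                        "score": score,
                        "pvalue": np.nan,
                    }
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "source_celltype",
            "target_celltype",
            "ligand",
            "receptor",
            "score",
            "pvalue",
        ],
    )
    return PredictionTable(tool_name="LR_product", records=records)
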