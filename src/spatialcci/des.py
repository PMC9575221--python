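"""Distance enrichment score (DES) for CCI-tool predictions.

The DES asks whether a tool's predictions respect spatial plausibility: for
two cell types that sit close together on the slide (a *near* pair), a good
tool's predicted interactions should be enriched at the top of the expected
short-range list; for a *far* pair, at the top of the expected long-range
list.  It is a GSEA-style running-sum statistic: walking down the expected
ranked list, a matched interaction adds its confidence weight
``(1 - p) / sum of (1 - p) over all matches`` and an unmatched one subtracts
``1 / (ns - nm)``; the DES is the maximum of the running sum, which lies in
[0, 1].  A tool's summary score is the unweighted mean DES over all near and
far cell-type pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .celltype_pairs import CellTypePair
from .tendency import TendencyResult

__all__ = [
    "ExpectedRankedList",
    "PredictionTable",
    "DESResult",
    "build_expected_lists",
    "des_for_pair",
    "tool_des",
    "rank_tools",
]

logger = logging.getLogger(__name__)


def canonical_interaction_key(ligand: str, receptor: str) -> tuple[str, str]:
    """Order-normalized (ligand, receptor) identity used to match predictions
    against expected interactions; subunits within a complex are sorted."""
    lig = "+".join(sorted(p.strip() for p in str(ligand).split("+") if p.strip()))
    rec = "+".join(sorted(p.strip() for p in str(receptor).split("+") if p.strip()))
    return lig, rec


@dataclass
class ExpectedRankedList:
    """Expected short- or long-range interactions, ranked by spatial tendency.

    ``entries`` pair each interaction key with the relevant one-sided
    permutation P-value (left-sided for the short list, right-sided for the
    long list).
    """

    entries: list[tuple[tuple[str, str], float]]
    list_kind: Literal["short", "long"]

    def __post_init__(self) -> None:
        for _, p in self.entries:
            if not (0 < p <= 1):
                raise ValueError("P-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [k for k, _ in self.entries]


def build_expected_lists(
    tendency: Sequence[TendencyResult],
) -> tuple[ExpectedRankedList, ExpectedRankedList]:
    """Expected ranked lists from classified tendency results.

    The short list L_s holds all short-range interactions sorted by
    (d_ratio asc, p_left asc, name); the long list L_l all long-range
    interactions sorted by (d_ratio desc, p_right asc, name).  Either list
    may be empty, in which case DES for that side is undefined and skipped
    downstream (with a warning).
    """
    short = sorted(
        (r for r in tendency if r.range_class == "short"),
        key=lambda r: (r.d_ratio, r.p_left, r.name),
    )
    long_ = sorted(
        (r for r in tendency if r.range_class == "long"),
        key=lambda r: (-r.d_ratio, r.p_right, r.name),
    )
    if not short:
        logger.warning("no short-range interactions; near-pair DES undefined")
    if not long_:
        logger.warning("no long-range interactions; far-pair DES undefined")

    def key(r: TendencyResult) -> tuple[str, str]:
        return canonical_interaction_key(r.interaction.ligand, r.interaction.receptor)

    return (
        ExpectedRankedList([(key(r), r.p_left) for r in short], "short"),
        ExpectedRankedList([(key(r), r.p_right) for r in long_], "long"),
    )


@dataclass
class PredictionTable:
    """One tool's predicted interactions per directed cell-type pair."""

    tool_name: str
    records: pd.DataFrame

    REQUIRED = ("source_celltype", "target_celltype", "ligand", "receptor")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ValueError(f"prediction table missing column(s): {sorted(missing)}")
        if "score" not in self.records.columns:
            self.records = self.records.assign(score=np.nan)
        if "pvalue" not in self.records.columns:
            self.records = self.records.assign(pvalue=np.nan)
        dup = self.records.duplicated(subset=list(self.REQUIRED))
        if dup.any():
            self.records = self.records.loc[~dup].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def interactions_between(self, type_a: str, type_b: str) -> set[tuple[str, str]]:
        """Predicted (ligand, receptor) keys pooled over both directions."""
        rec = self.records
        mask = (
            (rec["source_celltype"] == type_a) & (rec["target_celltype"] == type_b)
        ) | ((rec["source_celltype"] == type_b) & (rec["target_celltype"] == type_a))
        sub = rec.loc[mask]
        return {
            canonical_interaction_key(l, r)
            for l, r in zip(sub["ligand"], sub["receptor"])
        }

    def directed_interactions(self) -> dict[tuple[str, str], set[tuple[str, str]]]:
        """Predicted keys grouped by ordered (source, target) pair."""
        out: dict[tuple[str, str], set[tuple[str, str]]] = {}
        for row in self.records.itertuples(index=False):
            key = (row.source_celltype, row.target_celltype)
            out.setdefault(key, set()).add(
                canonical_interaction_key(row.ligand, row.receptor)
            )
        return out


def des_for_pair(
    S: Iterable[tuple[str, str]], L: ExpectedRankedList
) -> float:
    """Running-sum DES of an observed interaction set against an expected list.

    Walking down the ranked list, position ``i`` accumulates
    ``P_match(i) - P_unmatch(i)`` where matched entries add their normalized
    confidence ``(1 - p) / sum(1 - p over matches)`` and unmatched entries
    subtract ``1 / (ns - nm)``.  The DES is the maximum of the running sum.
    Edge cases: no match -> 0; all entries matched -> 1 (no unmatched mass).
    """
    if len(L) == 0:
        raise ValueError("expected ranked list is empty")
    S = set(S)
    ns = len(L)
    matched = [key in S for key, _ in L.entries]
    nm = sum(matched)
    if nm == 0:
        logger.debug("no overlap with expected %s list: DES = 0", L.list_kind)
        return 0.0
    if nm == ns:
        logger.debug("expected %s list fully predicted: DES = 1", L.list_kind)
        return 1.0
    weights = np.array([1.0 - p for _, p in L.entries])
    match_mass = weights[matched].sum()
    if match_mass <= 0:
        # all matched P-values are exactly 1: fall back to equal weights
        steps = np.where(matched, 1.0 / nm, -1.0 / (ns - nm))
    else:
        steps = np.where(matched, weights / match_mass, -1.0 / (ns - nm))
    running = np.cumsum(steps)
    return float(max(running.max(), 0.0))


@dataclass
class DESResult:
    """Per-tool DES summary across cell-type pairs."""

    tool_name: str
    per_pair_des: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_des: float = 0.0
    rank: float | None = None


def tool_des(
    pred: PredictionTable,
    pairs: Sequence[CellTypePair],
    L_s: ExpectedRankedList,
    L_l: ExpectedRankedList,
) -> DESResult:
    """Mean DES of one tool over classified cell-type pairs.

    Near pairs are scored against the short-range list, far pairs against
    the long-range list; medium pairs do not enter the score.  Predictions
    for a pair pool both directions, since the pair distance is symmetric.
    """
    if len(pred) == 0:
        logger.warning("%s predicts nothing; DES = 0 everywhere", pred.tool_name)
    per_pair: dict[tuple[str, str], float] = {}
    for pair in pairs:
        if pair.pair_class == "near":
            L = L_s
        elif pair.pair_class == "far":
            L = L_l
        else:
            continue
        if len(L) == 0:
            continue
        S = pred.interactions_between(pair.type_a, pair.type_b)
        per_pair[pair.key()] = des_for_pair(S, L)
    mean = float(np.mean(list(per_pair.values()))) if per_pair else 0.0
    return DESResult(tool_name=pred.tool_name, per_pair_des=per_pair, mean_des=mean)


def rank_tools(results: Sequence[DESResult]) -> list[DESResult]:
    """Assign competition-free ranks (1 = largest mean DES; ties averaged)."""
    if not results:
        raise ValueError("no DES results to rank")
    scores = pd.Series([r.mean_des for r in results])
    ranks = scores.rank(ascending=False, method="average")
    out = []
    for r, rk in zip(results, ranks):
        r.rank = float(rk)
        out.append(r)
    return sorted(out, key=lambda r: r.rank)


def average_rank(per_dataset_ranks: Mapping[str, Sequence[float]]) -> pd.Series:
    """Cross-dataset average rank per tool (mean of per-dataset ranks)."""
    frame = pd.DataFrame(per_dataset_ranks)
    return frame.mean(axis=1)
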