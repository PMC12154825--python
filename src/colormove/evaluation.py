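"""Per-rank evaluation of classifications with the TP/VP/FP/FN scheme.

At an evaluated rank (say species): a prediction whose projection to that
rank equals the truth's projection is a true positive (correct at the rank
or lower); a prediction strictly above the rank but on the truth lineage is
a vague positive; anything else classified is a false positive; an
unclassified positive read is a false negative.  Reads whose truth has no
ancestor at the rank are excluded.  Negative reads (truth marked absent
from the index) count as FP when classified and are excluded (true
negatives) when not — following the Kraken 2 evaluation convention.

recall = TP / (TP + VP + FN + FP);  precision = TP / (TP + FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .taxonomy import TaxonomyTree, ancestor_at_rank

#: Truth marker for reads simulated from clades absent from the index.
NEGATIVE = "-"


@dataclass
class RankCounts:
    rank: str
    tp: int = 0
    vp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.vp + self.fp + self.fn


def tally_rank_counts(
    predictions: Mapping[str, Optional[int]],
    truth: Mapping[str, object],
    tree: TaxonomyTree,
    rank: str,
    count_negative_fp: bool = True,
) -> RankCounts:
    """Tally TP/VP/FP/FN at one rank.

    ``predictions`` maps read id -> assigned taxon (None = unclassified);
    ``truth`` maps read id -> true taxon, or :data:`NEGATIVE` / None for
    reads from clades absent from the index.
    """
    counts = RankCounts(rank=rank)
    for read_id, true_taxon in truth.items():
        pred = predictions.get(read_id)
        if true_taxon in (NEGATIVE, None):
            if pred is not None:
                if count_negative_fp:
                    counts.fp += 1
            continue  # unclassified negative = true negative, excluded
        true_taxon = int(true_taxon)  # type: ignore[arg-type]
        true_at_rank = ancestor_at_rank(tree, true_taxon, rank)
        if true_at_rank is None:
            continue  # truth label above the evaluated rank: excluded
        if pred is None:
            counts.fn += 1
            continue
        if pred not in tree.nodes:
            raise ValueError(f"prediction taxon {pred} not in taxonomy")
        pred_at_rank = ancestor_at_rank(tree, int(pred), rank)
        if pred_at_rank is not None:
            if pred_at_rank == true_at_rank:
                counts.tp += 1
            else:
                counts.fp += 1
        elif tree.is_ancestor(int(pred), true_taxon):
            counts.vp += 1
        else:
            counts.fp += 1
    return counts


def precision_recall_f1(
    counts: RankCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(precision, recall, F1); ``None`` marks an undefined value
    (zero denominator) rather than raising."""
    p_den = counts.tp + counts.fp
    r_den = counts.tp + counts.vp + counts.fn + counts.fp
    precision = counts.tp / p_den if p_den else None
    recall = counts.tp / r_den if r_den else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1
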