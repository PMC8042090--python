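"""Disagreement between the feature sets chosen by the two protocols.

Because the nested protocol reselects features in every CV loop, its choices
form a distribution over loops.  This module measures (a) how often each
feature is picked across loops, (b) what fraction of a loop's nested
selection the leaky protocol's fixed set covers (the overlap ratio), and
(c) for connectivity features, which edges the leaky protocol misses entirely
despite being picked consistently by the nested one — the qualitative finding
that leaky selection can discard genuinely informative edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ConnectivityIndex
from .selection import SelectionResult


@dataclass
class SelectionFrequency:
    """Per-feature count of CV loops in which the nested protocol selected it."""

    counts: dict[str, int]
    n_loops: int

    def __getitem__(self, feature_id: str) -> int:
        return self.counts.get(feature_id, 0)

    def ever_selected(self) -> set[str]:
        return {f for f, c in self.counts.items() if c > 0}


@dataclass
class OverlapReport:
    """Per-loop overlap ratios between the fixed and per-loop feature sets."""

    per_loop_ratio: np.ndarray  # fractions in [0, 1]
    denominator: str  # "loop" | "union"

    @property
    def mean_percent(self) -> float:
        return float(self.per_loop_ratio.mean() * 100.0)


def _as_id_lists(within_loops: Sequence) -> list[list[str]]:
    out = []
    for loop_sel in within_loops:
        if isinstance(loop_sel, SelectionResult):
            out.append(list(loop_sel.feature_ids))
        else:
            out.append(list(loop_sel))
    return out


def selection_frequency(within_loops: Sequence) -> SelectionFrequency:
    """Count, per feature, the CV loops whose nested selection contained it.

    Accepts per-loop ``SelectionResult`` objects or plain id lists.  The sum
    of all counts equals the sum of per-loop set sizes.
    """
    loops = _as_id_lists(within_loops)
    counts: dict[str, int] = {}
    for ids in loops:
        for f in set(ids):
            counts[f] = counts.get(f, 0) + 1
    return SelectionFrequency(counts=counts, n_loops=len(loops))


def overlap_ratio(
    outside_set: SelectionResult | Sequence[str],
    within_loops: Sequence,
    denominator: str = "loop",
) -> OverlapReport:
    """Fraction of each loop's nested selection that the fixed set covers.

    With the default per-loop denominator, loop ratio =
    |outside ∩ within_loop| / |within_loop|; ``denominator='union'`` divides
    every loop's intersection by |union of all within-loop sets| instead.
    Loops whose selection is empty are excluded with a warning (the protocol
    fallback normally guarantees non-empty selections).
    """
    if denominator not in ("loop", "union"):
        raise ValueError("denominator must be 'loop' or 'union'")
    outside = set(
        outside_set.feature_ids if isinstance(outside_set, SelectionResult) else outside_set
    )
    loops = _as_id_lists(within_loops)
    union_size = len(set().union(*[set(l) for l in loops])) if loops else 0

    ratios = []
    for ids in loops:
        s = set(ids)
        if not s:
            logging.getLogger(__name__).warning("empty within-loop selection excluded")
            continue
        denom = len(s) if denominator == "loop" else union_size
        ratios.append(len(outside & s) / denom)
    return OverlapReport(per_loop_ratio=np.asarray(ratios, dtype=float), denominator=denominator)


def classify_edges(
    outside_set: SelectionResult | Sequence[str],
    freq: SelectionFrequency,
    index: ConnectivityIndex,
    cutoff: int = 50,
) -> pd.DataFrame:
    """Categorize connectivity edges by how the two protocols treated them.

    * ``shared`` — in the fixed (leaky) set and selected in at least one loop;
    * ``within_only_high`` — never in the fixed set but selected in >= cutoff
      loops (the consistently-chosen edges the leaky protocol misses);
    * ``within_only_low`` — never in the fixed set, selected in 1..cutoff-1
      loops.

    Returns one row per edge in the union of ever-selected features and the
    fixed set, annotated with channel pair, band and loop frequency.
    """
    outside = set(
        outside_set.feature_ids if isinstance(outside_set, SelectionResult) else outside_set
    )
    known = set(index.feature_ids)
    involved = sorted(outside | freq.ever_selected())
    unknown = [f for f in involved if f not in known]
    if unknown:
        raise KeyError(f"feature ids not in connectivity index: {unknown[:5]}")

    lookup = index.table.set_index("feature_id")
    rows = []
    for f in involved:
        c = freq[f]
        if f in outside:
            category = "shared" if c > 0 else "outside_only"
        elif c >= cutoff:
            category = "within_only_high"
        else:
            category = "within_only_low"
        rec = lookup.loc[f]
        rows.append(
            {
                "feature_id": f,
                "channel_a": rec["channel_a"],
                "channel_b": rec["channel_b"],
                "band": rec["band"],
                "frequency": c,
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def export_edge_categories(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
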