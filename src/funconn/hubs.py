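"""Hub classification from nodal centralities.

A hub is a node whose centrality stands far above the rest of the
network — here, more than ``k_sd`` standard deviations above the mean of
the per-node centrality distribution (default 2, the common choice in
connectome toolkits, which flags a handful of nodes out of ~150).
Centrality is aggregated across the density sweep as an AUC on the
group-mean association matrix, so single-threshold artifacts do not
drive hub membership.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import (AssociationMatrix, BinaryGraph, DensitySweep,
                         binarize_at_density, group_mean_association)
from .metrics import auc_over_densities, betweenness

__all__ = ["HubSet", "HubComparison", "identify_hubs", "compare_hub_sets"]

CRITERIA = ("degree", "betweenness")


@dataclass
class HubSet:
    """Hubs of one group under one centrality criterion."""

    group_id: str
    criterion: str
    hub_nodes: list[str]
    threshold_rule: str
    densities_used: tuple[float, ...]
    scores: pd.Series  # per-node centrality AUC, indexed by ROI label
    threshold: float

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "criterion": self.criterion,
            "hub_nodes": list(self.hub_nodes),
            "threshold_rule": self.threshold_rule,
            "threshold": self.threshold,
            "densities_used": list(self.densities_used),
            "scores": {k: float(v) for k, v in self.scores.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


def _nodal_centrality(graph: BinaryGraph, criterion: str) -> np.ndarray:
    if criterion == "degree":
        return graph.degrees().astype(float)
    if criterion == "betweenness":
        return betweenness(graph)
    raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")


def identify_hubs(
    group_matrices: Sequence[AssociationMatrix],
    sweep: DensitySweep,
    criterion: str = "degree",
    k_sd: float = 2.0,
    group_id: str = "",
    negatives: str = "exclude",
) -> HubSet:
    """Flag nodes whose centrality AUC exceeds mean + k_sd * SD.

    Builds the Fisher-z group-mean association matrix, binarizes it at
    each density of the sweep, computes the nodal centrality at each
    density, integrates over the sweep, and thresholds the resulting
    per-node AUC distribution.  ``k_sd = inf`` is an explicit "no node
    qualifies" sentinel and returns an empty hub set.
    """
    if len(group_matrices) == 0:
        raise ValueError("need at least one subject")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    if len(sweep) == 0:
        raise ValueError("empty density sweep")
    mean_assoc = group_mean_association(group_matrices,
                                        subject_id=f"{group_id}_mean")
    labels = mean_assoc.roi_labels
    per_density = np.empty((len(sweep), len(labels)))
    for di, d in enumerate(sweep):
        graph = binarize_at_density(mean_assoc, d, negatives=negatives)
        per_density[di] = _nodal_centrality(graph, criterion)
    if len(sweep) >= 2:
        scores = np.array([
            auc_over_densities(per_density[:, i], sweep.densities)
            for i in range(len(labels))
        ])
    else:  # single reference density: the centrality itself is the score
        scores = per_density[0]
    mu = float(scores.mean())
    sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
    if math.isinf(k_sd):
        threshold = float("inf")
        hub_idx = np.array([], dtype=int)
    else:
        threshold = mu + k_sd * sd
        hub_idx = np.nonzero(scores > threshold)[0]
    hub_idx = hub_idx[np.argsort(-scores[hub_idx], kind="stable")]
    return HubSet(
        group_id=group_id,
        criterion=criterion,
        hub_nodes=[labels[i] for i in hub_idx],
        threshold_rule=f"centrality AUC > mean + {k_sd}*SD",
        densities_used=sweep.densities,
        scores=pd.Series(scores, index=labels),
        threshold=threshold,
    )


@dataclass
class HubComparison:
    """Set partition of two groups' hubs: shared and group-unique."""

    criterion: str
    shared: list[str]
    unique_to_a: list[str]
    unique_to_b: list[str]
    group_a: str
    group_b: str

    def to_table(self) -> str:
        """Side-by-side text table of the two groups' hub lists."""
        rows = []
        for label in self.shared:
            rows.append((label, label))
        for label in self.unique_to_a:
            rows.append((label, ""))
        for label in self.unique_to_b:
            rows.append(("", label))
        width = max([len(self.group_a)] + [len(r[0]) for r in rows]) + 2
        lines = [f"{self.group_a:<{width}}{self.group_b}",
                 "-" * (width + len(self.group_b))]
        lines += [f"{a:<{width}}{b}" for a, b in rows]
        return "\n".join(lines)


def compare_hub_sets(a: HubSet, b: HubSet) -> HubComparison:
    """Partition two hub sets into shared / unique-to-each."""
    if a.criterion != b.criterion:
        raise ValueError(
            f"criterion mismatch: {a.criterion!r} vs {b.criterion!r}")
    if set(a.scores.index) != set(b.scores.index):
        raise ValueError("hub sets come from different ROI label universes")
    sa, sb = set(a.hub_nodes), set(b.hub_nodes)
    order_a = {lab: i for i, lab in enumerate(a.hub_nodes)}
    order_b = {lab: i for i, lab in enumerate(b.hub_nodes)}
    return HubComparison(
        criterion=a.criterion,
        shared=sorted(sa & sb, key=order_a.get),
        unique_to_a=sorted(sa - sb, key=order_a.get),
        unique_to_b=sorted(sb - sa, key=order_b.get),
        group_a=a.group_id or "A",
        group_b=b.group_id or "B",
    )
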