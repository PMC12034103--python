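"""Supervised evaluation of loop clusterings against known family labels.

Subclusters are mapped to motif families either by strict majority (a
subcluster is assigned to a family only when more than a threshold
fraction -- 60% by default -- of its labelled members belong to it) or by
one-to-one Hungarian assignment.  From the induced per-loop predictions
the usual classification report (precision / recall / F1 / support,
weighted averages, accuracy, confusion matrix) is computed, along with
the per-family Motif Clustering Accuracy (MCA: known motifs of a family
landing in that family's subclusters, over all known motifs of the
family) and a structural purity analysis (fraction of multi-member
subclusters whose average pairwise RMSD stays below a mean + 2 SD bound
derived from known-family pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import confusion_matrix as _sk_confusion

from .cluster import ClusterAssignment

UNASSIGNED = "unassigned"
DEFAULT_MAJORITY_THRESHOLD = 0.60


@dataclass
class FamilyAssignment:
    """Subcluster -> family mapping with the majority fractions behind it."""

    mapping: dict            # subcluster key -> family label or UNASSIGNED
    majority_fraction: dict  # subcluster key -> largest labelled fraction
    threshold: float = DEFAULT_MAJORITY_THRESHOLD

    def family_of(self, key) -> str:
        return self.mapping.get(key, UNASSIGNED)


def map_clusters_to_labels(
    assignment: ClusterAssignment,
    true_labels,
    mode: str = "majority",
    threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    exclude=None,
) -> FamilyAssignment:
    """Assign each subcluster a family from its labelled members.

    ``true_labels`` aligns with ``assignment.loop_ids``; ``None`` entries
    are unlabelled.  ``exclude`` is an optional collection of loop_ids to
    ignore (e.g. outliers or loops with missing annotations).  In
    ``majority`` mode a subcluster gets the family of the strict-majority
    fraction (> threshold) of its labelled members; ``hungarian`` mode
    computes a one-to-one subcluster/family assignment maximizing member
    overlap.
    """
    true_labels = list(true_labels)
    if len(true_labels) != len(assignment.loop_ids):
        raise ValueError("true_labels must align with the assignment")
    excluded = set(exclude or ())
    members = assignment.members()

    counts: dict[tuple, dict[str, int]] = {}
    for key, idxs in members.items():
        tally: dict[str, int] = {}
        for idx in idxs:
            if assignment.loop_ids[idx] in excluded:
                continue
            lbl = true_labels[idx]
            if lbl is None:
                continue
            tally[lbl] = tally.get(lbl, 0) + 1
        counts[key] = tally
    if not any(counts.values()):
        raise ValueError("no labelled members to map from")

    fractions = {}
    for key, tally in counts.items():
        total = sum(tally.values())
        fractions[key] = max(tally.values()) / total if total else 0.0

    if mode == "majority":
        mapping = {}
        for key, tally in counts.items():
            if not tally:
                mapping[key] = UNASSIGNED
                continue
            best = max(sorted(tally), key=lambda fam: tally[fam])
            mapping[key] = best if fractions[key] > threshold else UNASSIGNED
        return FamilyAssignment(mapping, fractions, threshold)

    if mode == "hungarian":
        keys = sorted(counts)
        families = sorted({f for tally in counts.values() for f in tally})
        cost = np.zeros((len(keys), len(families)))
        for r, key in enumerate(keys):
            for c, fam in enumerate(families):
                cost[r, c] = -counts[key].get(fam, 0)
        rows, cols = linear_sum_assignment(cost)
        mapping = {key: UNASSIGNED for key in keys}
        for r, c in zip(rows, cols):
            if counts[keys[r]].get(families[c], 0) > 0:
                mapping[keys[r]] = families[c]
        return FamilyAssignment(mapping, fractions, threshold)

    raise ValueError(f"unknown mapping mode {mode!r}")


def predicted_labels(
    assignment: ClusterAssignment, family_assignment: FamilyAssignment
) -> list[str]:
    """Per-loop predicted family: the family its subcluster was mapped to."""
    return [family_assignment.family_of(key) for key in assignment.subcluster_keys]


@dataclass
class ClassificationReport:
    per_class: pd.DataFrame     # precision, recall, f1, support per family
    weighted: dict              # weighted-average precision/recall/f1
    accuracy: float
    confusion: pd.DataFrame     # rows true, columns predicted (incl. unassigned)


def classification_report(predicted, truth) -> ClassificationReport:
    """Standard multi-class report; unassigned predictions count as errors."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    keep = np.array([t is not None for t in truth])
    predicted, truth = predicted[keep], truth[keep]
    families = sorted(set(truth))
    all_labels = families + ([UNASSIGNED] if UNASSIGNED in set(predicted) else [])
    conf = _sk_confusion(truth, predicted, labels=all_labels)
    conf_df = pd.DataFrame(conf, index=all_labels, columns=all_labels)

    rows = []
    for fam in families:
        tp = int(np.sum((truth == fam) & (predicted == fam)))
        fp = int(np.sum((truth != fam) & (predicted == fam)))
        fn = int(np.sum((truth == fam) & (predicted != fam)))
        support = int(np.sum(truth == fam))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {
                "family": fam,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "support": support,
                "empty": support == 0,
            }
        )
    per_class = pd.DataFrame(rows)
    weights = per_class["support"].to_numpy(dtype=float)
    total = weights.sum()
    weighted = {
        metric: float((per_class[metric].to_numpy() * weights).sum() / total)
        if total
        else 0.0
        for metric in ("precision", "recall", "f1")
    }
    accuracy = float(np.mean(predicted == truth)) if len(truth) else 0.0
    return ClassificationReport(per_class, weighted, accuracy, conf_df)


def mca(
    family: str,
    known_in_family_clusters: int | None = None,
    total_known: int | None = None,
    *,
    assignment: ClusterAssignment | None = None,
    family_assignment: FamilyAssignment | None = None,
    true_labels=None,
) -> float:
    """Motif Clustering Accuracy of one family.

    Either pass the two printed integers directly (known motifs found in
    the family's clusters, total known motifs), or pass an assignment +
    mapping + labels and both counts are derived: the numerator counts
    labelled loops of ``family`` whose subcluster was mapped to
    ``family``; the denominator counts all labelled loops of ``family``.
    """
    if known_in_family_clusters is None or total_known is None:
        if assignment is None or family_assignment is None or true_labels is None:
            raise ValueError("either pass both counts or a full assignment")
        labels = list(true_labels)
        total_known = sum(1 for lbl in labels if lbl == family)
        known_in_family_clusters = sum(
            1
            for key, lbl in zip(assignment.subcluster_keys, labels)
            if lbl == family and family_assignment.family_of(key) == family
        )
    if total_known <= 0:
        raise ValueError(f"family {family!r} has no known motifs")
    return known_in_family_clusters / total_known


@dataclass
class PurityThresholds:
    """Upper bounds (mean + 2 SD of known-family pairwise RMSDs) per backend."""

    interaction_bound: float
    structure_bound: float


def two_sd_upper_bound(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no RMSD values to bound")
    return float(values.mean() + 2.0 * values.std(ddof=0))


def purity_analysis(
    subcluster_members: dict,
    pairwise_rmsd,
    bound: float,
) -> float:
    """Fraction of multi-member subclusters below the RMSD purity bound.

    ``subcluster_members`` maps subcluster keys to lists of loop objects
    (or opaque items); ``pairwise_rmsd(a, b)`` returns the RMSD of one
    pair.  Singletons are excluded before the fraction is taken.
    """
    multi = {k: v for k, v in subcluster_members.items() if len(v) >= 2}
    if not multi:
        raise ValueError("no multi-member subclusters to analyze")
    below = 0
    for items in multi.values():
        rmsds = [pairwise_rmsd(a, b) for a, b in combinations(items, 2)]
        if float(np.mean(rmsds)) < bound:
            below += 1
    return below / len(multi)
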