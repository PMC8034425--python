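"""Consensus over heterogeneous target-prediction outputs.

Three families of predictor scores are supported: activity-spectrum
Pa/Pi probability pairs (scored as Pa - Pi), plain probabilities, and
pharmacophore fit scores (z-scores break ties only). Because the scales
are incomparable, cross-predictor aggregation uses per-predictor ranks:
targets are grouped by how many predictors report them (the Venn view) and
ordered by mean reciprocal rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SCORE_KINDS = ("pa_pi", "probability", "pharmacophore")


@dataclass
class PredictorEntry:
    predictor: str
    target: str
    score_kind: str
    pa: float | None = None
    pi: float | None = None
    probability: float | None = None
    fit_score: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score_kind {self.score_kind!r}")
        for name in ("pa", "pi", "probability"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.target = normalize_symbol(self.target)


@dataclass
class ConsensusTarget:
    target: str
    n_predictors: int
    per_predictor_rank: dict[str, float]
    consensus_score: float  # mean reciprocal rank over reporting predictors


def normalize_symbol(symbol: str) -> str:
    """Uppercase + trim; no alias resolution."""
    return symbol.strip().upper()


def score_entry(entry: PredictorEntry) -> float:
    """Comparable within-predictor score: Pa-Pi, probability, or fit score."""
    if entry.score_kind == "pa_pi":
        if entry.pa is None or entry.pi is None:
            raise ValueError(f"pa_pi entry for {entry.target} missing pa or pi")
        return entry.pa - entry.pi
    if entry.score_kind == "probability":
        if entry.probability is None:
            raise ValueError(f"probability entry for {entry.target} missing value")
        return entry.probability
    if entry.fit_score is None:
        raise ValueError(f"pharmacophore entry for {entry.target} missing fit_score")
    return entry.fit_score


def venn_membership(
    lists: dict[str, set[str] | list[str]],
) -> tuple[dict[str, frozenset[str]], dict[frozenset[str], int]]:
    """Exact set algebra over per-predictor target lists.

    Returns ``(membership, subset_sizes)``: each target mapped to the set of
    predictors reporting it, and the size of each non-empty exclusive Venn
    region (keyed by predictor subset). Region sizes sum to the union size.
    """
    if len(lists) < 2:
        raise ValueError("venn membership needs at least 2 predictors")
    sets = {
        name: {normalize_symbol(t) for t in targets}
        for name, targets in lists.items()
    }
    membership: dict[str, frozenset[str]] = {}
    for target in set().union(*sets.values()):
        membership[target] = frozenset(
            name for name, targets in sets.items() if target in targets
        )
    subset_sizes: dict[frozenset[str], int] = {}
    for predictors in membership.values():
        subset_sizes[predictors] = subset_sizes.get(predictors, 0) + 1
    return membership, subset_sizes


def consensus_rank(
    entries: list[PredictorEntry], min_predictors: int = 1
) -> list[ConsensusTarget]:
    """Rank targets by breadth of prediction, then mean reciprocal rank.

    Within each predictor, targets rank by score descending with
    average-rank ties (z-scores pre-break ties among pharmacophore entries).
    Targets reported by fewer than ``min_predictors`` predictors are
    dropped. Output order: n_predictors desc, consensus score desc, symbol.
    """
    by_predictor: dict[str, list[PredictorEntry]] = {}
    for e in entries:
        by_predictor.setdefault(e.predictor, []).append(e)

    ranks: dict[str, dict[str, float]] = {}
    for predictor, plist in sorted(by_predictor.items()):
        # rank by score descending, z descending as tie-break; exact
        # (score, z) ties receive their average rank
        keys = [
            (-score_entry(e), -(e.z if e.z is not None else 0.0))
            for e in plist
        ]
        sorted_keys = sorted(keys)
        for i, e in enumerate(plist):
            k = keys[i]
            first = sorted_keys.index(k) + 1
            avg_rank = first + (sorted_keys.count(k) - 1) / 2.0
            ranks.setdefault(e.target, {})[predictor] = avg_rank

    out = []
    for target, per_pred in ranks.items():
        if len(per_pred) < min_predictors:
            continue
        mrr = sum(1.0 / r for r in per_pred.values()) / len(per_pred)
        out.append(
            ConsensusTarget(
                target=target,
                n_predictors=len(per_pred),
                per_predictor_rank=dict(sorted(per_pred.items())),
                consensus_score=mrr,
            )
        )
    out.sort(key=lambda t: (-t.n_predictors, -t.consensus_score, t.target))
    return out


def consensus_table(targets: list[ConsensusTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [t.target for t in targets],
            "n_predictors": [t.n_predictors for t in targets],
            "consensus_score": [t.consensus_score for t in targets],
        }
    )
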