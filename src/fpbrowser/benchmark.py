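"""Ligand-based virtual-screening evaluation.

Given a screening deck (known actives spiked into a decoy background) and a
query molecule, the deck is ranked by city-block distance or Tanimoto
similarity to the query in one of the four fingerprint spaces, and recall
of the actives is summarized by the ROC AUC (rank-sum form with midrank tie
correction — the probability that a random active outranks a random decoy,
ties counted one half) and by enrichment factors at chosen fractions of the
screened deck:

    EF_f = (actives among the top ceil(f*N)) / (total actives) / f

so that EF at f = 1 is exactly 1 and a perfect top-1% selection of a
10-active / 1000-molecule deck gives EF_0.01 = 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .fingerprints import Space, fingerprint
from .metrics import cbd, tanimoto
from .standardize import MoleculeRecord

SCORERS = ("cbd", "tanimoto")

#: One entry of a ranked deck: (molecule id, score, is_active).
RankedEntry = tuple[str, float, bool]


@dataclass(frozen=True)
class ScreeningDeck:
    actives: list[MoleculeRecord]
    decoys: list[MoleculeRecord]
    query: MoleculeRecord

    def __post_init__(self) -> None:
        if not self.actives or not self.decoys:
            raise ValueError("deck needs at least one active and one decoy")
        ids = [r.id for r in self.actives] + [r.id for r in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("active and decoy id sets must be disjoint")


@dataclass(frozen=True)
class EnrichmentReport:
    space: Space
    scorer: str
    auc: float
    ef: dict[float, float]
    roc_points: list[tuple[float, float]]


def rank_deck(
    deck: ScreeningDeck, space: Space | str, scorer: str = "cbd"
) -> list[RankedEntry]:
    """Score the whole deck against the query and sort best-first.

    Ascending city-block distance or descending Tanimoto; ties broken by id
    so output files are deterministic.
    """
    space = Space(space)
    if scorer not in SCORERS:
        raise ValueError(f"scorer must be one of {SCORERS}, got {scorer!r}")
    query_fp = fingerprint(deck.query, space)
    entries: list[RankedEntry] = []
    for record, is_active in [(r, True) for r in deck.actives] + [
        (r, False) for r in deck.decoys
    ]:
        fp = fingerprint(record, space)
        score = cbd(query_fp, fp) if scorer == "cbd" else tanimoto(query_fp, fp)
        entries.append((record.id, float(score), is_active))
    reverse = scorer == "tanimoto"
    entries.sort(key=lambda e: (-e[1] if reverse else e[1], e[0]))
    return entries


def _goodness(ranked: list[RankedEntry]) -> np.ndarray:
    """Scores oriented so that larger is better, inferred from the ordering."""
    scores = np.array([score for _, score, _ in ranked])
    ascending = bool(scores[0] <= scores[-1]) if len(scores) > 1 else True
    return -scores if ascending else scores


def roc_auc(ranked: list[RankedEntry]) -> float:
    """Mann-Whitney AUC of actives vs decoys with midrank tie correction."""
    labels = np.array([a for _, _, a in ranked])
    n_act, n_dec = int(labels.sum()), int((~labels).sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError("AUC needs at least one active and one decoy")
    ranks = rankdata(_goodness(ranked))
    return float((ranks[labels].sum() - n_act * (n_act + 1) / 2) / (n_act * n_dec))


def roc_points(ranked: list[RankedEntry]) -> list[tuple[float, float]]:
    """ROC curve vertices (FPR, TPR), one per distinct score threshold."""
    labels = np.array([a for _, _, a in ranked])
    goodness = _goodness(ranked)
    n_act, n_dec = int(labels.sum()), int((~labels).sum())
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i, (g, active) in enumerate(zip(goodness, labels)):
        tp += int(active)
        fp += int(not active)
        if i + 1 == len(labels) or goodness[i + 1] != g:
            points.append((fp / n_dec, tp / n_act))
    return points


def enrichment_factor(ranked: list[RankedEntry], fraction: float) -> float:
    """EF at the top ``ceil(fraction * N)`` of the ranked deck."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    labels = [a for _, _, a in ranked]
    n_actives = sum(labels)
    if n_actives == 0:
        raise ValueError("EF needs at least one active in the deck")
    n_top = math.ceil(fraction * len(ranked))
    return sum(labels[:n_top]) / n_actives / fraction


def evaluate_deck(
    deck: ScreeningDeck,
    space: Space | str,
    scorer: str = "cbd",
    fractions: tuple[float, ...] = (0.001, 0.01),
) -> EnrichmentReport:
    """Rank the deck once and compute AUC, ROC points and EF values."""
    ranked = rank_deck(deck, space, scorer)
    return EnrichmentReport(
        space=Space(space),
        scorer=scorer,
        auc=roc_auc(ranked),
        ef={f: enrichment_factor(ranked, f) for f in fractions},
        roc_points=roc_points(ranked),
    )
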