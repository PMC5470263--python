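"""Scoring cacti for duplication history versus concerted evolution.

Columns that trace an old duplication split each species' paralogs into two
deep clusters, so under such a cactus the two most distant conspecific
sequences sit far apart. Columns homogenized by concerted evolution group
sequences by species, so the same pair sits close. The discrimination score
is therefore the cross-species mean of each species' maximum within-species
distance under a cactus — taking only the two most distant sequences avoids
biasing the statistic by how many sequences a species happens to have —
normalized across cacti so the top cactus scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import Alignment, DataError, GroupMap
from .segmentation import Cactus, Segmentation, fit_partition

CactusClass = Literal["duplication", "concerted"]


class ExtremePair(NamedTuple):
    """A species' two most distant sequences under a cactus."""

    distance: float
    pair: tuple[str, str]


@dataclass(frozen=True)
class DiscriminationScore:
    """Raw and cross-cactus-normalized score for one cactus."""

    cactus_index: int
    raw: float
    normalized: float
    n_species_used: int


def within_species_extreme(
    cactus: Cactus, groups: GroupMap, species: str
) -> ExtremePair:
    """Maximum cactus distance over one species' sequence pairs.

    Ties are broken to the lexicographically smallest pair so the reported
    pair is deterministic.
    """
    ids = [sid for sid in groups.ids_of_species(species) if sid in cactus.matrix.labels]
    if len(ids) < 2:
        raise DataError(f"species {species!r} has fewer than 2 sequences")
    best: ExtremePair | None = None
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = sorted((ids[x], ids[y]))
            d = cactus.matrix.get(a, b)
            if best is None or d > best.distance + 1e-15:
                best = ExtremePair(d, (a, b))
    return best


def discrimination_scores(
    seg: Segmentation, groups: GroupMap
) -> list[DiscriminationScore]:
    """Score every cactus: mean over species of the within-species maximum
    distance, then normalized by the maximum across cacti.

    Species with a single sequence carry no within-species distance and are
    excluded. When every raw score is zero, all normalized scores are zero.
    """
    multi_species = [
        sp for sp in groups.species_names() if len(groups.ids_of_species(sp)) >= 2
    ]
    if not multi_species:
        raise DataError("no species with >=2 sequences; statistic undefined")
    raws = []
    for cactus in seg.cacti:
        vals = [
            within_species_extreme(cactus, groups, sp).distance
            for sp in multi_species
        ]
        raws.append(float(np.mean(vals)))
    peak = max(raws)
    return [
        DiscriminationScore(
            cactus_index=k,
            raw=r,
            normalized=(r / peak if peak > 0 else 0.0),
            n_species_used=len(multi_species),
        )
        for k, r in enumerate(raws)
    ]


def classify_cacti(
    scores: Sequence[DiscriminationScore],
    threshold: float = 0.9,
    top_k: int | None = None,
) -> list[CactusClass]:
    """Label each cactus duplication or concerted.

    Default rule: duplication iff normalized score >= threshold (boundary
    counts as duplication). The default cutoff of 0.9 marks cacti whose
    within-species divergence is commensurate with the top cactus's: in a
    family without homogenization every column carries some duplication
    signal and background cacti score a substantial fraction of the top
    cactus, so only near-top cacti are reported; under concerted evolution
    homogenized cacti fall far below the cutoff either way. With ``top_k``
    set, the k highest-normalized cacti are labeled duplication instead
    (ties by smaller index).
    """
    if top_k is not None:
        if top_k < 0:
            raise DataError("top_k must be >= 0")
        order = sorted(
            range(len(scores)), key=lambda k: (-scores[k].normalized, k)
        )
        chosen = set(order[:top_k])
        return [
            "duplication" if k in chosen else "concerted" for k in range(len(scores))
        ]
    return [
        "duplication" if s.normalized >= threshold else "concerted" for s in scores
    ]


def diagnostic_sites(
    seg: Segmentation, labels: Sequence[CactusClass]
) -> list[int]:
    """1-based columns of all duplication-labeled cacti, ascending."""
    if len(labels) != len(seg.cacti):
        raise DataError("one label per cactus required")
    cols: set[int] = set()
    for cactus, lab in zip(seg.cacti, labels):
        if lab == "duplication":
            cols.update(cactus.columns_1based)
    return sorted(cols)


@dataclass
class DiscoveryResult:
    """End-to-end output of partition → score → classify → extract."""

    segmentation: Segmentation
    scores: list[DiscriminationScore]
    labels: list[CactusClass]
    sites: list[int]  # 1-based

    def report(self) -> pd.DataFrame:
        """One row per recovered site: column, cactus id, normalized score."""
        rows = []
        for k, (cactus, lab) in enumerate(zip(self.segmentation.cacti, self.labels)):
            if lab != "duplication":
                continue
            for col in cactus.columns_1based:
                rows.append(
                    {
                        "column": col,
                        "cactus": k,
                        "normalized_score": self.scores[k].normalized,
                    }
                )
        return (
            pd.DataFrame(rows, columns=["column", "cactus", "normalized_score"])
            .sort_values("column")
            .reset_index(drop=True)
        )


def discover(
    aln: Alignment,
    groups: GroupMap,
    n_iterations: int = 5,
    min_segment: int = 10,
    switch_penalty: float | None = None,
    threshold: float = 0.9,
    top_k: int | None = None,
) -> DiscoveryResult:
    """Run the full site-discovery pipeline on an alignment."""
    seg = fit_partition(
        aln,
        n_iterations=n_iterations,
        min_segment=min_segment,
        switch_penalty=switch_penalty,
    )
    scores = discrimination_scores(seg, groups)
    labels = classify_cacti(scores, threshold=threshold, top_k=top_k)
    sites = diagnostic_sites(seg, labels)
    return DiscoveryResult(segmentation=seg, scores=scores, labels=labels, sites=sites)
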