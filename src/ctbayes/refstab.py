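"""Reference-gene stability ranking and selection.

Two rankers are provided:

* ``genorm_rank`` — pairwise-variation M values with iterative exclusion of
  the least stable candidate, plus the V(k/k+1) series comparing
  normalization factors built from the best k and k+1 genes. Lower M is more
  stable; M is invariant to per-gene additive shifts of Ct.
* ``normfinder_rank`` — a model-based score combining the absolute
  group-specific bias of a gene (after per-sample centering across
  candidates) with its within-group sampling noise. Invariant to per-sample
  additive shifts.

Ct values are already log-scale quantities, so no further transform is
applied. Samples with any missing candidate Ct are excluded listwise (the
count is logged): both approaches assume complete matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .qpcr import CtMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityRanking:
    """Per-candidate stability scores and the derived ordering.

    ``ranks`` maps assay id -> rank (1 = most stable). For the pairwise
    method the two final genes are indistinguishable and share rank 1; the
    remaining genes are ranked by reverse exclusion order. ``scores`` are on
    the full candidate set (M values, or model-based scores in cycles).
    """

    method: str
    scores: pd.Series
    ranks: pd.Series
    exclusion_order: tuple[str, ...] | None = None
    v_series: pd.Series | None = None
    n_samples_used: int = 0
    n_samples_dropped: int = 0

    def __post_init__(self):
        if (self.scores < 0).any():
            raise ValueError("stability scores must be >= 0")

    @property
    def ordered(self) -> list[str]:
        """Assay ids from most to least stable (ties broken lexicographically)."""
        return sorted(self.ranks.index, key=lambda g: (self.ranks[g], g))


def _complete_cases(ct: CtMatrix, candidates: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in candidates if c not in ct.values.columns]
    if missing:
        raise InputError(f"candidate assay(s) absent from Ct matrix: {missing}")
    sub = ct.values[list(candidates)]
    detected_per_gene = sub.notna().sum(axis=0)
    poor = detected_per_gene[detected_per_gene < 2]
    if len(poor):
        raise InputError(
            f"candidate(s) detected in < 2 samples: {list(poor.index)}"
        )
    complete = sub.dropna(axis=0, how="any")
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("stability: dropped %d/%d samples with missing candidate Ct",
                    dropped, len(sub))
    if len(complete) < 2:
        raise InputError("fewer than 2 complete samples across candidates")
    return complete


def pairwise_m_values(data: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of sd_samples(Ct_j - Ct_k) for the given genes."""
    genes = list(data.columns)
    arr = data.to_numpy(float)
    m = {}
    for j, gj in enumerate(genes):
        sds = [
            float(np.std(arr[:, j] - arr[:, k], ddof=1))
            for k in range(len(genes))
            if k != j
        ]
        m[gj] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_rank(ct: CtMatrix, candidates: Sequence[str]) -> StabilityRanking:
    """Rank candidates by pairwise-variation M with stepwise exclusion.

    Requires >= 3 candidates, each detected in >= 2 samples. Returns M on
    the full set, the exclusion order (least stable first), and the
    V(k/k+1) series: the sd over samples of the difference between mean-Ct
    normalization factors built from the best k and best k+1 genes.
    """
    if len(candidates) < 3:
        raise InputError(f"need >= 3 candidates, got {len(candidates)}")
    data = _complete_cases(ct, candidates)

    full_m = pairwise_m_values(data)
    exclusion: list[str] = []
    remaining = list(candidates)
    while len(remaining) > 2:
        m = pairwise_m_values(data[remaining])
        worst_val = m.max()
        worst = sorted(m.index[m == worst_val])[-1]  # deterministic tie break
        exclusion.append(worst)
        remaining.remove(worst)

    # stability order: the two finalists (tied), then reverse exclusion order
    finalists = sorted(remaining)
    order = finalists + exclusion[::-1]
    ranks = pd.Series(index=full_m.index, dtype=float)
    ranks[finalists] = 1.0
    for pos, gene in enumerate(exclusion[::-1], start=3):
        ranks[gene] = float(pos)

    v = {}
    for k in range(2, len(order)):
        nf_k = data[order[:k]].mean(axis=1)
        nf_k1 = data[order[: k + 1]].mean(axis=1)
        v[f"{k}/{k + 1}"] = float(np.std(nf_k - nf_k1, ddof=1))
    v_series = pd.Series(v, name="V")

    return StabilityRanking(
        method="genorm",
        scores=full_m,
        ranks=ranks,
        exclusion_order=tuple(exclusion),
        v_series=v_series,
        n_samples_used=len(data),
        n_samples_dropped=ct.n_samples - len(data),
    )


def normfinder_rank(
    ct: CtMatrix,
    candidates: Sequence[str],
    groups: pd.Series,
) -> StabilityRanking:
    """Model-based stability: mean over groups of |group bias| + sd/sqrt(n).

    Ct values are first centered per sample (subtracting the sample mean over
    candidates, which removes global loading differences); the bias of a gene
    in a group is the deviation of its group mean from its grand mean on the
    centered scale.

    ``groups`` maps sample id -> group label; >= 2 groups of >= 2 samples
    each are required.
    """
    data = _complete_cases(ct, candidates)
    groups = groups.reindex(data.index)
    if groups.isna().any():
        raise InputError("every complete sample needs a group label")
    level_counts = groups.value_counts()
    if len(level_counts) < 2:
        raise InputError("need >= 2 groups")
    small = level_counts[level_counts < 2]
    if len(small):
        raise InputError(f"group(s) with < 2 samples: {list(small.index)}")

    centered = data.sub(data.mean(axis=1), axis=0)
    grand = centered.mean(axis=0)
    scores = {}
    for gene in data.columns:
        parts = []
        for level in level_counts.index:
            vals = centered.loc[groups == level, gene]
            bias = abs(vals.mean() - grand[gene])
            parts.append(bias + vals.std(ddof=1) / np.sqrt(len(vals)))
        scores[gene] = float(np.mean(parts))
    scores = pd.Series(scores, name="stability")

    order = scores.sort_values(kind="stable").index
    ranks = pd.Series(
        {gene: float(i + 1) for i, gene in enumerate(
            sorted(order, key=lambda g: (scores[g], g))
        )}
    )
    return StabilityRanking(
        method="normfinder",
        scores=scores,
        ranks=ranks,
        n_samples_used=len(data),
        n_samples_dropped=ct.n_samples - len(data),
    )


def select_references(
    rankings: Sequence[StabilityRanking],
    k: int = 2,
) -> list[str]:
    """Pick the k assays with the best (lowest) mean rank across rankings.

    Ties are broken lexicographically by assay id and logged.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if not rankings:
        raise InputError("at least one ranking required")
    common = set(rankings[0].ranks.index)
    for r in rankings[1:]:
        common &= set(r.ranks.index)
    if k > len(common):
        raise InputError(f"k={k} exceeds candidate count {len(common)}")
    mean_rank = pd.DataFrame(
        {r.method + str(i): r.ranks.reindex(sorted(common)) for i, r in enumerate(rankings)}
    ).mean(axis=1)
    ordered = sorted(mean_rank.index, key=lambda g: (mean_rank[g], g))
    cut = mean_rank[ordered[k - 1]]
    tied = [g for g in ordered[k:] if mean_rank[g] == cut]
    if tied:
        logger.warning("reference selection tie at rank %d broken lexicographically "
                       "(selected %s over %s)", k, ordered[k - 1], tied)
    return ordered[:k]
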