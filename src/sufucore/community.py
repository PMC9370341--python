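"""Community composition utilities: relative abundance, dominance
filtering, alpha diversity, and fermentation-stage assignment.

The study design partitions a post-fermentation time course into a
start sample (day 0), an early stage (days 10-30) and a late stage
(days 60-130); dominance ("relative abundance > 1%") is judged on the
stage-mean relative abundance with a strict inequality.

Alpha-diversity conventions:

* Chao1 uses the bias-corrected form S_obs + F1(F1-1)/(2(F2+1)), which
  stays finite when no doubletons are observed.
* ACE uses rare cutoff 10 with the standard rare-species coefficient of
  variation; degenerate rare classes fall back as documented below.
* Shannon uses natural log; Simpson is reported as Gini-Simpson
  (1 - sum p^2) by default, with the raw sum p^2 also available.
* Good's coverage is 1 - F1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMeta, ValidationError

__all__ = [
    "StageRule",
    "AlphaDiversityResult",
    "to_relative",
    "assign_stages",
    "dominant_genera",
    "chao1",
    "ace",
    "shannon",
    "gini_simpson",
    "simpson_concentration",
    "goods_coverage",
    "alpha_diversity",
]

STAGES = ("start", "early", "late")


@dataclass(frozen=True)
class StageRule:
    """Mapping from sampling day to fermentation stage (sets are disjoint)."""

    start_days: frozenset = frozenset({0})
    early_days: frozenset = frozenset({10, 20, 30})
    late_days: frozenset = frozenset({60, 90, 130})

    def __post_init__(self) -> None:
        sets = [set(self.start_days), set(self.early_days), set(self.late_days)]
        union = set().union(*sets)
        if sum(len(s) for s in sets) != len(union):
            raise ValidationError("stage day sets must be disjoint")

    def stage_of(self, day: int) -> str | None:
        if day in self.start_days:
            return "start"
        if day in self.early_days:
            return "early"
        if day in self.late_days:
            return "late"
        return None


@dataclass
class AlphaDiversityResult:
    sample_id: str
    observed: int
    chao1: float
    ace: float
    shannon: float
    gini_simpson: float
    goods_coverage: float


def to_relative(at: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to relative abundances (rows sum to 1)."""
    if at.mode != "counts":
        raise ValidationError("to_relative expects a counts-mode table")
    arr = at.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        bad = at.values.index[totals <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    rel = arr / totals[:, None]
    values = pd.DataFrame(rel, index=at.values.index, columns=at.values.columns)
    meta = [SampleMeta(m.sample_id, m.day, m.replicate, m.stage) for m in at.meta]
    return AbundanceTable(meta=meta, values=values, mode="relative")


def assign_stages(at: AbundanceTable, rule: StageRule = StageRule()) -> AbundanceTable:
    """Populate the stage field of every sample from its day.

    Every day present must belong to exactly one of the rule's sets;
    otherwise the offending days are listed in the error.
    """
    missing = sorted({m.day for m in at.meta if rule.stage_of(m.day) is None})
    if missing:
        raise ValidationError(f"days not covered by the stage rule: {missing}")
    meta = [
        SampleMeta(m.sample_id, m.day, m.replicate, rule.stage_of(m.day))
        for m in at.meta
    ]
    return AbundanceTable(meta=meta, values=at.values.copy(), mode=at.mode)


def dominant_genera(
    at: AbundanceTable, stage: str, threshold: float = 0.01
) -> list[str]:
    """Genera whose stage-mean relative abundance strictly exceeds
    ``threshold``, sorted by descending mean abundance.

    The ">1%" dominance convention is a strict inequality: a genus
    sitting exactly at the threshold is excluded.
    """
    if at.mode != "relative":
        raise ValidationError("dominant_genera expects a relative-mode table")
    sub = at.restrict(stage)
    means = sub.values.mean(axis=0)
    hits = means[means > threshold].sort_values(ascending=False, kind="stable")
    return list(hits.index)


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be non-negative integers")
    if arr.sum() <= 0:
        raise ValidationError("counts must contain at least one positive entry")
    return np.round(arr).astype(np.int64)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    arr = _check_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Species with <= ``rare_cutoff`` individuals form the rare class.
    With no rare species ACE reduces to the observed richness; when the
    rare class consists solely of singletons its sample coverage C_ace
    is 0 and the estimator is undefined, so the (bias-corrected) Chao1
    value is returned instead.
    """
    arr = _check_counts(counts)
    arr = arr[arr > 0]
    rare = arr[arr <= rare_cutoff]
    abund = arr[arr > rare_cutoff]
    s_rare = len(rare)
    s_abund = len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    fis = np.bincount(rare, minlength=rare_cutoff + 1)
    i = np.arange(1, rare_cutoff + 1)
    sum_term = float((i * (i - 1) * fis[1:]).sum())
    gamma2 = max(
        (s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1.0)) - 1.0
        if n_rare > 1
        else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts) -> float:
    """Shannon entropy in nats: -sum p ln p over detected genera."""
    arr = _check_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson_concentration(counts) -> float:
    """Raw Simpson concentration sum p^2 (probability two draws match)."""
    arr = _check_counts(counts)
    p = arr / arr.sum()
    return float((p**2).sum())


def gini_simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum p^2, in [0, 1]."""
    return 1.0 - simpson_concentration(counts)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (fraction of draws from seen-again taxa)."""
    arr = _check_counts(counts)
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / arr.sum()


def alpha_diversity(at: AbundanceTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample alpha-diversity summary of a counts-mode table."""
    if at.mode != "counts":
        raise ValidationError("alpha diversity is defined on counts")
    rows = []
    for m in at.meta:
        c = at.values.loc[m.sample_id].to_numpy()
        rows.append(
            {
                "sample_id": m.sample_id,
                "day": m.day,
                "replicate": m.replicate,
                "observed": int((c > 0).sum()),
                "chao1": chao1(c),
                "ace": ace(c, rare_cutoff=rare_cutoff),
                "shannon": shannon(c),
                "gini_simpson": gini_simpson(c),
                "goods_coverage": goods_coverage(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
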