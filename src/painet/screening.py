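"""Item-level screening: missingness, floor/ceiling effects, internal
consistency, and the deletion roster.

Deletion rules follow the questionnaire-development protocol: an item
is removed automatically only when its missing fraction exceeds the
"both roles" threshold (default 40%) in both the self-report and the
proxy-report; every other rule — missingness above 20% in either or
both roles, floor/ceiling effects, inter-item correlations above 0.7,
corrected item-total correlations below 0.3 — only flags the item as
*considered* for deletion.  Final removal of flagged items requires an
explicit consensus roster, mirroring the human review step of the
original development process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import (
    DyadDataset,
    ItemCatalog,
    ResponseMatrix,
    Table3Fixture,
)


@dataclass(frozen=True)
class ScreeningConfig:
    missing_both_threshold: float = 0.40
    missing_either_threshold: float = 0.20
    floor_ceiling_threshold: float = 0.70
    interitem_threshold: float = 0.7
    item_total_threshold: float = 0.3
    min_complete_for_alpha: int = 30

    def __post_init__(self) -> None:
        for name in (
            "missing_both_threshold",
            "missing_either_threshold",
            "floor_ceiling_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def missing_fraction(m: ResponseMatrix, item: str) -> float:
    if item not in m.items:
        raise KeyError(item)
    col = m.data[item]
    return float(col.isna().mean())


def category_fractions(m: ResponseMatrix, item: str) -> np.ndarray:
    """Observed category proportions; denominator excludes missing."""
    col = m.data[item].dropna()
    counts = np.array(
        [(col == c).sum() for c in range(1, m.n_categories + 1)], dtype=float
    )
    total = counts.sum()
    return counts / total if total else np.full(m.n_categories, np.nan)


def floor_ceiling_flags(
    category_fracs, threshold: float = 0.70
) -> tuple[bool | None, bool | None]:
    """Flag floor/ceiling when the first/last category share strictly
    exceeds ``threshold``; all-missing items return (None, None)."""
    fr = np.asarray(category_fracs, dtype=float)
    if np.isnan(fr).all():
        return None, None
    return bool(fr[0] > threshold), bool(fr[-1] > threshold)


def interitem_spearman(
    m: ResponseMatrix, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlations plus pairwise-n counts.

    Pairs with fewer than ``min_pairs`` complete observations are NaN.
    """
    if len(m.items) < 2:
        raise ValueError("need at least 2 items")
    corr = m.data.corr(method="spearman", min_periods=min_pairs)
    notna = m.data.notna().astype(float)
    n_pair = pd.DataFrame(
        notna.T.to_numpy() @ notna.to_numpy(),
        index=m.items,
        columns=m.items,
    ).astype(int)
    np.fill_diagonal(corr.values, 1.0)
    return corr, n_pair


def corrected_item_total(m: ResponseMatrix, item: str) -> float:
    """Spearman correlation of an item with the mean of the remaining
    items (per-subject mean over the subject's observed rest items)."""
    if len(m.items) < 3:
        raise ValueError("need at least 3 items")
    col = m.data[item]
    rest = m.data.drop(columns=[item]).mean(axis=1)
    usable = col.notna() & rest.notna()
    if usable.sum() < 3:
        return math.nan
    if col[usable].nunique() < 2 or rest[usable].nunique() < 2:
        return math.nan
    r, _ = stats.spearmanr(col[usable], rest[usable])
    return float(r)


def cronbach_alpha(
    m: ResponseMatrix, min_complete: int = 30
) -> tuple[float, int, bool]:
    """Cronbach's alpha over complete cases only.

    Returns ``(alpha, n_complete, reliable_flag)``; alpha is NaN when
    fewer than 3 complete cases exist or the total score is constant,
    and the flag marks estimates from fewer than ``min_complete`` cases
    as unreliable.
    """
    complete = m.data.dropna()
    n_complete = len(complete)
    if n_complete < 3:
        return math.nan, n_complete, False
    k = complete.shape[1]
    item_vars = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return math.nan, n_complete, False
    alpha = k / (k - 1) * (1 - item_vars.sum() / total_var)
    return float(alpha), n_complete, n_complete >= min_complete


@dataclass
class ScreeningReport:
    per_item_role: pd.DataFrame  # item_id, role, missing_fraction, cat fracs, flags
    low_item_total: dict[str, list[str]]  # role -> flagged items
    high_corr_pairs: dict[str, list[tuple[str, str, float]]]
    alpha: dict[str, tuple[float, int, bool]]
    deletion: pd.DataFrame  # item_id, reason in {missing_both, consensus}
    surviving_items: list[str]
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    @property
    def deleted_items(self) -> list[str]:
        return list(self.deletion["item_id"])


def _per_item_role_table(
    dyads: DyadDataset, config: ScreeningConfig
) -> pd.DataFrame:
    rows = []
    for role in ("child", "parent"):
        if not dyads.has(role, "test"):
            continue
        m = dyads.get(role, "test")
        for item in m.items:
            fracs = category_fractions(m, item)
            floor, ceiling = floor_ceiling_flags(
                fracs, config.floor_ceiling_threshold
            )
            rows.append(
                {
                    "item_id": item,
                    "role": role,
                    "missing_fraction": missing_fraction(m, item),
                    **{
                        f"cat{c}_fraction": fracs[c - 1]
                        for c in range(1, m.n_categories + 1)
                    },
                    "floor_flag": floor,
                    "ceiling_flag": ceiling,
                }
            )
    return pd.DataFrame(rows)


def build_screening_report(
    dyads: DyadDataset,
    config: ScreeningConfig = ScreeningConfig(),
    consensus_roster: list[str] | None = None,
) -> ScreeningReport:
    """Apply every screening rule; delete only on the missing-in-both
    rule plus the explicit consensus roster."""
    consensus_roster = list(consensus_roster or [])
    unknown = set(consensus_roster) - set(dyads.catalog.item_ids)
    if unknown:
        raise ValueError(f"roster items not in catalog: {sorted(unknown)}")

    table = _per_item_role_table(dyads, config)

    miss = table.pivot(index="item_id", columns="role", values="missing_fraction")
    roles_present = list(miss.columns)
    missing_both = miss.index[
        (miss > config.missing_both_threshold).all(axis=1)
    ].tolist()

    low_it: dict[str, list[str]] = {}
    high_pairs: dict[str, list[tuple[str, str, float]]] = {}
    alpha: dict[str, tuple[float, int, bool]] = {}
    for role in roles_present:
        m = dyads.get(role, "test")
        low_it[role] = [
            item
            for item in m.items
            if (r := corrected_item_total(m, item)) == r  # not NaN
            and r < config.item_total_threshold
        ]
        corr, _ = interitem_spearman(m)
        pairs = []
        items = m.items
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                r = corr.iloc[a, b]
                if pd.notna(r) and r > config.interitem_threshold:
                    pairs.append((items[a], items[b], float(r)))
        high_pairs[role] = pairs
        alpha[role] = cronbach_alpha(m, config.min_complete_for_alpha)

    deletion_rows = [
        {"item_id": it, "reason": "missing_both"} for it in sorted(missing_both)
    ] + [
        {"item_id": it, "reason": "consensus"}
        for it in consensus_roster
        if it not in missing_both
    ]
    deletion = pd.DataFrame(deletion_rows, columns=["item_id", "reason"])
    deleted = set(deletion["item_id"])
    surviving = [i for i in dyads.catalog.item_ids if i not in deleted]
    return ScreeningReport(
        per_item_role=table,
        low_item_total=low_it,
        high_corr_pairs=high_pairs,
        alpha=alpha,
        deletion=deletion,
        surviving_items=surviving,
        config=config,
    )


# ---------------------------------------------------------------------------
# Screening from the published summary table (percent scale)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureScreening:
    """Screening rules applied to the published per-item percentages."""

    missing_both: list[str]
    missing_both_after_first_rule: list[str]  # >20% in both, first rule's hits removed
    floor_both: list[str]
    ceiling_both: list[str]
    deleted: list[str]
    surviving: list[str]


def screen_fixture(
    fixture: Table3Fixture,
    config: ScreeningConfig = ScreeningConfig(),
    consensus_roster: list[str] | None = None,
) -> FixtureScreening:
    """Replays the deletion protocol on the printed summary percentages."""
    consensus_roster = list(consensus_roster or [])
    miss_c = fixture.missing_pct("child")
    miss_p = fixture.missing_pct("parent")
    t_both = config.missing_both_threshold * 100
    t_either = config.missing_either_threshold * 100
    missing_both = sorted(
        miss_c.index[(miss_c > t_both) & (miss_p > t_both)], key=fixture.item_ids.index
    )
    rest = [i for i in fixture.item_ids if i not in missing_both]
    missing20_both = [
        i for i in rest if miss_c[i] > t_either and miss_p[i] > t_either
    ]

    t_fc = config.floor_ceiling_threshold * 100
    cats_c = fixture.category_pcts("child")
    cats_p = fixture.category_pcts("parent")
    floor_both = [
        i
        for i in fixture.item_ids
        if cats_c.loc[i, "cat1_pct"] > t_fc and cats_p.loc[i, "cat1_pct"] > t_fc
    ]
    ceiling_both = [
        i
        for i in fixture.item_ids
        if cats_c.loc[i, "cat4_pct"] > t_fc and cats_p.loc[i, "cat4_pct"] > t_fc
    ]

    deleted = list(missing_both) + [
        i for i in consensus_roster if i not in missing_both
    ]
    surviving = [i for i in fixture.item_ids if i not in set(deleted)]
    return FixtureScreening(
        missing_both=missing_both,
        missing_both_after_first_rule=missing20_both,
        floor_both=floor_both,
        ceiling_both=ceiling_both,
        deleted=deleted,
        surviving=surviving,
    )
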