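"""Agreement statistics for dyadic and test-retest ordinal ratings.

Three statistics, each computed per item on pairs of ratings with any
missing member dropped:

* percentage agreement — exact matches / usable pairs x 100;
* weighted kappa — chance-corrected agreement with disagreement
  weights w_ij = |i-j|/(C-1) (linear, default) or ((i-j)/(C-1))^2
  (quadratic), kappa_w = 1 - sum(w o) / sum(w e) with expectation from
  marginal products;
* Kendall's coefficient of concordance W for the two raters of a dyad,
  with the correction for ties: midranks within each rater, rank sums
  R_i per dyad, S = sum (R_i - m(n+1)/2)^2 and
  W = 12 S / (m^2 (n^3 - n) - m sum_j T_j), T_j = sum over tie groups
  of (t^3 - t).  For two untied raters W reduces to (1 + rho_s)/2.

Interpretation bands: kappa >0.4 moderate, >0.6 good, >0.8 very good;
agreement 60-74% moderate, 75-89% good, >=90% excellent; W >0.7
adequate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import DyadDataset, Table3Fixture


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 2000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


def _usable_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rating vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def percent_agreement(x, y) -> float:
    """Exact-match percentage over pairs where both ratings are observed."""
    x, y = _usable_pairs(x, y)
    if x.size == 0:
        return math.nan
    return float(100.0 * np.mean(x == y))


def weighted_kappa(
    x, y, n_categories: int, weight_scheme: str = "linear"
) -> float:
    """Weighted kappa on categories 1..C; NaN when chance expectation
    is degenerate (both raters constant on the same category)."""
    x, y = _usable_pairs(x, y)
    if x.size == 0:
        return math.nan
    c = n_categories
    if (x < 1).any() or (x > c).any() or (y < 1).any() or (y > c).any():
        raise ValueError(f"ratings must lie in 1..{c}")
    obs = np.zeros((c, c))
    for xi, yi in zip(x.astype(int), y.astype(int)):
        obs[xi - 1, yi - 1] += 1
    obs /= obs.sum()
    px = obs.sum(axis=1)
    py = obs.sum(axis=0)
    exp = np.outer(px, py)
    idx = np.arange(c)
    diff = np.abs(idx[:, None] - idx[None, :]) / (c - 1)
    if weight_scheme == "linear":
        w = diff
    elif weight_scheme == "quadratic":
        w = diff**2
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    expected_disagreement = float((w * exp).sum())
    if expected_disagreement == 0:
        return math.nan
    return float(1.0 - (w * obs).sum() / expected_disagreement)


def _tie_correction(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kendalls_w(child, parent) -> float:
    """Tie-corrected Kendall's W for the two raters of each dyad."""
    x, y = _usable_pairs(child, parent)
    n = x.size
    if n < 2:
        return math.nan
    m = 2
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 and np.ptp(ry) == 0:
        return math.nan
    r_sum = rx + ry
    s = float(np.sum((r_sum - m * (n + 1) / 2) ** 2))
    denom = m**2 * (n**3 - n) - m * (_tie_correction(rx) + _tie_correction(ry))
    if denom <= 0:
        return math.nan
    return float(12.0 * s / denom)


def bootstrap_ci(
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    x,
    y,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling dyads with replacement and
    keeping the child-parent pairing; NaN interval when the statistic
    is undefined on more than half of the resamples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    n = x.size
    vals = np.empty(cfg.n_boot)
    for b in range(cfg.n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic_fn(x[idx], y[idx])
    ok = vals[~np.isnan(vals)]
    if ok.size < cfg.n_boot / 2:
        return math.nan, math.nan
    tail = (1 - cfg.ci_level) / 2
    lo, hi = np.quantile(ok, [tail, 1 - tail])
    return float(lo), float(hi)


def band_label(kind: str, value: float) -> str:
    """Interpretation band for a statistic value.

    ``kind`` is one of ``agreement_pct`` (suboptimal/moderate/good/
    excellent), ``weighted_kappa`` (suboptimal/moderate/good/very good)
    or ``kendalls_w`` (inadequate/adequate, strict >0.7).
    """
    if value != value:
        return "undefined"
    if kind == "agreement_pct":
        if value >= 90:
            return "excellent"
        if value >= 75:
            return "good"
        if value >= 60:
            return "moderate"
        return "suboptimal"
    if kind == "weighted_kappa":
        if value > 0.8:
            return "very good"
        if value > 0.6:
            return "good"
        if value > 0.4:
            return "moderate"
        return "suboptimal"
    if kind == "kendalls_w":
        return "adequate" if value > 0.7 else "inadequate"
    raise ValueError(f"unknown statistic kind {kind!r}")


@dataclass(frozen=True)
class ReliabilityRecord:
    item_id: str
    kind: str
    role: str | None
    value: float
    n_pairs: int
    ci_low: float = math.nan
    ci_high: float = math.nan

    @property
    def band(self) -> str:
        return band_label(self.kind, self.value)


def reliability_report(
    dyads: DyadDataset,
    items: Sequence[str] | None = None,
    bootstrap: BootstrapConfig | None = BootstrapConfig(),
    weight_scheme: str = "linear",
) -> pd.DataFrame:
    """Per-item agreement, weighted kappa (test vs retest, per role) and
    child-parent concordance W with bootstrap CI.

    Reliability is computed on the original response scale; rows for a
    role are emitted only when its retest matrix is present.
    """
    items = list(items or dyads.catalog.item_ids)
    n_cat = int(dyads.catalog.frame["n_categories"].max())
    rows = []
    for role in ("child", "parent"):
        if not (dyads.has(role, "test") and dyads.has(role, "retest")):
            continue
        t = dyads.get(role, "test").data
        r = dyads.get(role, "retest").data
        shared = t.index.intersection(r.index)
        for item in items:
            x, y = t.loc[shared, item], r.loc[shared, item]
            xu, yu = _usable_pairs(x, y)
            rows.append(
                {
                    "item_id": item,
                    "kind": "agreement_pct",
                    "role": role,
                    "value": percent_agreement(x, y),
                    "n_pairs": xu.size,
                }
            )
            rows.append(
                {
                    "item_id": item,
                    "kind": "weighted_kappa",
                    "role": role,
                    "value": weighted_kappa(x, y, n_cat, weight_scheme),
                    "n_pairs": xu.size,
                }
            )
    if dyads.has("child", "test") and dyads.has("parent", "test"):
        c = dyads.get("child", "test").data
        p = dyads.get("parent", "test").data
        shared = c.index.intersection(p.index)
        for item in items:
            x, y = c.loc[shared, item].to_numpy(), p.loc[shared, item].to_numpy()
            xu, _ = _usable_pairs(x, y)
            w = kendalls_w(x, y)
            lo = hi = math.nan
            if bootstrap is not None and xu.size:
                lo, hi = bootstrap_ci(kendalls_w, x, y, bootstrap)
            rows.append(
                {
                    "item_id": item,
                    "kind": "kendalls_w",
                    "role": None,
                    "value": w,
                    "n_pairs": xu.size,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    out = pd.DataFrame(rows)
    out["band"] = [band_label(k, v) for k, v in zip(out["kind"], out["value"])]
    return out


def adequate_concordance_items(
    fixture: Table3Fixture, threshold: float = 0.70
) -> list[str]:
    """Items whose printed concordance reaches the adequacy threshold.

    Printed values carry two decimals, so the strict >0.7 rule is
    applied at printed precision (>= threshold): a printed 0.70 counts
    as adequate.
    """
    conc = fixture.concordance()
    return [i for i in fixture.item_ids if pd.notna(conc[i]) and conc[i] >= threshold]
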