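"""Data model and I/O for dyadic ordinal questionnaire responses.

The canonical on-disk layout is a wide CSV with a ``dyad_id`` column
followed by one column per item; cells hold ordinal categories ``1..C``
or an NA token (blank or ``"NA"`` by default).  "Not applicable"
responses must be pre-coded as NA by the caller.

The module also ships two packaged fixtures: the 55-item PAI-CY 7-12
catalog (9 domains) and the published per-item summary table (response
distributions, test-retest agreement, weighted kappa, child-parent
concordance).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DOMAINS = ("PL", "SC", "MO", "LT", "CO", "SL", "SR", "AC", "FI")
ROLES = ("child", "parent")
OCCASIONS = ("test", "retest")

#: Items the developers decided to drop after reviewing screening,
#: reliability and concordance evidence (the "consensus" deletions, on
#: top of the automatic missing-in-both-roles rule which removes SL6).
CONSENSUS_DELETIONS = ("SC2", "LT5", "LT7", "CO2", "CO5", "SL1", "SR4")

DEFAULT_NA_TOKENS = ("", "NA")


class DataError(ValueError):
    """Raised for malformed response files or inconsistent containers."""


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered collection of questionnaire items with domain codes."""

    frame: pd.DataFrame  # columns: item_id, domain, label, n_categories

    def __post_init__(self) -> None:
        required = {"item_id", "domain", "label", "n_categories"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"catalog missing columns: {sorted(missing)}")
        ids = self.frame["item_id"]
        if ids.duplicated().any():
            raise DataError("duplicate item_ids in catalog")
        bad = set(self.frame["domain"]) - set(DOMAINS)
        if bad:
            raise DataError(f"unknown domain codes: {sorted(bad)}")

    @property
    def item_ids(self) -> list[str]:
        return list(self.frame["item_id"])

    @property
    def domains(self) -> dict[str, str]:
        return dict(zip(self.frame["item_id"], self.frame["domain"]))

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, item_ids: Iterable[str]) -> "ItemCatalog":
        keep = [i for i in self.item_ids if i in set(item_ids)]
        return ItemCatalog(
            self.frame[self.frame["item_id"].isin(keep)].reset_index(drop=True)
        )


@dataclass
class ResponseMatrix:
    """Subjects x items ordinal responses for one role and occasion.

    ``data`` is a float DataFrame indexed by dyad_id with one column per
    catalog item; missing cells are NaN, observed cells are integers in
    ``1..n_categories``.
    """

    data: pd.DataFrame
    role: str
    occasion: str
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DataError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.occasion not in OCCASIONS:
            raise DataError(
                f"occasion must be one of {OCCASIONS}, got {self.occasion!r}"
            )
        vals = self.data.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size and (
            (obs != np.round(obs)).any() or obs.min() < 1 or obs.max() > self.n_categories
        ):
            raise DataError(
                f"responses must be integers in 1..{self.n_categories}"
            )

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    @property
    def dyad_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def subset_items(self, item_ids: Iterable[str]) -> "ResponseMatrix":
        keep = [c for c in self.data.columns if c in set(item_ids)]
        return replace(self, data=self.data[keep])


@dataclass
class DyadDataset:
    """Up to four response matrices (role x occasion) over one catalog."""

    catalog: ItemCatalog
    matrices: dict[tuple[str, str], ResponseMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = self.catalog.item_ids
        for key, m in self.matrices.items():
            if m.items != cols:
                raise DataError(f"matrix {key} item columns do not match catalog")

    def get(self, role: str, occasion: str = "test") -> ResponseMatrix:
        return self.matrices[(role, occasion)]

    def has(self, role: str, occasion: str) -> bool:
        return (role, occasion) in self.matrices

    def subset_items(self, item_ids: Iterable[str]) -> "DyadDataset":
        return DyadDataset(
            catalog=self.catalog.subset(item_ids),
            matrices={
                k: m.subset_items(item_ids) for k, m in self.matrices.items()
            },
        )


def load_item_catalog() -> ItemCatalog:
    """Load the packaged 55-item PAI-CY 7-12 catalog."""
    with importlib.resources.files("painet").joinpath(
        "data/pai_cy_items.csv"
    ).open() as fh:
        frame = pd.read_csv(fh)
    return ItemCatalog(frame)


def read_responses(
    path,
    role: str,
    occasion: str,
    catalog: ItemCatalog,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ResponseMatrix:
    """Read a wide response CSV (``dyad_id`` + one column per item).

    Cells must be integers in ``1..C``, blank, or an NA token.  Unknown
    item columns and out-of-range categories are hard errors.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "dyad_id" not in raw.columns:
        raise DataError(f"{path}: missing dyad_id column")
    item_cols = [c for c in raw.columns if c != "dyad_id"]
    unknown = set(item_cols) - set(catalog.item_ids)
    if unknown:
        raise DataError(f"{path}: unknown item columns {sorted(unknown)}")
    missing_items = set(catalog.item_ids) - set(item_cols)
    if missing_items:
        raise DataError(f"{path}: missing item columns {sorted(missing_items)}")

    na_set = {t.strip() for t in na_tokens} | {""}
    n_cat = int(catalog.frame["n_categories"].max())
    data = pd.DataFrame(index=raw["dyad_id"], columns=catalog.item_ids, dtype=float)
    data.index.name = "dyad_id"
    for col in catalog.item_ids:
        for ridx, cell in zip(raw["dyad_id"], raw[col]):
            token = cell.strip()
            if token in na_set:
                continue
            try:
                val = int(token)
            except ValueError:
                raise DataError(
                    f"{path}: non-integer cell {token!r} at dyad {ridx}, item {col}"
                ) from None
            if not 1 <= val <= n_cat:
                raise DataError(
                    f"{path}: category {val} out of range 1..{n_cat}"
                    f" at dyad {ridx}, item {col}"
                )
            data.loc[ridx, col] = val
    return ResponseMatrix(data=data, role=role, occasion=occasion, n_categories=n_cat)


def write_responses(m: ResponseMatrix, path) -> None:
    """Write a ResponseMatrix as a wide CSV; missing cells become blank."""
    out = m.data.copy()
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=True, index_label="dyad_id")


def collapse_categories(
    m: ResponseMatrix, source_cat: int, into_cat: int
) -> ResponseMatrix:
    """Merge one response category into another (e.g. 4 -> 3).

    Used when the top category is endorsed too rarely to support its own
    level.  ``n_categories`` drops by one when the merged category was
    the maximum; missing cells are untouched.
    """
    if source_cat == into_cat:
        raise DataError("source and target categories must differ")
    if source_cat > m.n_categories or into_cat > m.n_categories:
        raise DataError("category outside the response scale")
    data = m.data.where(m.data != source_cat, other=float(into_cat))
    n_cat = m.n_categories - 1 if source_cat == m.n_categories else m.n_categories
    return ResponseMatrix(
        data=data, role=m.role, occasion=m.occasion, n_categories=n_cat
    )


@dataclass(frozen=True)
class Table3Fixture:
    """Published per-item summary: response distributions per role,
    test-retest agreement and weighted kappa per role, and child-parent
    concordance per item (one value, repeated on both role rows)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        n_items = self.frame["item_id"].nunique()
        if n_items != 55 or len(self.frame) != 2 * n_items:
            raise DataError("summary fixture must have 55 items x 2 roles")

    def row(self, item_id: str, role: str) -> pd.Series:
        sel = self.frame[
            (self.frame["item_id"] == item_id) & (self.frame["role"] == role)
        ]
        if sel.empty:
            raise KeyError((item_id, role))
        return sel.iloc[0]

    def missing_pct(self, role: str) -> pd.Series:
        sub = self.frame[self.frame["role"] == role]
        return pd.Series(sub["missing_pct"].values, index=sub["item_id"].values)

    def category_pcts(self, role: str) -> pd.DataFrame:
        sub = self.frame[self.frame["role"] == role].set_index("item_id")
        return sub[["cat1_pct", "cat2_pct", "cat3_pct", "cat4_pct"]]

    def concordance(self) -> pd.Series:
        sub = self.frame[self.frame["role"] == "child"].set_index("item_id")
        return sub["concordance"]

    @property
    def item_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["item_id"]))


def load_table3_fixture() -> Table3Fixture:
    """Load the packaged transcription of the published item summary."""
    with importlib.resources.files("painet").joinpath(
        "data/table3_summary.csv"
    ).open() as fh:
        frame = pd.read_csv(fh)
    return Table3Fixture(frame)


def read_responses_long(
    path,
    role: str,
    occasion: str,
    catalog: ItemCatalog,
    columns: Mapping[str, str] | None = None,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ResponseMatrix:
    """Import a long-format table (one row per dyad x item response).

    ``columns`` maps the roles ``{"dyad_id", "item_id", "value"}`` to the
    actual column names in the file.
    """
    colmap = {"dyad_id": "dyad_id", "item_id": "item_id", "value": "value"}
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for want in colmap.values():
        if want not in raw.columns:
            raise DataError(f"{path}: missing column {want!r}")
    na_set = {t.strip() for t in na_tokens} | {""}
    wide = raw.pivot_table(
        index=colmap["dyad_id"],
        columns=colmap["item_id"],
        values=colmap["value"],
        aggfunc="first",
    )
    unknown = set(wide.columns) - set(catalog.item_ids)
    if unknown:
        raise DataError(f"{path}: unknown item ids {sorted(unknown)}")
    wide = wide.reindex(columns=catalog.item_ids)
    n_cat = int(catalog.frame["n_categories"].max())

    def _parse(token):
        if token is None or (isinstance(token, float) and np.isnan(token)):
            return np.nan
        token = str(token).strip()
        if token in na_set:
            return np.nan
        val = int(token)
        if not 1 <= val <= n_cat:
            raise DataError(f"{path}: category {val} out of range 1..{n_cat}")
        return float(val)

    data = wide.map(_parse)
    data.index.name = "dyad_id"
    return ResponseMatrix(data=data, role=role, occasion=occasion, n_categories=n_cat)
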