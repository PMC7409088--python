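import numpy as np
import pandas as pd
import pytest

from painet.dataset_io import DyadDataset, ItemCatalog, ResponseMatrix


@pytest.fixture
def small_catalog() -> ItemCatalog:
    frame = pd.DataFrame(
        {
            "item_id": ["PL1", "SC1", "MO1"],
            "domain": ["PL", "SC", "MO"],
            "label": ["a", "b", "c"],
            "n_categories": 4,
        }
    )
    return ItemCatalog(frame)


def make_matrix(values, role="child", occasion="test", items=None, n_categories=4):
    """Build a ResponseMatrix from a 2-D list (None -> missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    items = items or [f"IT{j + 1}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(
        arr, index=[f"D{i + 1}" for i in range(arr.shape[0])], columns=items
    )
    frame.index.name = "dyad_id"
    return ResponseMatrix(
        data=frame, role=role, occasion=occasion, n_categories=n_categories
    )


@pytest.fixture
def matrix_factory():
    return make_matrix


def make_dyads(child_vals, parent_vals, items=None, n_categories=4,
               child_retest=None, parent_retest=None):
    child = make_matrix(child_vals, "child", "test", items, n_categories)
    parent = make_matrix(parent_vals, "parent", "test", items, n_categories)
    items = child.items
    frame = pd.DataFrame(
        {
            "item_id": items,
            "domain": ["PL"] * len(items),
            "label": items,
            "n_categories": n_categories,
        }
    )
    matrices = {("child", "test"): child, ("parent", "test"): parent}
    if child_retest is not None:
        matrices[("child", "retest")] = make_matrix(
            child_retest, "child", "retest", items, n_categories
        )
    if parent_retest is not None:
        matrices[("parent", "retest")] = make_matrix(
            parent_retest, "parent", "retest", items, n_categories
        )
    return DyadDataset(catalog=ItemCatalog(frame), matrices=matrices)


@pytest.fixture
def dyad_factory():
    return make_dyads
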