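"""End-to-end orchestration: screen -> reliability -> networks -> compare.

Stage order mirrors the questionnaire-development workflow: items are
screened and deleted first, reliability/concordance statistics are
computed on the surviving items at the original response scale, the
rarely endorsed top category is collapsed into the one below it, and
the role-specific conditional-independence networks are extracted from
the collapsed scale and compared on common layout coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataset_io import (
    CONSENSUS_DELETIONS,
    DyadDataset,
    collapse_categories,
    write_responses,
)
from .network_compare import (
    ItemNetwork,
    compare,
    fr_layout,
    render,
    write_edge_list,
)
from .network_inference import extract_network
from .reliability import BootstrapConfig, reliability_report
from .screening import ScreeningConfig, build_screening_report
from .synthetic import SyntheticSpec, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    synthetic: SyntheticSpec | None = None
    dyads: DyadDataset | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    bootstrap: BootstrapConfig | None = field(default_factory=BootstrapConfig)
    consensus_roster: tuple[str, ...] = ()
    collapse_top_category: bool = True
    penalty_grid: np.ndarray | None = None
    max_digits: float = 2.0
    retention: float = 0.75
    min_pairs: int = 3
    layout_seed: int = 0
    output_dir: Path | None = None
    render_figures: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.dyads is None):
            raise ValueError(
                "exactly one of synthetic spec or dyad dataset must be given"
            )


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the run report as a plain dict and,
    when an output directory is configured, writes stage artifacts."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        logger.info("simulating dyads: %s", config.synthetic)
        dyads, truth_c, truth_p = simulate_study(config.synthetic)
        if out:
            for (role, occ), m in dyads.matrices.items():
                write_responses(m, out / f"responses_{role}_{occ}.csv")
            truth = {
                "child_edges": sorted(map(sorted, truth_c.edges)),
                "parent_edges": sorted(map(sorted, truth_p.edges)),
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
    else:
        dyads = config.dyads

    report: dict = {"version": __version__}

    try:
        screening = build_screening_report(
            dyads, config.screening, list(config.consensus_roster)
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"screening stage failed: {exc}") from exc
    report["screening"] = {
        "n_items": len(dyads.catalog.item_ids),
        "deleted": screening.deleted_items,
        "n_deleted": len(screening.deleted_items),
        "n_surviving": len(screening.surviving_items),
        "alpha": {
            role: {"alpha": a, "n_complete": n, "reliable": flag}
            for role, (a, n, flag) in screening.alpha.items()
        },
    }
    if out:
        screening.per_item_role.to_csv(out / "screening_items.csv", index=False)
        screening.deletion.to_csv(out / "deletion_roster.csv", index=False)

    surviving = dyads.subset_items(screening.surviving_items)

    rel = reliability_report(surviving, bootstrap=config.bootstrap)
    if len(rel):
        bands = (
            rel.groupby("kind")["band"].value_counts().unstack(fill_value=0)
        )
        report["reliability"] = {
            "bands": {
                k: {lab: int(c) for lab, c in v.items()}
                for k, v in bands.iterrows()
            }
        }
    else:
        report["reliability"] = {"bands": {}}
    if out and len(rel):
        rel.to_csv(out / "reliability.csv", index=False)

    networks: dict[str, ItemNetwork] = {}
    net_summary: dict[str, dict] = {}
    domains = surviving.catalog.domains
    for role in ("child", "parent"):
        if not surviving.has(role, "test"):
            continue
        m = surviving.get(role, "test")
        if config.collapse_top_category and m.n_categories >= 4:
            m = collapse_categories(m, m.n_categories, m.n_categories - 1)
        try:
            result = extract_network(
                m,
                min_pairs=config.min_pairs,
                grid=config.penalty_grid,
                max_digits=config.max_digits,
                retention=config.retention,
            )
        except Exception as exc:
            raise RuntimeError(f"network stage failed for {role}: {exc}") from exc
        net = ItemNetwork.from_edge_table(
            result.retained_edges, nodes=m.items, domains=domains
        )
        networks[role] = net
        net_summary[role] = {
            "lambda": result.lam,
            "kappa": result.estimate.condition_number,
            "eta0": result.lfdr.eta0,
            "k_df": result.lfdr.k_df,
            "n_edges": int(len(net.edges)),
        }
        if out:
            result.edges.to_csv(out / f"edges_{role}.csv", index=False)
            result.path.to_csv(out / f"penalty_path_{role}.csv", index=False)
            write_edge_list(net, out / f"network_{role}.csv")
    report["networks"] = net_summary

    if {"child", "parent"} <= networks.keys():
        comparison = compare(networks["child"], networks["parent"])
        report["comparison"] = {
            "shared": sorted(sorted(e) for e in comparison.shared),
            "n_shared": len(comparison.shared),
            "n_unique_child": len(comparison.unique_to_a),
            "n_unique_parent": len(comparison.unique_to_b),
            "max_degree_child": comparison.max_degree_a,
            "max_degree_parent": comparison.max_degree_b,
        }
        if out and config.render_figures:
            coords = fr_layout(networks["child"], seed=config.layout_seed)
            render(networks["child"], coords, out / "network_child.png")
            coords_p = fr_layout(networks["parent"], reference=coords)
            render(networks["parent"], coords_p, out / "network_parent.png")

    if out:
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report


def fixture_report(
    screening_config: ScreeningConfig = ScreeningConfig(),
    consensus_roster: tuple[str, ...] = CONSENSUS_DELETIONS,
) -> dict:
    """Replay the deletion protocol and concordance adequacy rule on the
    packaged published summary table; returns the headline counts."""
    from .dataset_io import load_table3_fixture
    from .reliability import adequate_concordance_items
    from .screening import screen_fixture

    fixture = load_table3_fixture()
    scr = screen_fixture(fixture, screening_config, list(consensus_roster))
    adequate = adequate_concordance_items(fixture)
    return {
        "missing_gt40_both": scr.missing_both,
        "n_missing_gt40_both": len(scr.missing_both),
        "missing_gt20_both": scr.missing_both_after_first_rule,
        "n_missing_gt20_both": len(scr.missing_both_after_first_rule),
        "floor_both": scr.floor_both,
        "n_floor_both": len(scr.floor_both),
        "adequate_concordance": adequate,
        "n_adequate_concordance": len(adequate),
        "deleted": scr.deleted,
        "n_deleted": len(scr.deleted),
        "n_surviving": len(scr.surviving),
    }


def config_to_dict(config: RunConfig) -> dict:
    """JSON-safe echo of a run configuration."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: convert(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (Path,)):
            return str(obj)
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, DyadDataset):
            return "<in-memory dataset>"
        return obj

    return convert(config)
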