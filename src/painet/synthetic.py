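"""Latent-Gaussian dyad generator with a known conditional-independence graph.

Ordinal responses arise by thresholding correlated multivariate-normal
latents, the standard generative counterpart of the Spearman -> precision
pipeline used downstream.  The child's latent vector is drawn from a
Gaussian graphical model with known sparse precision matrix; the parent
latent blends the child's (item-wise, at the concordance correlation)
with an independent draw from the parent's own graphical model; retest
latents correlate with the test occasion at the retest correlation.
Cells are then removed completely at random, optionally with extra
"not applicable" blocks that knock out a whole item for a subject
subset (emulating items that simply do not apply to most children,
e.g. reading braille).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import DOMAINS, DyadDataset, ItemCatalog, ResponseMatrix

# Default per-item cut points on the standard-normal latent scale.
# Chosen so category probabilities are (0.65, 0.25, 0.08, 0.02): a
# strong floor with rare endorsement of the top category, the shape
# dominating the published response distributions.
DEFAULT_CATEGORY_PROBS = (0.65, 0.25, 0.08, 0.02)


def thresholds_from_probs(probs) -> np.ndarray:
    """Cut points z_1 < ... < z_{C-1} with P(cat c) = Phi(z_c) - Phi(z_{c-1})."""
    probs = np.asarray(probs, dtype=float)
    if probs.min() <= 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category probabilities must be positive and sum to 1")
    return stats.norm.ppf(np.cumsum(probs)[:-1])


@dataclass
class SyntheticSpec:
    """Data-generating parameters for a dyadic ordinal study."""

    p: int = 20
    n: int = 200
    edge_density: float = 0.1
    partial_corr_magnitude: float = 0.4
    thresholds: np.ndarray | None = None  # (p, C-1) or (C-1,); None -> default
    concordance_rho: float = 0.5
    retest_rho: float = 0.75
    missing_rate: float = 0.05
    na_block_items: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must be in [0, 1]")
        if not abs(self.partial_corr_magnitude) < 1:
            raise ValueError("|partial_corr_magnitude| must be < 1")
        for name in ("concordance_rho", "retest_rho"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")

    def threshold_matrix(self) -> np.ndarray:
        th = (
            thresholds_from_probs(DEFAULT_CATEGORY_PROBS)
            if self.thresholds is None
            else np.asarray(self.thresholds, dtype=float)
        )
        if th.ndim == 1:
            th = np.tile(th, (self.p, 1))
        if th.shape[0] != self.p:
            raise ValueError("threshold matrix must have one row per item")
        if not (np.diff(th, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly increasing per item")
        return th

    @property
    def n_categories(self) -> int:
        return self.threshold_matrix().shape[1] + 1


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth precision matrix and its off-diagonal support."""

    omega: np.ndarray
    edges: frozenset  # frozenset of (i, j) index pairs, i < j

    @property
    def p(self) -> int:
        return self.omega.shape[0]

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.omega))
        rho = -self.omega / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return rho


def sample_precision(
    p: int,
    edge_density: float,
    partial_corr_magnitude: float,
    seed: int,
    sign_prob_positive: float = 0.5,
    min_eig: float = 1e-3,
    max_attempts: int = 100,
) -> SyntheticTruth:
    """Draw a sparse precision matrix with unit diagonal whose edge
    partial correlations equal +/- ``partial_corr_magnitude`` exactly.

    An Erdos-Renyi graph at ``edge_density`` fixes the support; each
    edge gets a random sign.  Because the unit-diagonal parametrisation
    with exact edge magnitudes can be indefinite, the graph and signs
    are re-drawn until the matrix is positive definite; after
    ``max_attempts`` failures the requested magnitude/density
    combination is declared infeasible.
    """
    rng = np.random.default_rng(seed)
    mag = abs(partial_corr_magnitude)
    iu = np.triu_indices(p, k=1)
    for _ in range(max_attempts):
        present = rng.random(len(iu[0])) < edge_density
        signs = np.where(rng.random(len(iu[0])) < sign_prob_positive, 1.0, -1.0)
        omega = np.eye(p)
        # rho_ij = -omega_ij on the unit-diagonal scale
        omega[iu] = np.where(present, -signs * mag, 0.0)
        omega = omega + omega.T - np.eye(p)
        if mag == 0 or not present.any():
            edges = frozenset()
            return SyntheticTruth(omega=np.eye(p), edges=edges)
        if np.linalg.eigvalsh(omega)[0] > min_eig:
            edges = frozenset(
                (int(i), int(j))
                for i, j, keep in zip(iu[0], iu[1], present)
                if keep
            )
            return SyntheticTruth(omega=omega, edges=edges)
    raise ValueError(
        f"could not draw a positive-definite precision matrix at density "
        f"{edge_density}, |rho|={mag} after {max_attempts} attempts"
    )


def _latent_correlation(truth: SyntheticTruth) -> np.ndarray:
    sigma = np.linalg.inv(truth.omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _draw_latents(rng, corr: np.ndarray, n: int) -> np.ndarray:
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n, corr.shape[0])) @ chol.T


def _discretize(latents: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    p = latents.shape[1]
    out = np.empty_like(latents)
    for j in range(p):
        out[:, j] = np.searchsorted(thresholds[j], latents[:, j]) + 1
    return out


def _default_catalog(p: int) -> ItemCatalog:
    domains = [DOMAINS[j % len(DOMAINS)] for j in range(p)]
    frame = pd.DataFrame(
        {
            "item_id": [f"IT{j + 1}" for j in range(p)],
            "domain": domains,
            "label": [f"Synthetic item {j + 1}" for j in range(p)],
            "n_categories": 4,
        }
    )
    return ItemCatalog(frame)


def generate_dyads(
    truth_child: SyntheticTruth,
    truth_parent: SyntheticTruth,
    spec: SyntheticSpec,
    catalog: ItemCatalog | None = None,
    include_retest: bool = True,
) -> DyadDataset:
    """Simulate a full dyadic study (child/parent x test/retest)."""
    if truth_child.p != spec.p or truth_parent.p != spec.p:
        raise ValueError("truth dimension does not match spec.p")
    rng = np.random.default_rng(spec.seed)
    th = spec.threshold_matrix()
    n_cat = spec.n_categories
    if catalog is None:
        catalog = _default_catalog(spec.p)
        catalog.frame["n_categories"] = n_cat
    corr_child = _latent_correlation(truth_child)
    corr_parent = _latent_correlation(truth_parent)

    z_child = _draw_latents(rng, corr_child, spec.n)
    rho_c = spec.concordance_rho
    z_parent = rho_c * z_child + np.sqrt(1 - rho_c**2) * _draw_latents(
        rng, corr_parent, spec.n
    )

    latents = {("child", "test"): z_child, ("parent", "test"): z_parent}
    if include_retest:
        rho_t = spec.retest_rho
        for role, corr in (("child", corr_child), ("parent", corr_parent)):
            z = latents[(role, "test")]
            fresh = _draw_latents(rng, corr, spec.n)
            latents[(role, "retest")] = rho_t * z + np.sqrt(1 - rho_t**2) * fresh

    dyad_ids = [f"D{i + 1:04d}" for i in range(spec.n)]
    matrices = {}
    for key, z in latents.items():
        cats = _discretize(z, th).astype(float)
        mask = rng.random(cats.shape) < spec.missing_rate
        for j, frac in spec.na_block_items.items():
            block = rng.random(spec.n) < frac
            mask[:, j] |= block
        cats[mask] = np.nan
        frame = pd.DataFrame(cats, index=dyad_ids, columns=catalog.item_ids)
        frame.index.name = "dyad_id"
        matrices[key] = ResponseMatrix(
            data=frame, role=key[0], occasion=key[1], n_categories=n_cat
        )
    return DyadDataset(catalog=catalog, matrices=matrices)


def simulate_study(
    spec: SyntheticSpec,
    seed_child_structure: int | None = None,
    seed_parent_structure: int | None = None,
) -> tuple[DyadDataset, SyntheticTruth, SyntheticTruth]:
    """Convenience wrapper: draw role-specific truths, then the dyads.

    The two roles get different ground-truth graphs (different structure
    seeds), mirroring a study where the two respondent perspectives are
    differentially connected.
    """
    sc = spec.seed * 3 + 1 if seed_child_structure is None else seed_child_structure
    sp = spec.seed * 3 + 2 if seed_parent_structure is None else seed_parent_structure
    truth_child = sample_precision(
        spec.p, spec.edge_density, spec.partial_corr_magnitude, seed=sc
    )
    truth_parent = sample_precision(
        spec.p, spec.edge_density, spec.partial_corr_magnitude, seed=sp
    )
    dyads = generate_dyads(truth_child, truth_parent, spec)
    return dyads, truth_child, truth_parent


def category_probabilities(thresholds_row: np.ndarray) -> np.ndarray:
    """Normal-orthant category probabilities implied by one item's cuts."""
    cdf = stats.norm.cdf(np.asarray(thresholds_row, dtype=float))
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))
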