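"""Spatial interaction tendency of ligand-receptor pairs.

For each L-R interaction on a spatial transcriptomics slide, the ligand and
receptor expression profiles are treated as discrete spatial probability
distributions (spot coordinates as locations, expression as mass) and their
separation is measured with the symmetrized entropic-regularized Wasserstein
distance ``d_real``.  A permutation null is built by re-assigning the two
expression profiles to randomly permuted spot positions; the ratio of
``d_real`` to the mean permuted distance (``d_ratio``) quantifies spatial
tendency (``< 1``: ligand and receptor colocalize more than chance, a
short-range, juxtacrine-like interaction; ``> 1``: they are segregated, a
long-range, paracrine-like interaction).  One-sided permutation P-values
give the confidence, and interactions are classified short / medium / long
by intersecting top-fraction ranks with a significance cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lr_database import LRDatabase, LRInteraction
from .transport import WeightedPoints, wasserstein_lr, wasserstein_lr_batch

__all__ = [
    "SpatialExpression",
    "TendencyResult",
    "normalize_counts",
    "gene_distribution",
    "permutation_null",
    "tendency_statistics",
    "compute_tendency",
    "classify_ranges",
    "tendency_frame",
]

logger = logging.getLogger(__name__)


class MissingGeneError(KeyError):
    pass


class DegenerateDistributionError(ValueError):
    pass


@dataclass
class SpatialExpression:
    """Spot-resolved expression on a slide.

    ``values`` is a gene x spot matrix (dense ndarray or scipy sparse) with
    non-negative finite entries; ``coords`` holds one (x, y) pair per spot in
    arbitrary slide units.
    """

    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray
    values: np.ndarray | sp.spmatrix

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("duplicated spot_ids")
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be one (x, y) pair per spot")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"values shape {shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and (np.any(~np.isfinite(data)) or np.any(data < 0)):
            raise ValueError("expression values must be non-negative and finite")
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self.gene_index) != len(self.gene_ids):
            raise ValueError("duplicated gene_ids (sum duplicates on read)")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense per-spot expression vector for one gene."""
        if gene not in self.gene_index:
            raise MissingGeneError(gene)
        row = self.values[self.gene_index[gene]]
        if sp.issparse(self.values):
            return np.asarray(row.todense()).ravel()
        return np.asarray(row, dtype=float).ravel()

    def to_anndata(self):
        """Spot x gene AnnData view with coordinates in ``obsm['spatial']``."""
        import anndata as ad

        X = self.values.T.tocsr() if sp.issparse(self.values) else np.asarray(self.values).T
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=self.spot_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata


def normalize_counts(
    st: SpatialExpression,
    method: Literal["library_log1p", "none"] | None = "library_log1p",
    transform=None,
) -> SpatialExpression:
    """Pre-transform counts before building spatial distributions.

    The default scales every spot to the median library size and applies
    log1p.  A custom ``transform`` hook (matrix -> matrix) may be supplied
    instead; any negative values it produces are clamped to zero so the
    result can serve as distribution mass.
    """
    dense = np.asarray(_dense(st.values), dtype=float)
    if transform is not None:
        out = np.asarray(transform(dense), dtype=float)
    elif method in (None, "none"):
        out = dense
    elif method == "library_log1p":
        lib = dense.sum(axis=0)
        target = np.median(lib[lib > 0]) if np.any(lib > 0) else 1.0
        scale = np.divide(target, lib, out=np.zeros_like(lib), where=lib > 0)
        out = np.log1p(dense * scale[None, :])
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    out = np.clip(out, 0.0, None)
    return SpatialExpression(
        gene_ids=list(st.gene_ids),
        spot_ids=list(st.spot_ids),
        coords=st.coords.copy(),
        values=out,
    )


def _dense(values) -> np.ndarray:
    return np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values)


def _combined_values(st: SpatialExpression, genes: Sequence[str]) -> np.ndarray:
    """Per-spot mass of a gene or complex (elementwise minimum over subunits)."""
    if isinstance(genes, str):
        genes = [genes]
    vals = st.gene_values(genes[0]).copy()
    for gene in genes[1:]:
        vals = np.minimum(vals, st.gene_values(gene))
    return vals


def gene_distribution(
    st: SpatialExpression, gene_or_complex: Sequence[str] | str
) -> WeightedPoints:
    """Spatial expression distribution of a gene or subunit complex.

    Mass at each spot is the gene's expression value, or the per-spot
    minimum over subunits for a complex (all subunits must be present for
    the complex to exist); zero-mass spots are dropped and weights are
    normalized to total mass one.
    """
    vals = _combined_values(st, gene_or_complex)
    total = vals.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            f"no spot expresses {gene_or_complex!r} (combined mass is zero)"
        )
    support = vals > 0
    return WeightedPoints(coords=st.coords[support], weights=vals[support] / total)


@dataclass
class TendencyResult:
    """Spatial-tendency summary for one interaction."""

    interaction: LRInteraction
    d_real: float
    d_sim_mean: float
    d_ratio: float
    p_left: float
    p_right: float
    n_perm: int
    range_class: Literal["short", "medium", "long"] = "medium"

    @property
    def name(self) -> str:
        return self.interaction.name


def permutation_null(
    st: SpatialExpression,
    interaction: LRInteraction,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    reg: float = 0.001,
) -> np.ndarray:
    """Permutation null of the ligand-receptor Wasserstein distance.

    Each replicate independently re-assigns the ligand's and the receptor's
    per-spot expression values to coordinates drawn by permuting the full
    set of slide spot positions, rebuilds the two distributions, and records
    their symmetrized Sinkhorn distance.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lv = _combined_values(st, interaction.ligand_subunits)
    rv = _combined_values(st, interaction.receptor_subunits)
    if lv.sum() <= 0 or rv.sum() <= 0:
        raise DegenerateDistributionError(interaction.name)
    l_idx = np.flatnonzero(lv)
    r_idx = np.flatnonzero(rv)
    wl = lv[l_idx] / lv[l_idx].sum()
    wr = rv[r_idx] / rv[r_idx].sum()

    S = st.n_spots
    coords_l = np.empty((n_perm, len(l_idx), 2))
    coords_r = np.empty((n_perm, len(r_idx), 2))
    for b in range(n_perm):
        perm_l = rng.permutation(S)
        perm_r = rng.permutation(S)
        coords_l[b] = st.coords[perm_l[l_idx]]
        coords_r[b] = st.coords[perm_r[r_idx]]
    return wasserstein_lr_batch(wl, coords_l, wr, coords_r, reg=reg)


def tendency_statistics(
    d_real: float, d_sims: np.ndarray
) -> tuple[float, float, float]:
    """``d_ratio`` and one-sided permutation P-values.

    ``d_ratio = d_real / mean(d_sims)``.  P-values use the add-one
    (permutation-inclusive) estimator, ``(count + 1) / (n + 1)``, so they lie
    in (0, 1] and are never exactly zero.
    """
    d_sims = np.asarray(d_sims, dtype=float)
    if d_sims.size == 0:
        raise ValueError("empty permutation null")
    mean = float(d_sims.mean())
    if mean <= 0:
        raise ValueError("degenerate permutation null (zero mean distance)")
    n = d_sims.size
    d_ratio = d_real / mean
    p_left = (np.count_nonzero(d_sims <= d_real) + 1) / (n + 1)
    p_right = (np.count_nonzero(d_sims >= d_real) + 1) / (n + 1)
    return d_ratio, float(p_left), float(p_right)


def compute_tendency(
    st: SpatialExpression,
    db: LRDatabase,
    n_perm: int = 1000,
    reg: float = 0.001,
    seed: int = 0,
    top_fraction: float = 0.10,
    alpha: float = 0.01,
    classify: bool = True,
    strategy: Literal["intersection", "composite"] = "intersection",
) -> list[TendencyResult]:
    """Full spatial-tendency pass over a (coverage-filtered) database.

    Each interaction gets its own permutation stream spawned from ``seed``,
    so results are independent of database order and reproducible.
    """
    results: list[TendencyResult] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(db.interactions))
    for inter, child in zip(db.interactions, children):
        L = gene_distribution(st, inter.ligand_subunits)
        R = gene_distribution(st, inter.receptor_subunits)
        # evaluate d_real through the same batched solver settings as the
        # null so solver bias cancels out of d_ratio and the P-values
        d_real = float(
            wasserstein_lr_batch(
                L.weights, L.coords[None], R.weights, R.coords[None], reg=reg
            )[0]
        )
        d_sims = permutation_null(
            st, inter, n_perm=n_perm, seed=np.random.default_rng(child), reg=reg
        )
        d_ratio, p_left, p_right = tendency_statistics(d_real, d_sims)
        results.append(
            TendencyResult(
                interaction=inter,
                d_real=d_real,
                d_sim_mean=float(np.mean(d_sims)),
                d_ratio=d_ratio,
                p_left=p_left,
                p_right=p_right,
                n_perm=n_perm,
            )
        )
        logger.debug(
            "%s: d_real=%.4g d_ratio=%.3f p_left=%.3g p_right=%.3g",
            inter.name, d_real, d_ratio, p_left, p_right,
        )
    if classify:
        results = classify_ranges(
            results, top_fraction=top_fraction, alpha=alpha, strategy=strategy
        )
    return results


def _top_set(results, key, k) -> set[str]:
    ordered = sorted(results, key=key)
    return {r.name for r in ordered[:k]}


def classify_ranges(
    results: Sequence[TendencyResult],
    top_fraction: float = 0.10,
    alpha: float = 0.01,
    strategy: Literal["intersection", "composite"] = "intersection",
) -> list[TendencyResult]:
    """Assign short / medium / long range classes.

    Short candidates sit in the smallest ``top_fraction`` both by ``d_ratio``
    and by left-sided P-value; long candidates in the largest ``top_fraction``
    by ``d_ratio`` and the smallest by right-sided P-value (``intersection``
    strategy; ``composite`` ranks by the sum of the two ranks instead).
    Candidates whose relevant one-sided P-value is below ``alpha`` are
    classified, everything else is ``medium``.  Ties at the boundary break by
    P-value, then interaction name, for determinism.
    """
    if len(results) == 0:
        raise ValueError("no tendency results to classify")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    k = max(1, int(np.floor(top_fraction * len(results))))

    if strategy == "intersection":
        short_cand = _top_set(
            results, lambda r: (r.d_ratio, r.p_left, r.name), k
        ) & _top_set(results, lambda r: (r.p_left, r.d_ratio, r.name), k)
        long_cand = _top_set(
            results, lambda r: (-r.d_ratio, r.p_right, r.name), k
        ) & _top_set(results, lambda r: (r.p_right, -r.d_ratio, r.name), k)
    elif strategy == "composite":
        def ranks(key):
            ordered = sorted(results, key=key)
            return {r.name: i for i, r in enumerate(ordered)}

        r1 = ranks(lambda r: (r.d_ratio, r.p_left, r.name))
        r2 = ranks(lambda r: (r.p_left, r.d_ratio, r.name))
        short_cand = set(
            sorted(
                (r.name for r in results),
                key=lambda nm: (r1[nm] + r2[nm], nm),
            )[:k]
        )
        r3 = ranks(lambda r: (-r.d_ratio, r.p_right, r.name))
        r4 = ranks(lambda r: (r.p_right, -r.d_ratio, r.name))
        long_cand = set(
            sorted(
                (r.name for r in results),
                key=lambda nm: (r3[nm] + r4[nm], nm),
            )[:k]
        )
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")

    out = []
    for r in results:
        if r.name in short_cand and r.p_left < alpha:
            cls = "short"
        elif r.name in long_cand and r.p_right < alpha:
            cls = "long"
        else:
            cls = "medium"
        out.append(replace(r, range_class=cls))
    return out


def tendency_frame(results: Iterable[TendencyResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of tendency results."""
    rows = [
        {
            "interaction_name": r.name,
            "ligand": r.interaction.ligand,
            "receptor": r.interaction.receptor,
            "d_real": r.d_real,
            "d_sim_mean": r.d_sim_mean,
            "d_ratio": r.d_ratio,
            "p_left": r.p_left,
            "p_right": r.p_right,
            "range_class": r.range_class,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
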