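"""Gene-expression decoding of a statistical surface map plus set enrichment.

Decoding ranks genes by the Pearson correlation between their expression
profile across spatial samples and the t-map values at the sample
locations.  Candidate genes (positive correlation, nominal p below the
selection threshold) are then tested for overlap with curated gene sets by
the hypergeometric upper tail over a declared gene universe, with
enrichment odds ratios from the 2x2 overlap table and Benjamini-Hochberg
adjustment across all sets tested in one run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet
from .mesh import SurfaceMesh


@dataclass
class ExpressionMatrix:
    """Genes x spatial samples with per-sample vertex assignment."""

    genes: list[str]
    values: np.ndarray              # (n_genes, n_samples)
    sample_vertices: np.ndarray     # vertex index per sample
    mesh_id: str = "mesh"
    universe_size: int | None = None  # declared number of genes tested

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.sample_vertices = np.asarray(self.sample_vertices, dtype=np.int64)
        if self.values.shape != (len(self.genes), len(self.sample_vertices)):
            raise ValueError("expression shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            self._collapse_duplicates()
        if self.universe_size is None:
            self.universe_size = len(self.genes)

    def _collapse_duplicates(self) -> None:
        warnings.warn("duplicate gene symbols collapsed by mean", stacklevel=3)
        order: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            order.setdefault(g, []).append(i)
        self.values = np.vstack([self.values[rows].mean(axis=0) for rows in order.values()])
        self.genes = list(order)

    def bind_check(self, mesh: SurfaceMesh) -> None:
        if self.sample_vertices.min() < 0 or self.sample_vertices.max() >= mesh.n_vertices:
            raise ValueError("sample vertex ids out of range for mesh")


@dataclass
class DecodingResult:
    table: pd.DataFrame             # gene, r, p, similar
    candidates: list[str]
    alpha: float
    excluded_constant: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame             # set, annotation, overlap, table cells, OR, p, p_adj
    universe_size: int


def sample_tmap(tmap: np.ndarray, sample_vertices: np.ndarray,
                parcels: np.ndarray | None = None) -> np.ndarray:
    """t value at each sample's vertex (or parcel mean when parcel-assigned)."""
    t = np.asarray(tmap, dtype=np.float64).ravel()
    sv = np.asarray(sample_vertices, dtype=np.int64)
    if sv.min() < 0 or sv.max() >= t.shape[0]:
        raise ValueError("sample not bound to a valid vertex")
    if parcels is None:
        return t[sv]
    parcels = np.asarray(parcels, dtype=np.int64)
    out = np.empty(len(sv))
    for i, pid in enumerate(sv):
        members = np.flatnonzero(parcels == parcels[pid])
        out[i] = t[members].mean()
    return out


def decode(tmap: np.ndarray, expr: ExpressionMatrix, alpha: float = 0.05,
           signed: bool = False) -> DecodingResult:
    """Per-gene spatial Pearson correlation against the sampled t-map.

    Candidates are genes with r > 0 and two-sided p < alpha ("similar"
    spatial pattern); ``signed=True`` additionally returns the dissimilar
    list via a second table column.  Constant gene rows are excluded.
    """
    profile = sample_tmap(tmap, expr.sample_vertices)
    n = profile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    if profile.std() == 0:
        raise ValueError("t-map is constant at the sampled locations")

    X = expr.values
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all gene rows are constant")
    Xc = X - X.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(constant, np.nan, (Xc @ pc) / np.where(denom > 0, denom, 1.0))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    similar = (~constant) & (r > 0) & (p < alpha)
    table = pd.DataFrame({"gene": expr.genes, "r": r, "p": p, "similar": similar})
    if signed:
        table["dissimilar"] = (~constant) & (r < 0) & (p < alpha)
    table = table.sort_values(["r"], ascending=False, kind="stable").reset_index(drop=True)
    candidates = table.loc[table["similar"], "gene"].tolist()
    return DecodingResult(table=table, candidates=candidates, alpha=alpha,
                          excluded_constant=[g for g, c in zip(expr.genes, constant) if c])


def enrich(candidates, gene_sets, universe_size: int) -> EnrichmentResult:
    """Hypergeometric over-representation of each gene set in the candidates.

    The 2x2 table over the universe is (a, b; c, d) = (in-list & in-set,
    in-list only, in-set only, neither); p = P(X >= a) for X hypergeometric
    with population ``universe_size``, ``|set|`` successes and ``|list|``
    draws.  A zero cell gets the Haldane-Anscombe 0.5 correction for the
    reported odds ratio only.  BH adjustment spans all sets in this call.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    cand = set(candidates)
    rows = []
    for gs in gene_sets:
        members = set(gs.members)
        if universe_size < len(cand | members):
            raise ValueError(
                f"universe ({universe_size}) smaller than candidates union set "
                f"({len(cand | members)}) for {gs.name}")
        a = len(cand & members)
        b = len(cand) - a
        c = len(members) - a
        d = universe_size - a - b - c
        p = float(stats.hypergeom.sf(a - 1, universe_size, len(members), len(cand)))
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
            odds = (aa * dd) / (bb * cc)
            if a == 0:
                odds = 0.0
        else:
            odds = (a * d) / (b * c)
        rows.append({"set": gs.name, "annotation": gs.annotation, "overlap": a,
                     "in_list_only": b, "in_set_only": c, "neither": d,
                     "odds_ratio": float(odds), "p": p})
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p"], method="fdr_bh")
    table["p_adj"] = p_adj
    return EnrichmentResult(table=table, universe_size=universe_size)
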