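"""Cluster-wise brain-behavior correlation with FDR control.

Mean CT_spc within each significant cluster is extracted per subject and
correlated (Pearson) with symptom measures; Benjamini-Hochberg adjustment
runs over the full cluster-by-measure family computed in one call, the
conservative reading of an unspecified family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rft import Cluster


@dataclass
class ClusterFeatureTable:
    values: pd.DataFrame        # subjects x clusters, columns "cluster_<id>"
    clusters: list[Cluster]
    weighted: bool = False


def extract_cluster_means(ctspc: np.ndarray, clusters: list[Cluster],
                          vertex_areas: np.ndarray | None = None,
                          subject_ids=None) -> ClusterFeatureTable:
    """Per-subject mean CT_spc over each cluster's member vertices.

    Unweighted vertex mean by default; pass ``vertex_areas`` for an
    area-weighted mean (recorded on the returned table).
    """
    Y = np.atleast_2d(np.asarray(ctspc, dtype=np.float64))
    cols = {}
    for c in clusters:
        if c.n_vertices == 0:
            raise ValueError(f"cluster {c.id} is empty")
        block = Y[:, c.vertices]
        if vertex_areas is None:
            cols[f"cluster_{c.id}"] = block.mean(axis=1)
        else:
            w = np.asarray(vertex_areas)[c.vertices]
            cols[f"cluster_{c.id}"] = block @ (w / w.sum())
    frame = pd.DataFrame(cols, index=subject_ids)
    return ClusterFeatureTable(values=frame, clusters=list(clusters),
                               weighted=vertex_areas is not None)


def correlate_with_fdr(features: ClusterFeatureTable | pd.DataFrame,
                       scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r with two-sided p for every (cluster, measure) pair, BH-adjusted.

    Pairs need >= 3 complete observations; zero-variance columns are flagged
    and excluded from the family.
    """
    feats = features.values if isinstance(features, ClusterFeatureTable) else features
    rows = []
    for cname in feats.columns:
        for mname in scores.columns:
            x = feats[cname].to_numpy(dtype=np.float64)
            y = scores[mname].to_numpy(dtype=np.float64)
            ok = ~np.isnan(x) & ~np.isnan(y)
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"fewer than 3 complete pairs for {cname} x {mname}")
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({"cluster": cname, "measure": mname, "n": n,
                             "r": np.nan, "p": np.nan, "excluded": True})
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"cluster": cname, "measure": mname, "n": n,
                         "r": float(r), "p": float(p), "excluded": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = ~out["excluded"]
    if tested.any():
        _, p_adj, _, _ = multipletests(out.loc[tested, "p"], alpha=alpha, method="fdr_bh")
        out.loc[tested, "p_adj"] = p_adj
    return out
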