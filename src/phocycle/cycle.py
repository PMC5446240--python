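"""Mutant-cycle decomposition of induction into TF, cofactor, and
collaborative components, with Ward clustering into regulatory classes.

For each gene the four genotype means of the 2x2 factorial are combined
into

    X_tf  = beta(TF-only)      - beta(double-null)
    X_cof = beta(cofactor-only) - beta(double-null)
    CO    = (beta(full) - beta(cofactor-only)) - (beta(TF-only) - beta(double-null))

so that X_tf + X_cof + CO == beta(full) - beta(double-null) exactly.
CO is the 2x2 interaction contrast: the extra induction delivered when
TF and cofactor are present together, beyond the sum of their solo
effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .de import DEFit, G_COFACTOR_ONLY, G_FULL, G_NULL, G_TF_ONLY, GENOTYPES

COMPONENT_COLUMNS = ["X_Pho4", "X_Pho2", "CO"]


def decompose(fit: DEFit) -> pd.DataFrame:
    """Per-gene cycle components with moderated-t tests.

    Component standard errors reuse the moderated variance of the fit:
    se = s_tilde * sqrt(sum of 1/n over the genotypes in the contrast)
    (two genotypes for the solo components, all four for CO).
    """
    for g in GENOTYPES:
        if g not in fit.beta.columns:
            raise ValueError(f"genotype mean missing from fit: {g}")
    if fit.s2_tilde is None:
        raise ValueError("fit must carry moderated variances")
    b = fit.beta
    n = fit.n_per_genotype
    x_tf = b[G_TF_ONLY] - b[G_NULL]
    x_cof = b[G_COFACTOR_ONLY] - b[G_NULL]
    co = (b[G_FULL] - b[G_COFACTOR_ONLY]) - (b[G_TF_ONLY] - b[G_NULL])
    s = np.sqrt(fit.s2_tilde)
    lev2 = {
        "X_Pho4": 1.0 / n[G_TF_ONLY] + 1.0 / n[G_NULL],
        "X_Pho2": 1.0 / n[G_COFACTOR_ONLY] + 1.0 / n[G_NULL],
        "CO": sum(1.0 / n[g] for g in GENOTYPES),
    }
    df = min(fit.df_total, 1e9)
    out = pd.DataFrame({"X_Pho4": x_tf, "X_Pho2": x_cof, "CO": co})
    for comp in COMPONENT_COLUMNS:
        se = s * np.sqrt(lev2[comp])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = out[comp] / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        out[f"se_{comp}"] = se
        out[f"t_{comp}"] = t
        out[f"p_{comp}"] = p
    return out


def cluster_classes(components: pd.DataFrame, k: int = 3) -> tuple[pd.Series, np.ndarray]:
    """Ward-linkage clustering of (X_Pho4, X_Pho2, CO) into k classes.

    Classes follow the regulatory reading of the components:
    class I = cluster whose centroid maximizes X_Pho4 - |CO| (TF main
    effect dominates), class II = cluster maximizing CO - X_Pho4
    (collaboration dominates), class III = the rest. Returns the labels
    and the linkage matrix (for dendrogram export).
    """
    x = components[COMPONENT_COLUMNS].to_numpy()
    n = x.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} genes into {k} clusters")
    if k == 1:
        return pd.Series("I", index=components.index), np.empty((0, 4))
    linkage = hierarchy.ward(x)
    assignments = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    centroids = {
        c: x[assignments == c].mean(axis=0) for c in np.unique(assignments)
    }
    score_i = {c: cen[0] - abs(cen[2]) for c, cen in centroids.items()}
    class_i = max(score_i, key=score_i.get)
    score_ii = {
        c: cen[2] - cen[0] for c, cen in centroids.items() if c != class_i
    }
    class_ii = max(score_ii, key=score_ii.get) if score_ii else None
    name = {class_i: "I"}
    if class_ii is not None:
        name[class_ii] = "II"
    labels = pd.Series(
        [name.get(c, "III") for c in assignments], index=components.index
    )
    return labels, linkage


def component_heat_table(
    components: pd.DataFrame, cap_hi: float = 3.0, cap_lo: float = -2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Display tables: component estimates clipped to [cap_lo, cap_hi]
    and the companion -log10 p values. The input frame is left unclipped."""
    est = components[COMPONENT_COLUMNS].clip(lower=cap_lo, upper=cap_hi)
    with np.errstate(divide="ignore"):
        logp = -np.log10(components[[f"p_{c}" for c in COMPONENT_COLUMNS]])
    logp.columns = COMPONENT_COLUMNS
    return est, logp


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with branch
    lengths taken from merge heights."""
    if linkage.shape[0] == 0:
        return f"({','.join(labels)});" if len(labels) > 1 else f"{labels[0]};"
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
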