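"""Joining binding to induction: peak-to-gene assignment, direct-target
calling, functional peak categories, and cofactor-dependence summaries.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .chip import group_mean_bootstrap, group_ttest, peak_overlap
from .io import Gene

FUNCTIONAL_CATEGORIES = (
    "induced-with-or-without",
    "induced-only-with-cofactor",
    "non-functional",
    "NA",
)
_CATEGORY_RANK = {c: i for i, c in enumerate(FUNCTIONAL_CATEGORIES)}


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: list[Gene],
    allow_cds: bool = False,
    max_dist: int | None = None,
) -> pd.DataFrame:
    """Assign each peak to the nearest gene(s) on both sides, keeping a
    candidate only when the peak lies on the gene's 5' (upstream) side
    of its TSS.

    A peak between two divergently transcribed genes is assigned to
    both. Peaks overlapping any gene body (CDS) are dropped unless
    `allow_cds`; CDS overlap is recorded in the `in_cds` column.
    Returns one row per (peak, gene) with the TSS distance in bp.
    """
    if not genes:
        raise ValueError("empty gene table")
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for peak_id, row in peaks.iterrows():
        chrom, ps, pe = row["chrom"], int(row["start"]), int(row["end"])
        cands = by_chrom.get(chrom, [])
        in_cds = any(g.start < pe and ps < g.end for g in cands)
        if in_cds and not allow_cds:
            continue
        # nearest TSS strictly left of the peak, strictly right, or inside
        left, right, inside = None, None, []
        for g in cands:
            t = g.tss
            if ps <= t < pe:
                inside.append(g)
            elif t < ps:
                if left is None or t > left.tss:
                    left = g
            else:
                if right is None or t < right.tss:
                    right = g
        chosen: list[tuple[Gene, int]] = [(g, 0) for g in inside]
        if left is not None and left.strand == "-":
            chosen.append((left, ps - left.tss))
        if right is not None and right.strand == "+":
            chosen.append((right, right.tss - (pe - 1)))
        for g, dist in chosen:
            if max_dist is not None and dist > max_dist:
                continue
            rows.append({
                "peak_id": peak_id,
                "gene_id": g.gene_id,
                "distance": int(dist),
                "in_cds": bool(in_cds),
            })
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance", "in_cds"])


def call_direct_targets(
    assignments: pd.DataFrame,
    calls_with: pd.DataFrame,
    calls_without: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Categorize every (peak, gene) assignment by induction and call
    direct targets.

    A pair is `induced-with-or-without` when the gene is significantly
    induced in both cofactor states, `induced-only-with-cofactor` when
    only with the cofactor, otherwise `non-functional`; genes absent
    from the induction calls (filtered out upstream) get `NA` and are
    excluded from denominators. The per-peak category is the most
    functional category among the peak's genes. Direct targets are the
    genes behind at least one functional (induced) assignment.
    """
    pair_rows = assignments.copy()
    cats = []
    for gid in assignments["gene_id"]:
        if gid not in calls_with.index or gid not in calls_without.index:
            cats.append("NA")
            continue
        w = bool(calls_with.loc[gid, "induced"])
        wo = bool(calls_without.loc[gid, "induced"])
        if w and wo:
            cats.append("induced-with-or-without")
        elif w:
            cats.append("induced-only-with-cofactor")
        else:
            cats.append("non-functional")
    pair_rows["category"] = cats
    per_peak = (
        pair_rows.groupby("peak_id")["category"]
        .agg(lambda s: min(s, key=_CATEGORY_RANK.get))
        .to_frame("category")
    )
    direct = set(
        pair_rows.loc[
            pair_rows["category"].isin(FUNCTIONAL_CATEGORIES[:2]), "gene_id"
        ]
    )
    return pair_rows, per_peak, direct


def percent_activated(bound: int, induced: int, digits: int = 0) -> float:
    """100 * induced / bound with half-up rounding to `digits`."""
    if bound <= 0:
        raise ValueError("bound peak/gene count must be positive")
    if not 0 <= induced <= bound:
        raise ValueError("induced count must lie in [0, bound]")
    pct = Decimal(100 * induced) / Decimal(bound)
    q = Decimal(1).scaleb(-digits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def dependence_ratio(
    fc_noco: pd.Series, fc_co: pd.Series, shared_genes: set[str] | list[str]
) -> tuple[pd.Series, dict[str, float]]:
    """Per-gene linear-scale fold-change ratio without / with cofactor,
    over a shared target gene set, with boxplot-ready summaries.

    The mean of the ratios is the headline per-variant dependence
    statistic (1 = fully cofactor independent, -> 0 = fully dependent).
    """
    genes = [g for g in fc_co.index if g in set(shared_genes)]
    co = fc_co.loc[genes]
    noco = fc_noco.loc[genes]
    if (co <= 0).any() or (noco <= 0).any():
        raise ValueError("fold changes must be positive on the linear scale")
    ratios = (noco / co).rename("ratio")
    summary = {
        "mean": float(ratios.mean()),
        "q1": float(ratios.quantile(0.25)),
        "median": float(ratios.median()),
        "q3": float(ratios.quantile(0.75)),
        "n": int(len(ratios)),
    }
    return ratios, summary


def phosphatase_dependence_percent(
    act_noco: float,
    act_co: float,
    blank_noco: float,
    blank_co: float,
    floor_factor: float = 2.0,
) -> float | str:
    """Cofactor dependence of reporter enzyme activity, as a percentage.

    A condition counts as active only when its activity exceeds
    `floor_factor` times the TF-null blank; the percentage is
    100 * (activity - blank) without cofactor over the same with
    cofactor. Returns the string "no activity" when either condition is
    at blank level (or the denominator vanishes).
    """
    if min(act_noco, act_co, blank_noco, blank_co) < 0:
        raise ValueError("activities must be non-negative")
    if act_co <= floor_factor * blank_co:
        return "no activity"
    denom = act_co - blank_co
    if denom <= 0:
        return "no activity"
    if act_noco <= floor_factor * blank_noco:
        return 0.0
    return 100.0 * (act_noco - blank_noco) / denom


def most_accessible_quartile(occupancy: pd.Series) -> pd.Series:
    """The ceil(0.25 * n) sites with the lowest occupancy scores."""
    k = int(np.ceil(0.25 * len(occupancy)))
    return occupancy.nsmallest(k)


def motif_site_score_compare(
    site_scores: pd.Series,
    groups: pd.Series,
    compare: tuple[str, str],
    n_boot: int = 10_000,
    seed: int | None = None,
    restrict_accessible_quartile: bool = False,
) -> dict:
    """Compare a per-motif-site score (e.g. nucleosome occupancy or a
    competitor TF's enrichment) between binding groups.

    Groups are typically bound-by-both / bound-only-by-one / unbound,
    formed upstream by intersecting the motif inventory with peak sets.
    Reports group means with percentile-bootstrap CIs and a two-sided
    Student's t-test between the two named groups. With
    `restrict_accessible_quartile`, only the 25% of sites with the
    lowest scores are kept before grouping (used for competitor
    enrichment, to avoid confounding by nucleosomes).
    """
    scores = site_scores.astype(float)
    if restrict_accessible_quartile:
        scores = most_accessible_quartile(scores)
        groups = groups.loc[scores.index]
    present = []
    for g in pd.unique(groups):
        if (groups == g).sum() == 0:
            warnings.warn(f"empty group {g!r} omitted")
        else:
            present.append(g)
    summary = group_mean_bootstrap(
        scores.to_numpy(), groups.to_numpy(), n_boot=n_boot, seed=seed
    )
    a = scores[groups == compare[0]]
    b = scores[groups == compare[1]]
    t, p = group_ttest(a, b)
    return {"summary": summary, "t": t, "p": p, "groups": present}


def overlap_venn(a_peaks: pd.DataFrame, b_peaks: pd.DataFrame) -> dict[str, int]:
    """Venn counts of two factors' peak sets (any-bp overlap)."""
    fa = peak_overlap(a_peaks, b_peaks)["shared"]
    fb = peak_overlap(b_peaks, a_peaks)["shared"]
    return {
        "a_total": int(len(a_peaks)),
        "b_total": int(len(b_peaks)),
        "a_shared": int(fa.sum()),
        "a_only": int((~fa).sum()),
        "b_only": int((~fb).sum()),
    }
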