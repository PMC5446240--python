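"""ChIP coverage-track normalization, peak calling, occupancy ratios,
and cofactor-dependence classification.

Tracks are scaled so the genome-wide mean coverage is 1, enrichment is
taken as fold over a mock/input track, and a TF binding site is called
"cofactor dependent" when the cofactor co-binds and the peak height
drops more than `fold_cut`-fold when the cofactor is deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PEAK_COLUMNS

EPS = 1e-3  # floor added to enrichment ratios to avoid division by zero


@dataclass
class CoverageTrack:
    """Per-chromosome, per-bp non-negative enrichment values."""

    data: dict[str, np.ndarray]
    sample: str = ""
    condition: str = ""
    normalized: bool = False

    def chroms(self) -> list[str]:
        return list(self.data)

    def mean(self) -> float:
        total = sum(float(v.sum()) for v in self.data.values())
        n = sum(v.size for v in self.data.values())
        return total / n


def normalize_track(raw: CoverageTrack) -> CoverageTrack:
    """Scale so the genome-wide mean per-bp coverage is exactly 1."""
    mu = raw.mean()
    if mu == 0:
        raise ValueError("cannot normalize an all-zero track")
    data = {c: v / mu for c, v in raw.data.items()}
    return CoverageTrack(data, raw.sample, raw.condition, normalized=True)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def call_peaks_simple(
    tf: CoverageTrack,
    mock: CoverageTrack,
    min_fe: float = 3.0,
    min_width: int = 50,
    merge_gap: int = 100,
    min_run: int = 5,
) -> pd.DataFrame:
    """Threshold-based peak caller on fold enrichment over mock.

    FE = (tf + eps) / (mock + eps); maximal runs with FE >= min_fe are
    merged across gaps <= merge_gap and merged runs narrower than
    min_width are dropped. Runs shorter than min_run bp are treated as
    single-bp noise excursions and discarded before merging, so isolated
    spikes cannot chain into spurious wide calls. Summit = leftmost
    argmax of FE, height = max FE.
    """
    if set(tf.data) != set(mock.data):
        raise ValueError("tf and mock tracks cover different chromosomes")
    rows = []
    for chrom in tf.data:
        t, m = tf.data[chrom], mock.data[chrom]
        if t.size != m.size:
            raise ValueError(f"track length mismatch on {chrom}")
        fe = (t + EPS) / (m + EPS)
        runs = [(s, e) for s, e in _runs(fe >= min_fe) if e - s >= min_run]
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < min_width:
                continue
            summit = s + int(np.argmax(fe[s:e]))
            rows.append(
                {"chrom": chrom, "start": s, "end": e,
                 "summit": summit, "height": float(fe[s:e].max())}
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def peak_overlap(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Flag, for every peak in `a`, whether it overlaps >=1 bp with any
    peak in `b` (half-open interval arithmetic). Returns `a` plus a
    boolean `shared` column."""
    out = a.copy()
    shared = np.zeros(len(a), dtype=bool)
    by_chrom: dict[str, np.ndarray] = {}
    if len(b):
        for chrom, grp in b.groupby("chrom"):
            ivs = grp[["start", "end"]].to_numpy()
            by_chrom[chrom] = ivs[np.argsort(ivs[:, 0])]
    for i, (_, row) in enumerate(a.iterrows()):
        ivs = by_chrom.get(row["chrom"])
        if ivs is None:
            continue
        # first interval whose start is >= row.end cannot overlap; scan left
        j = np.searchsorted(ivs[:, 0], row["end"])
        shared[i] = bool((ivs[:j, 1] > row["start"]).any())
    out["shared"] = shared
    return out


def overlap_summary(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, int]:
    """Venn-style counts: shared/specific peaks in each set."""
    fa = peak_overlap(a, b)["shared"]
    fb = peak_overlap(b, a)["shared"]
    return {
        "shared_a": int(fa.sum()),
        "specific_a": int((~fa).sum()),
        "shared_b": int(fb.sum()),
        "specific_b": int((~fb).sum()),
    }


def occupancy_ratio(
    peaks: pd.DataFrame, track_noco: CoverageTrack, track_co: CoverageTrack
) -> pd.Series:
    """Per-peak log2 of (max coverage without cofactor) / (with cofactor).

    Both maxima are taken over the peak interval on normalized tracks;
    an epsilon floor keeps the ratio finite.
    """
    ratios = []
    for _, row in peaks.iterrows():
        chrom, s, e = row["chrom"], int(row["start"]), int(row["end"])
        for trk in (track_noco, track_co):
            if chrom not in trk.data or e > trk.data[chrom].size:
                raise ValueError(f"peak {chrom}:{s}-{e} outside track")
        hi_no = track_noco.data[chrom][s:e].max()
        hi_co = track_co.data[chrom][s:e].max()
        ratios.append(np.log2((hi_no + EPS) / (hi_co + EPS)))
    return pd.Series(ratios, index=peaks.index, name="log2_ratio")


def classify_dependence(
    peaks: pd.DataFrame,
    cofactor_peaks: pd.DataFrame,
    ratios: pd.Series,
    fold_cut: float = 2.0,
) -> pd.DataFrame:
    """Classify TF peaks by cofactor co-binding and binding dependence.

    dependent  : cofactor co-bound AND height drops more than fold_cut-fold
                 without the cofactor (log2 ratio < -log2(fold_cut))
    independent: co-bound, height maintained
    not-cobound: no cofactor peak overlaps
    """
    out = peak_overlap(peaks, cofactor_peaks).rename(columns={"shared": "cobound"})
    out["log2_ratio"] = ratios.to_numpy()
    cut = -np.log2(fold_cut)
    cat = np.where(
        ~out["cobound"], "not-cobound",
        np.where(out["log2_ratio"] < cut, "dependent", "independent"),
    )
    out["category"] = cat
    return out


def dependence_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Category tallies in dendrogram order (total, cobound split)."""
    c = classified["category"].value_counts()
    return {
        "total": int(len(classified)),
        "cobound": int((classified["cobound"]).sum()),
        "not_cobound": int(c.get("not-cobound", 0)),
        "dependent": int(c.get("dependent", 0)),
        "independent": int(c.get("independent", 0)),
    }


# ---------------------------------------------------------------------------
# Group statistics used for occupancy comparisons

def group_mean_bootstrap(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    n_boot: int = 10_000,
    seed: int | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Non-parametric percentile-bootstrap CI of each group mean."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    rows = []
    for g in pd.unique(groups):
        x = values[groups == g]
        mean = float(x.mean())
        if x.size < 2:
            rows.append({"group": g, "n": x.size, "mean": mean,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        boots = x[idx].mean(axis=1)
        rows.append({
            "group": g, "n": int(x.size), "mean": mean,
            "ci_lo": float(np.percentile(boots, lo_q)),
            "ci_hi": float(np.percentile(boots, hi_q)),
        })
    return pd.DataFrame(rows).set_index("group")


def group_ttest(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    variant: str = "student",
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant}")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)
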