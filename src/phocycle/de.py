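"""Differential-induction engine for the 2x2 TF x cofactor factorial design.

Counts are filtered for low expression, scaled between samples with TMM
(trimmed mean of M-values), transformed to log2 counts-per-million, and
fit with a per-gene genotype-means linear model. Residual variances are
shared across genes through an empirical-Bayes scaled-F prior, and
induction is tested against the composite null |log2 fold change| <= lfc
(a threshold fold-change test), with Benjamini-Hochberg control applied
globally across all contrasts so the raw p-value cutoff is the same for
every comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

# The four genotypes of the factorial design: TF (PHO4) present/absent
# crossed with cofactor (PHO2) present/absent. Lower case = deletion.
GENOTYPES = ("pho4.pho2", "pho4.PHO2", "PHO4.pho2", "PHO4.PHO2")
G_NULL, G_COFACTOR_ONLY, G_TF_ONLY, G_FULL = GENOTYPES

#: induction contrasts: TF-present vs TF-null, within each cofactor state
CONTRAST_WITH_COFACTOR = (G_FULL, G_COFACTOR_ONLY)
CONTRAST_WITHOUT_COFACTOR = (G_TF_ONLY, G_NULL)


def has_tf(genotype: str) -> bool:
    return genotype.split(".")[0] == "PHO4"


def has_cofactor(genotype: str) -> bool:
    return genotype.split(".")[1] == "PHO2"


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus the sample sheet.

    The sheet has columns ``sample_id``, ``genotype``, ``replicate``;
    sample ids must be bijective with count columns and every genotype
    must be present.
    """

    counts: pd.DataFrame
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.sheet["sample_id"]):
            raise ValueError("sample sheet ids do not match count matrix columns")
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing entries")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(GENOTYPES) - set(self.sheet["genotype"])
        if missing:
            raise ValueError(f"genotypes absent from sample sheet: {sorted(missing)}")
        # keep sheet in column order
        self.sheet = (
            self.sheet.set_index("sample_id").loc[list(self.counts.columns)].reset_index()
        )

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, genotype: str) -> list[str]:
        return list(self.sheet.loc[self.sheet["genotype"] == genotype, "sample_id"])


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    lib_sizes: pd.Series
    factors: pd.Series
    ref_sample: str


@dataclass
class DEFit:
    """Per-gene genotype means with (optionally moderated) variances."""

    beta: pd.DataFrame          # genes x genotypes, log2-CPM units
    s2: pd.Series               # pooled residual variance, df = df_resid
    df_resid: int
    n_per_genotype: pd.Series
    d0: float | None = None     # prior df (may be inf)
    s0_2: float | None = None   # prior variance
    s2_tilde: pd.Series | None = None
    components: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def df_total(self) -> float:
        if self.d0 is None:
            return float(self.df_resid)
        return self.d0 + self.df_resid


class EmptyResultError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Filtering

def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_low_samples: int = 3
) -> CountMatrix:
    """Drop genes with CPM < `min_cpm` in at least `min_low_samples` samples.

    CPM is computed on raw library sizes, before any TMM scaling.
    """
    cpm = cm.counts / cm.lib_sizes * 1e6
    n_low = (cpm < min_cpm).sum(axis=1)
    keep = n_low < min_low_samples
    if not keep.any():
        raise EmptyResultError("low-expression filter removed every gene")
    return CountMatrix(cm.counts.loc[keep].copy(), cm.sheet.copy())


# ---------------------------------------------------------------------------
# TMM normalization

def _quantile_ref(counts: pd.DataFrame, lib_sizes: pd.Series, p: float = 0.75) -> str:
    """Reference = sample whose upper-quartile count fraction is closest
    to the across-sample mean upper quartile."""
    f = counts.div(lib_sizes, axis=1).quantile(p, axis=0)
    return (f - f.mean()).abs().idxmin()

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f).

    Genes with a zero in either library are excluded; the per-gene log
    ratio M is weighted by its inverse asymptotic (delta-method binomial)
    variance and doubly trimmed on M and on average abundance A.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("no genes shared with reference; TMM factor set to 1")
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or w[sel].sum() == 0:
        return 1.0
    f = np.sum(m[sel] * w[sel]) / np.sum(w[sel])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1."""
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = cm.lib_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    ref = ref_sample or _quantile_ref(cm.counts, lib)
    ref_col = cm.counts[ref].to_numpy()
    factors = {}
    for s in cm.counts.columns:
        factors[s] = _tmm_pair(
            cm.counts[s].to_numpy(), ref_col, lib[s], lib[ref], trim_m, trim_a
        )
    f = pd.Series(factors)
    f /= np.exp(np.mean(np.log(f)))
    return NormFactors(lib_sizes=lib, factors=f, ref_sample=ref)


# ---------------------------------------------------------------------------
# log-CPM

def log_cpm(cm: CountMatrix, nf: NormFactors, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2((count + pseudocount) / (lib_size * factor + 1) * 1e6)."""
    eff = nf.lib_sizes * nf.factors
    return np.log2((cm.counts + pseudocount).div(eff + 1.0, axis=1) * 1e6)


# ---------------------------------------------------------------------------
# Genotype-means linear model

def fit_genotype_means(logcpm: pd.DataFrame, sheet: pd.DataFrame) -> DEFit:
    """Per-gene means by genotype with a pooled residual variance.

    Equivalent to OLS on genotype indicators: beta_{ij} is the mean over
    replicates of genotype j; s_i^2 is RSS_i / d with d = n - #genotypes.
    """
    groups = {g: list(sheet.loc[sheet["genotype"] == g, "sample_id"]) for g in GENOTYPES}
    for g, cols in groups.items():
        if not cols:
            raise ValueError(f"genotype {g} has no samples")
    n = logcpm.shape[1]
    d = n - len(GENOTYPES)
    beta = pd.DataFrame(
        {g: logcpm[cols].mean(axis=1) for g, cols in groups.items()}
    )
    rss = pd.Series(0.0, index=logcpm.index)
    for g, cols in groups.items():
        resid = logcpm[cols].sub(beta[g], axis=0)
        rss += (resid ** 2).sum(axis=1)
    if d >= 1:
        s2 = rss / d
    else:
        s2 = pd.Series(np.nan, index=logcpm.index)
    n_per = pd.Series({g: len(cols) for g, cols in groups.items()})
    return DEFit(beta=beta, s2=s2, df_resid=max(d, 0), n_per_genotype=n_per)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation (scaled-F prior, moment matching
# of log s^2 with digamma/trigamma inversion)

def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x for tiny x
        return 1.0 / np.sqrt(y)
    lo, hi = 1e-8, 1e8
    return brentq(lambda x: special.polygamma(1, x) - y, lo, hi)


def moderate_variances(fit: DEFit) -> DEFit:
    """Shrink per-gene variances toward a common prior.

    The prior (d0, s0^2) is estimated by matching the first two moments
    of log s^2 to those of a scaled F distribution; the posterior
    variance is the df-weighted average (d0*s0^2 + d*s^2) / (d0 + d).
    """
    d = fit.df_resid
    if d < 1:
        raise ValueError("no residual degrees of freedom; cannot moderate")
    s2 = fit.s2
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("too few positive variances to estimate a prior")
    z = np.log(s2[ok].to_numpy())
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    # residual spread of log s^2 beyond sampling noise => prior df
    excess = e_var * (ok.sum() - 1) / ok.sum() - special.polygamma(1, d / 2.0)
    if excess > 0:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    if np.isinf(d0):
        s2_tilde = pd.Series(s0_2, index=s2.index)
    else:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
        s2_tilde = s2_tilde.fillna(s0_2)
    return DEFit(
        beta=fit.beta,
        s2=fit.s2,
        df_resid=fit.df_resid,
        n_per_genotype=fit.n_per_genotype,
        d0=float(d0),
        s0_2=s0_2,
        s2_tilde=s2_tilde,
    )


# ---------------------------------------------------------------------------
# Threshold fold-change test (composite null |logFC| <= lfc)

def treat_test(
    fit: DEFit, contrast: tuple[str, str], lfc: float = 1.0
) -> pd.DataFrame:
    """Test each gene against the null |log2 FC| <= lfc.

    p = P(T > (|logFC| - lfc)/se) + P(T > (|logFC| + lfc)/se) on
    d0 + d degrees of freedom.
    """
    if fit.s2_tilde is None:
        raise ValueError("run moderate_variances first (moderated variances required)")
    ga, gb = contrast
    logfc = fit.beta[ga] - fit.beta[gb]
    leverage = 1.0 / fit.n_per_genotype[ga] + 1.0 / fit.n_per_genotype[gb]
    se = np.sqrt(fit.s2_tilde * leverage)
    df = min(fit.df_total, 1e9)
    afc = logfc.abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_right = (afc - lfc) / se
        t_left = (afc + lfc) / se
        p = stats.t.sf(t_right, df) + stats.t.sf(t_left, df)
    p = pd.Series(np.minimum(p, 1.0), index=logfc.index)
    zero = se == 0
    if zero.any():
        p[zero] = np.where(afc[zero] > lfc, 0.0, 1.0)
    return pd.DataFrame({"logFC": logfc, "se": se, "p": p})


# ---------------------------------------------------------------------------
# Globally pooled BH adjustment

def bh_adjust_global(
    tests: dict[str, pd.DataFrame], fdr: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Benjamini-Hochberg on the p-values pooled across every contrast.

    Pooling makes the implied raw-p cutoff identical for all contrasts.
    Adds columns q and induced (q < fdr and positive fold change).
    """
    names = list(tests)
    pooled = np.concatenate([tests[c]["p"].to_numpy() for c in names])
    _, q, _, _ = multipletests(pooled, method="fdr_bh")
    out = {}
    i = 0
    for c in names:
        t = tests[c].copy()
        n = len(t)
        t["q"] = q[i : i + n]
        t["induced"] = (t["q"] < fdr) & (t["logFC"] > 0)
        out[c] = t
        i += n
    return out


# ---------------------------------------------------------------------------
# Convenience: the full differential-induction pipeline

def run_de(
    cm: CountMatrix,
    lfc: float = 1.0,
    fdr: float = 0.05,
    min_cpm: float = 1.0,
    min_low_samples: int = 3,
    contrasts: dict[str, tuple[str, str]] | None = None,
) -> tuple[DEFit, dict[str, pd.DataFrame]]:
    """Filter, normalize, fit, moderate, and test induction contrasts."""
    if contrasts is None:
        contrasts = {
            "with_cofactor": CONTRAST_WITH_COFACTOR,
            "without_cofactor": CONTRAST_WITHOUT_COFACTOR,
        }
    cm = filter_low_expression(cm, min_cpm=min_cpm, min_low_samples=min_low_samples)
    nf = tmm_factors(cm)
    lc = log_cpm(cm, nf)
    fit = fit_genotype_means(lc, cm.sheet)
    fit = moderate_variances(fit)
    tests = {name: treat_test(fit, pair, lfc=lfc) for name, pair in contrasts.items()}
    calls = bh_adjust_global(tests, fdr=fdr)
    return fit, calls
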