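"""Synthetic genomes, factorial RNA-seq counts, and ChIP tracks with
machine-readable planted truth.

The generators emulate the study design this package analyzes: a toy
yeast-like genome with E-box motifs of graded quality planted in
promoters; a 4-genotype (TF x cofactor deletion) x replicate negative
binomial count matrix whose per-gene expected log2 induction follows the
additive component model (TF-alone + cofactor-alone + collaborative);
and per-bp ChIP coverage tracks with Gaussian-shaped peaks whose heights
attenuate by a planted factor alpha when the cofactor is absent.

Every source of randomness flows from the seed argument of each
generator, so identical seeds give byte-identical output files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip import CoverageTrack
from .de import CountMatrix, GENOTYPES, has_cofactor, has_tf
from .io import Gene
from .motif import EBOX, MOTIF_LEN, _window_mismatches

BASES = np.array(list("ACGT"))

PROMOTER_LEN = 1000   # bp upstream of the TSS used for motif planting
GENE_SLOT = 2000      # private bp per gene: guarantees non-overlapping promoters
CDS_LEN = 500


class PlacementError(ValueError):
    """Raised when genes cannot be placed with the required spacing."""


@dataclass(frozen=True)
class PlantedMotif:
    chrom: str
    position: int        # 0-based start of the 6-mer on the forward strand
    grade: int           # Hamming distance to the consensus (0, 1 or 2)
    owner: str | None    # gene whose promoter holds the site


@dataclass
class ToyGenome:
    chromosomes: dict[str, str]
    genes: list[Gene]
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    promoter_len: int = PROMOTER_LEN

    def promoter(self, gene: Gene) -> tuple[int, int]:
        """Promoter interval (0-based half-open) on the gene's strand."""
        if gene.strand == "+":
            return max(0, gene.tss - self.promoter_len), gene.tss
        end = min(len(self.chromosomes[gene.chrom]), gene.tss + 1 + self.promoter_len)
        return gene.tss + 1, end

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _mutate_kmer(kmer: list[str], positions: np.ndarray, rng: np.random.Generator) -> None:
    for p in positions:
        choices = [b for b in "ACGT" if b != kmer[p]]
        kmer[p] = choices[rng.integers(len(choices))]


def make_toy_genome(
    n_chrom: int = 2,
    chrom_len: int = 50_000,
    n_genes: int = 20,
    motif_plan: dict[int, int] | None = None,
    seed: int = 0,
    cds_len: int = CDS_LEN,
) -> ToyGenome:
    """Random genome with evenly slotted genes and motifs planted in
    promoters at recorded positions.

    Each gene owns a private 2 kb slot, so promoters (1 kb upstream of
    the TSS) never overlap a neighboring gene. `motif_plan` maps a
    mismatch grade (0, 1 or 2) to the number of promoters that receive a
    site of that grade; promoters are scrubbed so they contain no other
    window within one mismatch of the consensus.
    """
    motif_plan = dict(motif_plan or {})
    if any(g not in (0, 1, 2) for g in motif_plan):
        raise ValueError("motif grades must be 0, 1 or 2")
    n_motifs = sum(motif_plan.values())
    if n_motifs > n_genes:
        raise PlacementError(f"{n_motifs} motifs requested for {n_genes} promoters")
    slots_per_chrom = chrom_len // GENE_SLOT
    if slots_per_chrom * n_chrom < n_genes:
        raise PlacementError(
            f"cannot place {n_genes} genes with {GENE_SLOT} bp spacing in "
            f"{n_chrom} x {chrom_len} bp"
        )

    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=chrom_len))
        for i in range(n_chrom)
    }
    seqs = {c: list(s) for c, s in chroms.items()}

    # lay out genes, alternating chromosomes, one per slot
    genes: list[Gene] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        take = min(slots_per_chrom, n_genes - gi)
        for k in range(take):
            slot = k * GENE_SLOT
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                # [promoter 0..1000) [CDS 1000..1000+cds_len)
                start = slot + PROMOTER_LEN
                genes.append(Gene(f"g{gi:04d}", chrom, start, start + cds_len, "+"))
            else:
                # [CDS 100..100+cds_len) [promoter ...)
                start = slot + 100
                genes.append(Gene(f"g{gi:04d}", chrom, start, start + cds_len, "-"))
            gi += 1
        if gi == n_genes:
            break

    genome = ToyGenome(chromosomes=chroms, genes=genes)

    # plant motifs in randomly chosen promoters
    order = rng.permutation(n_genes)
    grades = [g for g, cnt in sorted(motif_plan.items()) for _ in range(cnt)]
    planted: list[PlantedMotif] = []
    for idx, grade in zip(order, grades):
        gene = genes[idx]
        p_start, p_end = genome.promoter(gene)
        # keep sites central so ChIP peaks built on them stay inside the promoter
        margin = min(300, (p_end - p_start - MOTIF_LEN) // 3)
        pos = int(rng.integers(p_start + margin, p_end - MOTIF_LEN - margin + 1))
        kmer = list(EBOX)
        if grade:
            positions = rng.choice(MOTIF_LEN, size=grade, replace=False)
            _mutate_kmer(kmer, positions, rng)
        seqs[gene.chrom][pos : pos + MOTIF_LEN] = kmer
        planted.append(PlantedMotif(gene.chrom, pos, grade, gene.gene_id))

    # scrub promoters: no background window within 1 mismatch of the
    # consensus anywhere in a promoter, other than the planted sites
    planted_at = {(m.chrom, m.position) for m in planted}
    for gene in genes:
        p_start, p_end = genome.promoter(gene)
        for _ in range(100):
            window_seq = "".join(seqs[gene.chrom][p_start:p_end])
            mm = _window_mismatches(window_seq)
            bad = [
                int(w) for w in np.flatnonzero(mm <= 1)
                if (gene.chrom, p_start + w) not in planted_at
            ]
            if not bad:
                break
            for w in bad:
                abs_w = p_start + w
                # mutate a base of this window that is outside any planted 6-mer
                candidates = [
                    abs_w + o for o in range(MOTIF_LEN)
                    if not any(
                        m.chrom == gene.chrom and m.position <= abs_w + o < m.position + MOTIF_LEN
                        for m in planted
                    )
                ]
                if not candidates:
                    continue
                p = candidates[int(rng.integers(len(candidates)))]
                cur = seqs[gene.chrom][p]
                seqs[gene.chrom][p] = [b for b in "ACGT" if b != cur][int(rng.integers(3))]
        else:
            raise PlacementError(f"could not scrub promoter of {gene.gene_id}")

    genome.chromosomes = {c: "".join(s) for c, s in seqs.items()}
    genome.planted_motifs = planted
    return genome


def motif_table(genome: ToyGenome) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": m.chrom, "position": m.position, "grade": m.grade,
             "owner": m.owner or ""}
            for m in genome.planted_motifs
        ],
        columns=["chrom", "position", "grade", "owner"],
    )


# ---------------------------------------------------------------------------
# Expression truth and factorial counts

EXPRESSION_CLASSES = ("I", "II", "III", "null")


def _class_label(x4: float, x2: float, co: float) -> str:
    if x4 == 0 and x2 == 0 and co == 0:
        return "null"
    if co == 0:
        return "I"
    if x4 == 0:
        return "II"
    return "III"


def make_expression_truth(
    gene_ids: list[str],
    frac_induced: float = 0.10,
    class_props: tuple[float, float, float] = (0.4, 0.4, 0.2),
    effect_range: tuple[float, float] = (1.0, 5.0),
    mix_range: tuple[float, float] = (0.5, 2.0),
    dispersion: float = 0.05,
    baseline_log2_range: tuple[float, float] = (3.0, 9.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Plant additive induction components on a random subset of genes.

    Class I genes carry a TF-alone effect (X_Pho4 ~ U(effect_range)),
    class II a purely collaborative effect (CO), class III a moderate
    mix of both; everything else is null. Baselines are log2-CPM-scale
    draws; the negative-binomial dispersion is shared by default.
    """
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    baseline = rng.uniform(*baseline_log2_range, size=n)
    x4 = np.zeros(n)
    x2 = np.zeros(n)
    co = np.zeros(n)
    n_induced = int(round(frac_induced * n))
    chosen = rng.permutation(n)[:n_induced]
    props = np.asarray(class_props, dtype=float)
    props = props / props.sum()
    n1 = int(round(props[0] * n_induced))
    n2 = int(round(props[1] * n_induced))
    c1, c2, c3 = chosen[:n1], chosen[n1 : n1 + n2], chosen[n1 + n2 :]
    x4[c1] = rng.uniform(*effect_range, size=c1.size)
    co[c2] = rng.uniform(*effect_range, size=c2.size)
    x4[c3] = rng.uniform(*mix_range, size=c3.size)
    co[c3] = rng.uniform(*mix_range, size=c3.size)
    labels = [_class_label(a, b, c) for a, b, c in zip(x4, x2, co)]
    return pd.DataFrame(
        {
            "baseline_log2": baseline,
            "X_Pho4": x4,
            "X_Pho2": x2,
            "CO": co,
            "class_label": labels,
            "dispersion": dispersion,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def expected_log2_expression(truth: pd.DataFrame, genotype: str) -> pd.Series:
    """baseline + X_Pho4*[TF] + X_Pho2*[cofactor] + CO*[both]."""
    tf, cof = has_tf(genotype), has_cofactor(genotype)
    return (
        truth["baseline_log2"]
        + truth["X_Pho4"] * tf
        + truth["X_Pho2"] * cof
        + truth["CO"] * (tf and cof)
    )


def simulate_counts(
    truth: pd.DataFrame,
    n_replicates: int = 2,
    lib_sizes: dict[str, float] | float = 5e6,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial counts for the 4-genotype factorial design.

    Per-sample means are lib_size * p where p renormalizes the expected
    linear-scale expression 2**(expected log2) to proportions within the
    sample. Variance is mu + phi * mu**2 (gamma-Poisson); phi = 0 gives
    pure Poisson noise.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate per genotype")
    phi = truth["dispersion"].to_numpy(dtype=float)
    if (phi < 0).any():
        raise ValueError("dispersions must be >= 0")
    rng = np.random.default_rng(seed)
    sample_ids, genotypes, replicates = [], [], []
    for g in GENOTYPES:
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"{g}_r{r}")
            genotypes.append(g)
            replicates.append(r)
    if isinstance(lib_sizes, (int, float)):
        lib_map = {s: float(lib_sizes) for s in sample_ids}
    else:
        lib_map = {s: float(lib_sizes[s]) for s in sample_ids}
    cols = {}
    for s, g in zip(sample_ids, genotypes):
        mu_log2 = expected_log2_expression(truth, g).to_numpy()
        prop = 2.0 ** mu_log2
        prop = prop / prop.sum()
        mu = lib_map[s] * prop
        lam = mu.copy()
        pos = phi > 0
        if pos.any():
            lam[pos] = rng.gamma(1.0 / phi[pos], mu[pos] * phi[pos])
        cols[s] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=truth.index)
    sheet = pd.DataFrame(
        {"sample_id": sample_ids, "genotype": genotypes, "replicate": replicates}
    )
    return CountMatrix(counts, sheet)


# ---------------------------------------------------------------------------
# ChIP truth and coverage tracks

PEAK_SIGMA = 50.0  # Gaussian peak width parameter, bp


def make_chip_truth(
    genome: ToyGenome,
    gene_ids: list[str] | None = None,
    frac_cobound: float = 0.77,
    frac_dependent: float = 14.0 / 77.0,
    height_range: tuple[float, float] = (6.0, 12.0),
    alpha_dependent: tuple[float, float] = (0.10, 0.35),
    alpha_independent: tuple[float, float] = (0.70, 1.00),
    sigma: float = PEAK_SIGMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant one TF peak per gene promoter, with cofactor co-binding and
    attenuation drawn to the study's proportions.

    The summit sits on the gene's planted motif when it has one,
    otherwise mid-promoter. Dependent peaks (alpha < 0.5) and
    independent peaks draw alpha from well-separated ranges so the
    planted label matches the >2-fold classification rule.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [g.gene_id for g in genome.genes]
    motif_pos = {m.owner: m for m in genome.planted_motifs if m.owner}
    n = len(gene_ids)
    n_cobound = int(round(frac_cobound * n))
    n_dep = int(round(frac_dependent * n_cobound))
    order = rng.permutation(n)
    cobound = np.zeros(n, dtype=bool)
    cobound[order[:n_cobound]] = True
    dependent = np.zeros(n, dtype=bool)
    dependent[order[:n_dep]] = True  # dependent peaks are a subset of cobound
    rows = []
    for i, gid in enumerate(gene_ids):
        gene = genome.gene_by_id(gid)
        if gid in motif_pos:
            summit = motif_pos[gid].position + MOTIF_LEN // 2
        else:
            p_start, p_end = genome.promoter(gene)
            summit = (p_start + p_end) // 2
        if summit >= len(genome.chromosomes[gene.chrom]):
            raise ValueError(f"peak summit outside chromosome for {gid}")
        alpha = (
            rng.uniform(*alpha_dependent)
            if dependent[i]
            else (rng.uniform(*alpha_independent) if cobound[i] else rng.uniform(*alpha_independent))
        )
        rows.append({
            "chrom": gene.chrom,
            "summit": int(summit),
            "sigma": sigma,
            "height": float(rng.uniform(*height_range)),
            "alpha": float(alpha),
            "cobound": bool(cobound[i]),
            "gene_id": gid,
        })
    return pd.DataFrame(rows)


def _add_bumps(
    arr: np.ndarray, summits: np.ndarray, heights: np.ndarray, sigmas: np.ndarray
) -> None:
    for s, h, sig in zip(summits, heights, sigmas):
        half = int(6 * sig)
        lo, hi = max(0, s - half), min(arr.size, s + half + 1)
        x = np.arange(lo, hi)
        arr[lo:hi] += h * np.exp(-0.5 * ((x - s) / sig) ** 2)


def simulate_chip_tracks(
    genome: ToyGenome,
    chip_truth: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
) -> dict[str, CoverageTrack]:
    """Per-bp tracks: TF with/without cofactor, cofactor, and mock.

    Each planted peak contributes a Gaussian bump over a flat baseline;
    without the cofactor the TF bump height is multiplied by the peak's
    alpha; the cofactor track carries bumps only at co-bound peaks; mock
    is baseline plus noise. Gaussian noise (sd = noise_sd) is added
    independently per track and values are clipped at zero.
    """
    lengths = {c: len(s) for c, s in genome.chromosomes.items()}
    for _, row in chip_truth.iterrows():
        if row["chrom"] not in lengths or not 0 <= row["summit"] < lengths[row["chrom"]]:
            raise ValueError(f"planted peak outside genome: {row['chrom']}:{row['summit']}")
    # warn on overlapping planted peaks (their signal simply sums)
    for chrom, grp in chip_truth.groupby("chrom"):
        s = np.sort(grp["summit"].to_numpy())
        sig = grp["sigma"].max()
        if (np.diff(s) < 4 * sig).any():
            warnings.warn(f"overlapping planted peaks on {chrom}; signal is summed")

    rng = np.random.default_rng(seed)
    tracks = {}
    specs = {
        "tf_with_cofactor": ("height", None),
        "tf_without_cofactor": ("height", "alpha"),
        "cofactor": ("height", "cobound"),
        "mock": (None, None),
    }
    for name, (hcol, mod) in specs.items():
        data = {c: np.full(n, float(baseline)) for c, n in lengths.items()}
        if hcol is not None:
            for chrom, grp in chip_truth.groupby("chrom"):
                h = grp[hcol].to_numpy(dtype=float)
                if mod == "alpha":
                    h = h * grp["alpha"].to_numpy(dtype=float)
                elif mod == "cobound":
                    h = h * grp["cobound"].to_numpy(dtype=float)
                _add_bumps(
                    data[chrom],
                    grp["summit"].to_numpy(),
                    h,
                    grp["sigma"].to_numpy(dtype=float),
                )
        if noise_sd > 0:
            for chrom in data:
                data[chrom] = data[chrom] + rng.normal(0.0, noise_sd, data[chrom].size)
        for chrom in data:
            data[chrom] = np.clip(data[chrom], 0.0, None)
        tracks[name] = CoverageTrack(data, sample=name, condition=name)
    return tracks
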