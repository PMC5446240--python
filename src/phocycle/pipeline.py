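"""End-to-end orchestration: simulate (or load) inputs, run every
analysis stage, and write a manifest so a run is reproducible and
re-runnable stage by stage from the files on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip, cycle, de, integrate, io, motif, syndata

log = logging.getLogger("phocycle")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    In simulate mode the synthetic-data module generates every input;
    otherwise counts/sheet/tracks/fasta/genes paths must point at
    existing files. Thresholds default to the analysis' standard values:
    fold-change null bound lfc=1 (twofold), FDR 0.05, peak calling at
    fold enrichment 3 over mock, binding dependence at a twofold height
    drop, motif grading up to 2 mismatches.
    """

    out_dir: str = "phocycle_run"
    simulate: bool = True
    seed: int = 0
    # simulation sizes
    n_chrom: int = 2
    chrom_len: int = 60_000
    n_genes: int = 60
    n_bound: int = 20
    n_replicates: int = 2
    lib_size: float = 5e6
    noise_sd: float = 0.1
    variant: str = "independent"  # 'independent' (class I targets) or 'dependent' (class II)
    # input paths (non-simulate mode)
    counts: str | None = None
    sheet: str | None = None
    fasta: str | None = None
    genes: str | None = None
    tf_track: str | None = None
    tf_noco_track: str | None = None
    cofactor_track: str | None = None
    mock_track: str | None = None
    # thresholds
    lfc: float = 1.0
    fdr: float = 0.05
    min_fe: float = 3.0
    fold_cut: float = 2.0
    max_mm: int = 2
    k_classes: int = 3
    allow_cds: bool = False
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extras = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cfg

    def validate(self) -> None:
        for name in ("lfc", "fdr", "min_fe", "fold_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not self.simulate:
            for name in ("counts", "sheet", "fasta", "genes",
                         "tf_track", "tf_noco_track", "cofactor_track", "mock_track"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config path {name!r} missing: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def simulate_study(cfg: RunConfig) -> dict:
    """Generate a coherent synthetic study: genome, expression truth
    with planted components on the TF-bound genes, factorial counts,
    ChIP truth, and coverage tracks."""
    rng = np.random.default_rng(cfg.seed)
    sub = lambda: int(rng.integers(2**31 - 1))  # noqa: E731
    genome = syndata.make_toy_genome(
        n_chrom=cfg.n_chrom, chrom_len=cfg.chrom_len, n_genes=cfg.n_genes,
        motif_plan={0: cfg.n_bound}, seed=sub(),
    )
    bound = sorted({m.owner for m in genome.planted_motifs if m.owner})
    gene_ids = [g.gene_id for g in genome.genes]
    truth = syndata.make_expression_truth(gene_ids, frac_induced=0.0, seed=sub())
    n_induced = int(round(0.8 * len(bound))) if cfg.variant == "independent" else int(round(0.5 * len(bound)))
    induced = list(rng.permutation(bound)[:n_induced])
    effects = rng.uniform(2.5, 5.0, size=len(induced))
    comp = "X_Pho4" if cfg.variant == "independent" else "CO"
    truth.loc[induced, comp] = effects
    truth["class_label"] = [
        syndata._class_label(a, b, c)
        for a, b, c in truth[["X_Pho4", "X_Pho2", "CO"]].itertuples(index=False)
    ]
    cm = syndata.simulate_counts(
        truth, n_replicates=cfg.n_replicates, lib_sizes=cfg.lib_size, seed=sub()
    )
    chip_truth = syndata.make_chip_truth(genome, gene_ids=bound, seed=sub())
    tracks = syndata.simulate_chip_tracks(
        genome, chip_truth, noise_sd=cfg.noise_sd, seed=sub()
    )
    return {
        "genome": genome, "truth": truth, "counts": cm,
        "chip_truth": chip_truth, "tracks": tracks, "bound_genes": bound,
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write outputs + manifest under out_dir.

    Returns the in-memory results bundle (fit, calls, components,
    classified peaks, motif census, target table, summary statistics).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    log.info("run_all seed=%s simulate=%s", cfg.seed, cfg.simulate)
    written: list[Path] = []

    def save(path: Path) -> Path:
        written.append(path)
        return path

    try:
        if cfg.simulate:
            study = simulate_study(cfg)
            genome, cm = study["genome"], study["counts"]
            tracks, chip_truth = study["tracks"], study["chip_truth"]
            io.write_fasta(genome.chromosomes, save(out / "genome.fa"))
            io.write_genes_bed(genome.genes, save(out / "genes.bed"))
            syndata.motif_table(genome).to_csv(
                save(out / "truth_motifs.tsv"), sep="\t", index=False)
            study["truth"].to_csv(save(out / "truth_expression.tsv"), sep="\t")
            chip_truth.to_csv(save(out / "truth_chip.tsv"), sep="\t", index=False)
            io.write_counts(cm.counts, save(out / "counts.tsv"))
            io.write_sample_sheet(cm.sheet, save(out / "sample_sheet.tsv"))
            for name, trk in tracks.items():
                io.write_bedgraph(trk.data, save(out / f"track_{name}.bedGraph"))
            genes = genome.genes
            fasta = genome.chromosomes
        else:
            cm = de.CountMatrix(io.read_counts(cfg.counts), io.read_sample_sheet(cfg.sheet))
            fasta = io.read_fasta(cfg.fasta)
            genes = io.read_genes_bed(cfg.genes)
            lengths = {c: len(s) for c, s in fasta.items()}
            tracks = {
                "tf_with_cofactor": chip.CoverageTrack(io.read_bedgraph(cfg.tf_track, lengths)),
                "tf_without_cofactor": chip.CoverageTrack(io.read_bedgraph(cfg.tf_noco_track, lengths)),
                "cofactor": chip.CoverageTrack(io.read_bedgraph(cfg.cofactor_track, lengths)),
                "mock": chip.CoverageTrack(io.read_bedgraph(cfg.mock_track, lengths)),
            }

        # --- differential induction ---------------------------------
        fit, calls = de.run_de(cm, lfc=cfg.lfc, fdr=cfg.fdr)
        for name, tab in calls.items():
            tab.to_csv(save(out / f"de_{name}.tsv"), sep="\t", index_label="gene_id")
        nf = de.tmm_factors(de.filter_low_expression(cm))
        pd.DataFrame({"lib_size": nf.lib_sizes, "tmm_factor": nf.factors}).to_csv(
            save(out / "normalization.tsv"), sep="\t", index_label="sample_id")

        # --- mutant cycle -------------------------------------------
        components = cycle.decompose(fit)
        labels, linkage = cycle.cluster_classes(components, k=cfg.k_classes)
        components["class"] = labels
        components.to_csv(save(out / "cycle_components.tsv"), sep="\t",
                          index_label="gene_id")
        (out / "cycle_dendrogram.nwk").write_text(
            cycle.linkage_to_newick(linkage, list(components.index)))
        written.append(out / "cycle_dendrogram.nwk")

        # --- ChIP ----------------------------------------------------
        norm = {k: chip.normalize_track(t) for k, t in tracks.items()}
        peaks = chip.call_peaks_simple(norm["tf_with_cofactor"], norm["mock"],
                                       min_fe=cfg.min_fe)
        cof_peaks = chip.call_peaks_simple(norm["cofactor"], norm["mock"],
                                           min_fe=cfg.min_fe)
        ratios = chip.occupancy_ratio(peaks, norm["tf_without_cofactor"],
                                      norm["tf_with_cofactor"])
        classified = chip.classify_dependence(peaks, cof_peaks, ratios,
                                              fold_cut=cfg.fold_cut)
        io.write_peaks_bed(classified, save(out / "peaks_tf.bed"), name="TF:with_cofactor")
        classified.to_csv(save(out / "peaks_classified.tsv"), sep="\t",
                          index_label="peak_id")

        # --- motif ---------------------------------------------------
        grades, census = motif.best_motif_per_peak(peaks, fasta, max_mm=cfg.max_mm)
        motif.hits_table(peaks, fasta, max_mm=cfg.max_mm).to_csv(
            save(out / "motif_hits.tsv"), sep="\t", index=False)
        census.to_csv(save(out / "motif_census.tsv"), sep="\t", header=True)

        # --- integrate ----------------------------------------------
        assignments = integrate.assign_peaks_to_genes(peaks, genes,
                                                      allow_cds=cfg.allow_cds)
        pairs, per_peak, direct = integrate.call_direct_targets(
            assignments, calls["with_cofactor"], calls["without_cofactor"])
        pairs.to_csv(save(out / "target_table.tsv"), sep="\t", index=False)
        per_peak.to_csv(save(out / "peak_categories.tsv"), sep="\t",
                        index_label="peak_id")
        counts_cat = per_peak["category"].value_counts().to_dict()
        denom = int((per_peak["category"] != "NA").sum())
        functional = sum(counts_cat.get(c, 0)
                         for c in integrate.FUNCTIONAL_CATEGORIES[:2])
        summary = {
            "n_peaks": int(len(peaks)),
            "n_assigned_peaks": int(per_peak.shape[0]),
            "n_direct_targets": len(direct),
            "category_counts": {k: int(v) for k, v in counts_cat.items()},
            "percent_activated": (
                integrate.percent_activated(denom, functional) if denom else None
            ),
            "dependence_counts": chip.dependence_counts(classified),
            "motif_census": {str(k): int(v) for k, v in census.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        written.append(out / "summary.json")

        manifest = {
            "config": {k: v for k, v in asdict(cfg).items() if k != "extras"},
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {
            "fit": fit, "calls": calls, "components": components,
            "classified_peaks": classified, "motif_census": census,
            "target_pairs": pairs, "peak_categories": per_peak,
            "direct_targets": direct, "summary": summary,
        }
    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; partial outputs retained\n")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
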