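"""Classify TF binding sites by cofactor dependence from ChIP tracks.

Synthetic coverage tracks carry Gaussian peaks whose height attenuates
by a planted factor alpha when the cofactor is deleted; a site is
"dependent" when the cofactor co-binds and the peak height drops more
than twofold without it.
"""

from phocycle import chip, syndata

genome = syndata.make_toy_genome(n_chrom=4, chrom_len=250_000, n_genes=50, seed=5)
chip_truth = syndata.make_chip_truth(genome, seed=5)
tracks = syndata.simulate_chip_tracks(genome, chip_truth, noise_sd=0.1, seed=5)

norm = {k: chip.normalize_track(t) for k, t in tracks.items()}
peaks = chip.call_peaks_simple(norm["tf_with_cofactor"], norm["mock"], min_fe=3)
cof_peaks = chip.call_peaks_simple(norm["cofactor"], norm["mock"], min_fe=3)
ratios = chip.occupancy_ratio(peaks, norm["tf_without_cofactor"],
                              norm["tf_with_cofactor"])
classified = chip.classify_dependence(peaks, cof_peaks, ratios, fold_cut=2)

print(chip.dependence_counts(classified))
print(f"planted: {int(chip_truth['cobound'].sum())} cobound, "
      f"{int((chip_truth['alpha'] < 0.5).sum())} dependent (alpha < 0.5)")
print("log2_ratio < -1 at a co-bound site means binding needs the cofactor.")
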