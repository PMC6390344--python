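"""Genomic features versus the recombination landscape.

Correlates the window recombination track with (i) common-haplotype-allele
counts from the true parental strands, (ii) GC content and CpG-island
density of a synthetic chromosome-1 sequence whose composition is coupled
to the true hotspot map (emulating the GC/CpG enrichment of real
hotspots), and (iii) per-bird genomic inbreeding F on an LD-pruned panel
against individual GRN.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from recombscape import SimulationConfig, read_genotypes, simulate_population
from recombscape.features import (
    common_haplotype_alleles,
    cpg_density_windows,
    feature_correlations,
    gc_content_windows,
    inbreeding_coefficient,
    ld_prune,
)

QC = Path("results/qc")
SIM = Path("results/simdata")
MAPS = Path("results/maps")
OUT = Path("results/features")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def synthetic_sequence(length, intensity, rng):
    """Random sequence whose per-window GC tracks the crossover intensity."""
    chunks = []
    edges, rates = intensity
    rel = rates / rates.mean()
    for k in range(len(rates)):
        gc = np.clip(0.40 + 0.05 * (rel[k] - 1.0) + rng.normal(0, 0.01), 0.25, 0.7)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        n = int(edges[k + 1] - edges[k])
        chunks.append(BASES[rng.choice(4, size=n, p=p)])
    return np.concatenate(chunks).tobytes().decode()


def planted_islands(intensity, rng):
    edges, rates = intensity
    hot = rates > rates.min()
    rows = []
    for k in range(len(rates)):
        for _ in range(rng.poisson(4.0 if hot[k] else 0.8)):
            start = int(rng.integers(edges[k], edges[k + 1] - 600))
            rows.append(("1", start, start + 500))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def main() -> None:
    cfg = SimulationConfig.from_yaml(SIM / "config.yaml")
    rng = np.random.default_rng(cfg.seed + 100)
    track = pd.read_csv(MAPS / "window_rates.tsv", sep="\t", dtype={"chromosome": str})
    G = read_genotypes(QC / "genotypes", dialect="matrix")

    # regenerate the cohort (bit-identical from the stored config) for the
    # true parental haplotype strands
    _, ped, truth = simulate_population(cfg)
    windows = track[["chromosome", "start", "end"]]
    hap_track = common_haplotype_alleles(
        truth.haplotypes.reshape(-1, truth.haplotypes.shape[-1]),
        G.markers, windows,
    )

    chr1 = track["chromosome"] == "1"
    intensity = (truth.intensity.edges["1"], truth.intensity.rates["1"])
    seq = synthetic_sequence(cfg.chromosome_lengths_bp["1"], intensity, rng)
    gc_track = gc_content_windows({"1": seq}, windows[chr1])
    islands = planted_islands(intensity, rng)
    cpg_track = cpg_density_windows(islands, windows[chr1])

    OUT.mkdir(parents=True, exist_ok=True)
    islands.to_csv(OUT / "cpg_islands.bed", sep="\t", index=False, header=False)
    feats = hap_track.copy()
    feats["gc"] = np.nan
    feats.loc[chr1.to_numpy(), "gc"] = gc_track["gc"].to_numpy()
    feats["cpg_density"] = np.nan
    feats.loc[chr1.to_numpy(), "cpg_density"] = cpg_track["cpg_density"].to_numpy()
    feats.to_csv(OUT / "feature_tracks.tsv", sep="\t", index=False)

    rate = track.rename(columns={"c_w_all": "c_w"})
    corr = feature_correlations(
        rate,
        {
            "haplotype_alleles": feats[["chromosome", "start", "end", "n_common_haplotypes"]],
            "gc": feats[["chromosome", "start", "end", "gc"]],
            "cpg": feats[["chromosome", "start", "end", "cpg_density"]],
        },
        cfg.chromosome_lengths_bp,
    )
    corr.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    print(corr.to_string(index=False))

    # inbreeding vs individual recombination
    keep = ld_prune(G)
    F = inbreeding_coefficient(G.subset_markers(keep)).set_index("individual")
    summary = pd.read_csv(MAPS / "parent_summary.tsv", sep="\t").set_index("parent")
    joined = summary.join(F["F"])
    r = joined[["grn", "F"]].corr().iloc[0, 1]
    joined.reset_index().to_csv(OUT / "inbreeding_vs_grn.tsv", sep="\t", index=False)
    print(f"LD pruning kept {keep.sum()}/{G.n_markers} markers; "
          f"corr(F, GRN) over parents = {r:.2f}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
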