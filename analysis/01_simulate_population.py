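"""Generate the synthetic layer-chicken cohort used by the whole analysis.

Two 60-Mb autosomes at 20 SNPs/Mb; 250 half-sib families (focal parents in
full-sib groups of four from a genotyped grandparent generation, so the
pedigree carries additive relationships); hotspot-structured crossover map
(10% of 0.5-Mb windows at 10x intensity, normalised); dams 10% hotter than
sires; heritable genome-wide recombination propensity (h2 = 0.17,
repeatability = 0.24 on the count scale) with one planted QTL; 0.1%
genotyping error.  Writes genotypes, pedigree and the full ground truth.
"""

from pathlib import Path

from recombscape import SimulationConfig, simulate_population
from recombscape.simulate import write_population

OUT = Path("results/simdata")

CFG = SimulationConfig(
    seed=1,
    chromosome_lengths_mb=(60.0, 60.0),
    markers_per_mb=20.0,
    n_families=250,
    offspring_per_family=4,
    family_size_distribution="shifted_poisson",
    dam_family_fraction=0.5,
    parent_full_sib_group=4,
    founder_pool_size=30,
    crossovers_per_chromosome=1.4,  # ~2.3 cM/Mb
    hotspot_fraction=0.10,
    hotspot_intensity_multiplier=10.0,
    sex_rate_multiplier=1.10,
    grn_h2=0.17,
    grn_repeatability=0.24,
    qtl=((600, 0.2),),  # one locus, +22% propensity per copy (e^0.2)
    genotyping_error_rate=0.001,
)


def main() -> None:
    G, ped, truth = simulate_population(CFG)
    OUT.mkdir(parents=True, exist_ok=True)
    write_population(G, ped, truth, OUT)
    CFG.to_yaml(OUT / "config.yaml")
    focal = truth.crossovers["parent"].str.match(r"P|GS|GD")
    n_meioses = len(ped[ped["sire"] != "0"]) * 2
    print(f"cohort: {G.n_individuals} birds, {G.n_markers} SNPs on {len(CFG.chromosomes)} autosomes")
    print(f"true crossovers recorded: {len(truth.crossovers)} over {n_meioses} meioses")
    print(f"expected events/meiosis (sire baseline): {CFG.expected_crossovers_per_meiosis:.2f}")
    print(f"planted QTL: marker column {CFG.qtl[0][0]} "
          f"({G.markers.loc[CFG.qtl[0][0], 'marker_id']}), effect {CFG.qtl[0][1]} per copy (log scale)")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
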