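"""SNP quality control and missing-genotype fill.

Applies the standard panel filters (call rate >= 0.95, MAF >= 0.025,
parent-offspring Mendelian inconsistency <= 0.05) and the deterministic
Mendelian/mean-dosage fill, then writes the cleaned panel.
"""

from pathlib import Path

from recombscape import fill_missing_genotypes, qc_filter_snps, read_genotypes, read_pedigree
from recombscape.genotype_io import write_genotypes

SIM = Path("results/simdata")
OUT = Path("results/qc")


def main() -> None:
    G = read_genotypes(SIM / "genotypes.ped")
    ped = read_pedigree(SIM / "pedigree.tsv")
    G_qc, report = qc_filter_snps(G, ped)
    G_filled = fill_missing_genotypes(G_qc, ped)
    OUT.mkdir(parents=True, exist_ok=True)
    write_genotypes(G_filled, OUT / "genotypes", dialect="matrix")
    report.to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    removed = report[report["removed"]]
    print(f"markers in: {G.n_markers}; removed: {len(removed)} "
          f"({dict(removed['reason'].value_counts())})")
    print(f"markers out: {G_filled.n_markers}; "
          f"missing calls filled: {(G_qc.calls == -1).sum()}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
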