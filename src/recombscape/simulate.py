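"""Synthetic half-sib populations with known crossovers.

The generator emulates a layer-chicken breeding design: many small half-sib
families whose focal parents (sires and dams) transmit gametes produced by a
Poisson crossover process on a hotspot-structured intensity map.  Founders
draw haplotypes from a finite pool, so pool size is the single knob for
line-level diversity/inbreeding.  Each parent carries a heritable
genome-wide recombination propensity (log-normal, additive genetic +
permanent environment) calibrated so that per-meiosis crossover counts show
a chosen narrow-sense heritability and repeatability; optional QTL act
log-additively on the propensity.

Everything downstream is tested against the returned :class:`TruthSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypeMatrix, MAP_COLUMNS, write_genotypes, write_pedigree

WINDOW_BP = 500_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic population.

    Rates are per meiosis; ``crossovers_per_chromosome`` is the expected
    crossover count per chromosome for a baseline (sire) meiosis.  Dams'
    meioses are multiplied by ``sex_rate_multiplier`` (female maps in layers
    run roughly 5-20% longer).  ``grn_h2``/``grn_repeatability`` calibrate
    the between-parent propensity variance on the crossover-count scale.
    """

    seed: int
    chromosome_lengths_mb: tuple[float, ...] = (100.0, 100.0)
    markers_per_mb: float = 20.0
    n_families: int = 50
    offspring_per_family: int = 4
    family_size_distribution: str = "fixed"  # "fixed" | "shifted_poisson"
    dam_family_fraction: float = 0.5
    parent_full_sib_group: int = 1  # > 1 adds a genotyped grandparent generation
    founder_pool_size: int = 30
    crossovers_per_chromosome: float = 2.0
    hotspot_fraction: float = 0.10
    hotspot_intensity_multiplier: float = 10.0
    normalize_intensity: bool = True
    sex_rate_multiplier: float = 1.1
    grn_h2: float = 0.17
    grn_repeatability: float = 0.24
    qtl: tuple[tuple[int, float], ...] = ()  # (marker column index, log-propensity effect/copy)
    genotyping_error_rate: float = 0.0
    allele_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.founder_pool_size < 2:
            raise ValueError("need at least one family and two founder haplotypes")
        if self.offspring_per_family < 1:
            raise ValueError("offspring_per_family must be positive")
        if min(self.chromosome_lengths_mb) <= 0 or self.markers_per_mb <= 0:
            raise ValueError("chromosome lengths and marker density must be positive")
        if self.crossovers_per_chromosome < 0 or self.hotspot_fraction < 0:
            raise ValueError("rates must be non-negative")
        if self.sex_rate_multiplier <= 0:
            raise ValueError("sex_rate_multiplier must be positive")
        if not (0.0 <= self.grn_h2 <= self.grn_repeatability <= 1.0):
            raise ValueError("need 0 <= grn_h2 <= grn_repeatability <= 1")
        if self.grn_repeatability >= 1.0 and self.grn_repeatability > 0:
            if self.grn_repeatability == 1.0:
                raise ValueError("grn_repeatability must be < 1")
        if not (0.0 <= self.genotyping_error_rate < 1.0):
            raise ValueError("genotyping_error_rate must be in [0, 1)")

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(len(self.chromosome_lengths_mb))]

    @property
    def chromosome_lengths_bp(self) -> dict[str, int]:
        return {
            c: int(round(l * 1e6))
            for c, l in zip(self.chromosomes, self.chromosome_lengths_mb)
        }

    @property
    def expected_crossovers_per_meiosis(self) -> float:
        """Baseline (sire) genome-wide expectation.  Exact when the
        intensity map is normalized (the default)."""
        base = self.crossovers_per_chromosome * len(self.chromosome_lengths_mb)
        if self.normalize_intensity:
            return base
        f, m = self.hotspot_fraction, self.hotspot_intensity_multiplier
        return base * (1.0 + f * (m - 1.0))

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["chromosome_lengths_mb"] = list(self.chromosome_lengths_mb)
        d["allele_freq_range"] = list(self.allele_freq_range)
        d["qtl"] = [list(q) for q in self.qtl]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["chromosome_lengths_mb"] = tuple(d["chromosome_lengths_mb"])
        d["allele_freq_range"] = tuple(d["allele_freq_range"])
        d["qtl"] = tuple(tuple(q) for q in d.get("qtl", []))
        return cls(**d)


@dataclass
class IntensityMap:
    """Piecewise-constant crossover intensity (per bp) per chromosome."""

    edges: dict[str, np.ndarray]  # bin edges in bp, 0-based
    rates: dict[str, np.ndarray]  # per-bp rate per bin

    def expected_count(self, chrom: str) -> float:
        return float(np.sum(self.rates[chrom] * np.diff(self.edges[chrom])))

    @property
    def expected_per_meiosis(self) -> float:
        return sum(self.expected_count(c) for c in self.edges)

    def window_table(self) -> pd.DataFrame:
        rows = []
        for chrom in self.edges:
            e, r = self.edges[chrom], self.rates[chrom]
            for k in range(len(r)):
                rows.append((chrom, int(e[k]), int(e[k + 1]), float(r[k])))
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "rate_per_bp"])


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    crossovers: pd.DataFrame  # parent, offspring, chromosome, position
    propensity: pd.DataFrame  # individual, g, pe, scale, expected_grn
    qtl: tuple[tuple[int, float], ...]
    intensity: IntensityMap
    haplotypes: np.ndarray  # (n_individuals, 2, n_markers) int8; [0]=from sire
    individuals: list[str]

    def haplotypes_of(self, individual: str) -> np.ndarray:
        return self.haplotypes[self.individuals.index(individual)]


def build_intensity_map(cfg: SimulationConfig, rng: np.random.Generator) -> IntensityMap:
    edges: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosome_lengths_bp.items():
        e = np.arange(0, length, WINDOW_BP, dtype=np.int64)
        e = np.append(e, length)
        k = len(e) - 1
        base = cfg.crossovers_per_chromosome / length
        r = np.full(k, base)
        n_hot = int(round(cfg.hotspot_fraction * k))
        if n_hot > 0 and cfg.hotspot_intensity_multiplier != 1.0:
            hot = rng.choice(k, size=n_hot, replace=False)
            r[hot] *= cfg.hotspot_intensity_multiplier
            if cfg.normalize_intensity:
                total = np.sum(r * np.diff(e))
                if total > 0:
                    r *= cfg.crossovers_per_chromosome / total
        edges[chrom] = e
        rates[chrom] = r
    return IntensityMap(edges, rates)


def simulate_meiosis(
    parent_haplotypes: np.ndarray,
    marker_positions: np.ndarray,
    edges: np.ndarray,
    rates: np.ndarray,
    propensity_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete for one chromosome.

    The crossover count is Poisson(propensity_scale x integral of intensity);
    positions are drawn proportional to the piecewise-constant intensity.
    The gamete alternates between the two parental haplotypes, starting from
    a fair-coin phase.  Returns (gamete dosage-alleles, crossover bp).
    """
    if propensity_scale <= 0:
        raise ValueError("propensity_scale must be positive")
    widths = np.diff(edges).astype(float)
    mass = rates * widths
    lam = propensity_scale * mass.sum()
    n_xo = rng.poisson(lam) if lam > 0 else 0
    if n_xo > 0:
        seg = rng.choice(len(mass), size=n_xo, p=mass / mass.sum())
        pos = edges[seg] + rng.random(n_xo) * widths[seg]
        pos = np.sort(pos.astype(np.int64))
    else:
        pos = np.empty(0, dtype=np.int64)
    phase0 = int(rng.integers(2))
    n_before = np.searchsorted(pos, marker_positions, side="left")
    origin = (phase0 + n_before) % 2
    gamete = parent_haplotypes[origin, np.arange(parent_haplotypes.shape[1])]
    return gamete.astype(np.int8), pos


def _propensity_log_variances(cfg: SimulationConfig) -> tuple[float, float]:
    """Log-scale additive and permanent-environment variances that give the
    configured count-scale h2 and repeatability.

    With mean genome-wide count mu and Poisson residual variance ~ mu, a
    between-parent variance V_b = t*mu/(1-t) yields repeatability t; the
    additive share is h2/t of V_b.  Small log-variances map to count-scale
    variances via Var(count) ~ mu^2 * Var(log scale)."""
    t, h2 = cfg.grn_repeatability, cfg.grn_h2
    if t == 0:
        return 0.0, 0.0
    mu = cfg.expected_crossovers_per_meiosis
    v_between = t * mu / (1.0 - t)
    v_a = v_between * (h2 / t)
    v_pe = v_between - v_a
    return v_a / mu**2, v_pe / mu**2


def assign_parent_propensity(
    ped: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    dosages: np.ndarray | None = None,
    individuals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-individual propensity scale = exp(g + pe - centering).

    Additive genetic values are transmitted parent -> offspring as
    mid-parent plus a Mendelian-segregation deviation of half the additive
    variance; QTL (if any) add ``effect * centered dosage`` to g."""
    var_g, var_pe = _propensity_log_variances(cfg)
    sd_g, sd_pe = np.sqrt(var_g), np.sqrt(var_pe)
    g: dict[str, float] = {}
    pe: dict[str, float] = {}
    for r in ped.itertuples():
        mid, n_known = 0.0, 0
        for p in (r.sire, r.dam):
            if p in g:
                mid += g[p]
                n_known += 1
        if n_known == 2:
            g[r.individual] = mid / 2.0 + rng.normal(0.0, sd_g * np.sqrt(0.5))
        else:
            g[r.individual] = rng.normal(0.0, sd_g)
        pe[r.individual] = rng.normal(0.0, sd_pe)
    ids = list(ped["individual"])
    g_arr = np.array([g[i] for i in ids])
    pe_arr = np.array([pe[i] for i in ids])
    if cfg.qtl and dosages is not None and individuals is not None:
        lookup = {ind: k for k, ind in enumerate(individuals)}
        rows = np.array([lookup[i] for i in ids])
        for marker_idx, effect in cfg.qtl:
            d = dosages[rows, marker_idx].astype(float)
            p_bar = float(dosages[:, marker_idx].mean()) / 2.0
            g_arr = g_arr + effect * (d - 2.0 * p_bar)
    scale = np.exp(g_arr + pe_arr - 0.5 * (var_g + var_pe))
    return pd.DataFrame({"individual": ids, "g": g_arr, "pe": pe_arr, "scale": scale})


def simulate_population(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthSet]:
    """Full synthetic cohort: genotypes, pedigree, and ground truth.

    Founders draw haplotypes from the pool; every non-founder genotype is
    the union of two simulated gametes, with all crossovers recorded.  With
    ``parent_full_sib_group`` > 1 the focal parents are produced in
    full-sib groups from a genotyped grandparent generation, giving the
    focal parents pedigree relationships (needed to separate additive and
    permanent-environment variance downstream).  Mates are drawn fresh per
    offspring, so each focal family is a pure half-sib family.
    Bit-reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = cfg.chromosome_lengths_bp

    # marker map
    marker_rows = []
    chrom_slices: dict[str, slice] = {}
    col = 0
    for chrom, length in chrom_lengths.items():
        m_c = max(2, int(round(length / 1e6 * cfg.markers_per_mb)))
        pos = np.unique(rng.integers(1, length + 1, size=2 * m_c))
        while pos.size < m_c:  # top up after collisions (rare at these densities)
            pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=m_c)]))
        pos = np.sort(rng.choice(pos, size=m_c, replace=False))
        for k, p in enumerate(pos):
            marker_rows.append((f"snp_{chrom}_{k:05d}", chrom, int(p)))
        chrom_slices[chrom] = slice(col, col + m_c)
        col += m_c
    markers = pd.DataFrame(marker_rows, columns=MAP_COLUMNS)
    m = len(markers)
    positions = markers["position"].to_numpy()

    # founder haplotype pool
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    pool = (rng.random((cfg.founder_pool_size, m)) < freqs).astype(np.int8)

    # pedigree structure
    n_dam_families = int(round(cfg.dam_family_fraction * cfg.n_families))
    focal_sexes = ["F"] * n_dam_families + ["M"] * (cfg.n_families - n_dam_families)
    if cfg.family_size_distribution == "fixed":
        fam_sizes = np.full(cfg.n_families, cfg.offspring_per_family)
    elif cfg.family_size_distribution == "shifted_poisson":
        fam_sizes = 2 + rng.poisson(max(cfg.offspring_per_family - 2, 0), cfg.n_families)
    else:
        raise ValueError(f"unknown family_size_distribution {cfg.family_size_distribution!r}")
    focal_ids = [f"P{k + 1:04d}" for k in range(cfg.n_families)]
    n_off_total = int(fam_sizes.sum())
    mate_ids = [f"Q{k + 1:04d}" for k in range(n_off_total)]
    off_ids = [f"O{k + 1:04d}" for k in range(n_off_total)]

    ped_rows = []
    matings = []  # (sire, dam, child) in generation order
    group = max(int(cfg.parent_full_sib_group), 1)
    grand_ids: list[str] = []
    if group > 1:
        n_couples = (cfg.n_families + group - 1) // group
        for c in range(n_couples):
            for gid, gsex in ((f"GS{c + 1:04d}", "M"), (f"GD{c + 1:04d}", "F")):
                grand_ids.append(gid)
                ped_rows.append((gid, "0", "0", gsex))
        for k, (pid, sex) in enumerate(zip(focal_ids, focal_sexes)):
            c = k // group
            ped_rows.append((pid, f"GS{c + 1:04d}", f"GD{c + 1:04d}", sex))
            matings.append((f"GS{c + 1:04d}", f"GD{c + 1:04d}", pid))
    else:
        for pid, sex in zip(focal_ids, focal_sexes):
            ped_rows.append((pid, "0", "0", sex))
    mate_sex = {}
    k = 0
    for fam, (pid, sex) in enumerate(zip(focal_ids, focal_sexes)):
        for _ in range(fam_sizes[fam]):
            mate = mate_ids[k]
            mate_sex[mate] = "M" if sex == "F" else "F"
            sire, dam = (pid, mate) if sex == "M" else (mate, pid)
            matings.append((sire, dam, off_ids[k]))
            k += 1
    for mate in mate_ids:
        ped_rows.append((mate, "0", "0", mate_sex[mate]))
    off_sex = {off: rng.choice(["M", "F"]) for off in off_ids}
    for sire, dam, child in matings:
        if child in off_sex:
            ped_rows.append((child, sire, dam, off_sex[child]))
    ped = pd.DataFrame(ped_rows, columns=["individual", "sire", "dam", "sex"])
    sex_of = dict(zip(ped["individual"], ped["sex"]))

    individuals = grand_ids + focal_ids + mate_ids + off_ids
    idx = {ind: i for i, ind in enumerate(individuals)}
    H = np.zeros((len(individuals), 2, m), dtype=np.int8)
    founders = grand_ids + mate_ids + ([] if grand_ids else focal_ids)
    for ind in founders:
        for h in range(2):
            for chrom in chrom_lengths:
                sl = chrom_slices[chrom]
                H[idx[ind], h, sl] = pool[rng.integers(cfg.founder_pool_size), sl]

    intensity = build_intensity_map(cfg, rng)
    var_g, var_pe = _propensity_log_variances(cfg)
    centering = 0.5 * (var_g + var_pe)
    p_bar = {j: None for j, _ in cfg.qtl}  # QTL allele freqs fixed from the pool

    def qtl_term(dosage_row: np.ndarray) -> float:
        out = 0.0
        for j, effect in cfg.qtl:
            if p_bar[j] is None:
                p_bar[j] = float(pool[:, j].mean())
            out += effect * (float(dosage_row[j]) - 2.0 * p_bar[j])
        return out

    g_val: dict[str, float] = {}
    scale: dict[str, float] = {}
    for ind in founders:
        g = rng.normal(0.0, np.sqrt(var_g)) if var_g > 0 else 0.0
        pe = rng.normal(0.0, np.sqrt(var_pe)) if var_pe > 0 else 0.0
        g += qtl_term(H[idx[ind]].sum(axis=0))
        g_val[ind] = g
        scale[ind] = float(np.exp(g + pe - centering))

    xo_rows = []
    for sire, dam, child in matings:
        row = idx[child]
        for parent in (sire, dam):
            is_dam = sex_of[parent] == "F"
            mult = cfg.sex_rate_multiplier if is_dam else 1.0
            for chrom in chrom_lengths:
                sl = chrom_slices[chrom]
                gamete, xo = simulate_meiosis(
                    H[idx[parent], :, sl],
                    positions[sl],
                    intensity.edges[chrom],
                    intensity.rates[chrom],
                    scale[parent] * mult,
                    rng,
                )
                H[row, 1 if is_dam else 0, sl] = gamete
                for p in xo:
                    xo_rows.append((parent, child, chrom, int(p)))
        g = 0.5 * (g_val[sire] + g_val[dam] - qtl_term(H[idx[sire]].sum(axis=0))
                   - qtl_term(H[idx[dam]].sum(axis=0)))
        if var_g > 0:
            g += rng.normal(0.0, np.sqrt(var_g * 0.5))
        pe = rng.normal(0.0, np.sqrt(var_pe)) if var_pe > 0 else 0.0
        g += qtl_term(H[row].sum(axis=0))
        g_val[child] = g
        scale[child] = float(np.exp(g + pe - centering))

    dosage = H.sum(axis=1).astype(np.int8)
    if cfg.genotyping_error_rate > 0:
        err = rng.random(dosage.shape) < cfg.genotyping_error_rate
        shift = rng.choice([-1, 1], size=dosage.shape)
        dosage = np.where(err, np.clip(dosage + shift, 0, 2), dosage).astype(np.int8)

    G = GenotypeMatrix(individuals, markers.copy(), dosage)
    mu = cfg.expected_crossovers_per_meiosis
    prop_all = pd.DataFrame(
        {
            "individual": individuals,
            "g": [g_val[i] for i in individuals],
            "scale": [scale[i] for i in individuals],
            "expected_grn": [
                scale[i] * mu * (cfg.sex_rate_multiplier if sex_of[i] == "F" else 1.0)
                for i in individuals
            ],
        }
    )
    truth = TruthSet(
        crossovers=pd.DataFrame(
            xo_rows, columns=["parent", "offspring", "chromosome", "position"]
        ),
        propensity=prop_all,
        qtl=cfg.qtl,
        intensity=intensity,
        haplotypes=H,
        individuals=individuals,
    )
    return G, ped, truth


def downsample_panel(
    G: GenotypeMatrix, keep_fraction: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Uniform random marker subset (exact count, order preserved)."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return G
    k = int(round(keep_fraction * G.n_markers))
    keep = np.sort(rng.choice(G.n_markers, size=k, replace=False))
    return G.subset_markers(keep)


def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.crossovers.to_csv(outdir / "true_crossovers.tsv", sep="\t", index=False)
    truth.propensity.to_csv(outdir / "true_propensity.tsv", sep="\t", index=False)
    truth.intensity.window_table().to_csv(outdir / "true_intensity.tsv", sep="\t", index=False)
    pd.DataFrame(list(truth.qtl), columns=["marker_index", "effect"]).to_csv(
        outdir / "true_qtl.tsv", sep="\t", index=False
    )


def write_population(
    G: GenotypeMatrix, ped: pd.DataFrame, truth: TruthSet, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(G, outdir / "genotypes", dialect="pedmap")
    write_pedigree(ped, outdir / "pedigree.tsv")
    write_truth(truth, outdir)
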