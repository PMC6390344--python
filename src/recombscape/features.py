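"""Window-level genomic covariates and genomic inbreeding.

Covers GC fraction and CpG-island density per 0.5-Mb window (from a FASTA
or a user BED), counts of common haplotype alleles, LD pruning, the
observed/expected-homozygosity inbreeding coefficient F, and the
correlation table relating window recombination rate to these features and
to chromosome size (macro GGA1-5 / intermediate GGA6-10 / micro GGA11-28
classes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, ParseError


def load_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def _as_sequences(fasta: str | Path | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(fasta, (str, Path)):
        return load_fasta(fasta)
    return fasta


def gc_content_windows(
    fasta: str | Path | Mapping[str, str], windows: pd.DataFrame
) -> pd.DataFrame:
    """GC fraction per window: (#G + #C) / (#A + #C + #G + #T); N bases are
    excluded from the denominator and all-N windows are missing."""
    seqs = {k: v.upper() for k, v in _as_sequences(fasta).items()}
    windows = windows.reset_index(drop=True)
    values = np.full(len(windows), np.nan)
    for chrom, grp in windows.groupby("chromosome", sort=False):
        if chrom not in seqs:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        arr = np.frombuffer(seqs[chrom].encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
        cum_n = np.concatenate([[0], np.cumsum(is_acgt)])
        for i, (s, e) in enumerate(zip(grp["start"], grp["end"])):
            denom = cum_n[e] - cum_n[s]
            if denom > 0:
                values[grp.index[i]] = (cum_gc[e] - cum_gc[s]) / denom
    out = windows.copy()
    out["gc"] = values
    return out


def cpg_island_scan(
    sequence: str, min_length: int = 200, gc_min: float = 0.5, oe_min: float = 0.6
) -> list[tuple[int, int]]:
    """Classical three-criteria CpG-island scan: merge all 200-bp windows
    with GC >= 0.5 and observed/expected CpG >= 0.6 into islands."""
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    if n < min_length:
        return []
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, n - min_length + 1)
    ends = starts + min_length
    c = cum_c[ends] - cum_c[starts]
    g = cum_g[ends] - cum_g[starts]
    cpg = cum_cpg[ends] - cum_cpg[starts]
    gc_frac = (c + g) / min_length
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(c * g > 0, cpg * min_length / np.maximum(c * g, 1), 0.0)
    ok = (gc_frac >= gc_min) & (oe >= oe_min)
    islands: list[tuple[int, int]] = []
    for s in np.flatnonzero(ok):
        e = s + min_length
        if islands and s <= islands[-1][1]:
            islands[-1] = (islands[-1][0], e)
        else:
            islands.append((s, e))
    return islands


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: BED needs >= 3 columns")
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad BED coordinates") from exc
        if e <= s:
            raise ParseError(f"{path}:{ln}: BED end must exceed start")
        rows.append((parts[0], s, e))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def cpg_density_windows(
    islands: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of each window covered by CpG islands (BED-style 0-based
    half-open intervals)."""
    windows = windows.reset_index(drop=True)
    out = windows.copy()
    values = np.zeros(len(windows))
    for chrom, grp in windows.groupby("chromosome", sort=False):
        isl = islands[islands["chromosome"] == chrom]
        if len(isl) == 0:
            continue
        s_arr = isl["start"].to_numpy()
        e_arr = isl["end"].to_numpy()
        for i, (s, e) in enumerate(zip(grp["start"], grp["end"])):
            ov = np.minimum(e_arr, e) - np.maximum(s_arr, s)
            values[grp.index[i]] = float(np.clip(ov, 0, None).sum()) / (e - s)
    out["cpg_density"] = values
    return out


def common_haplotype_alleles(
    haplotypes: np.ndarray,
    markers: pd.DataFrame,
    windows: pd.DataFrame,
    min_freq: float = 0.01,
) -> pd.DataFrame:
    """Number of distinct haplotype alleles at frequency >= ``min_freq`` in
    each window, counted over the marker string spanned by the window.
    Windows without markers are missing."""
    haplotypes = np.asarray(haplotypes)
    windows = windows.reset_index(drop=True)
    n_hap = haplotypes.shape[0]
    values = np.full(len(windows), np.nan)
    chrom_col = markers["chromosome"].to_numpy()
    pos_col = markers["position"].to_numpy()
    for chrom, grp in windows.groupby("chromosome", sort=False):
        cols = np.flatnonzero(chrom_col == chrom)
        pos0 = pos_col[cols] - 1  # to 0-based for window comparison
        for i, (s, e) in enumerate(zip(grp["start"], grp["end"])):
            sel = cols[(pos0 >= s) & (pos0 < e)]
            if sel.size == 0:
                continue
            _, counts = np.unique(haplotypes[:, sel], axis=0, return_counts=True)
            values[grp.index[i]] = int(np.sum(counts / n_hap >= min_freq))
    out = windows.copy()
    out["n_common_haplotypes"] = values
    return out


def ld_prune(
    G: GenotypeMatrix, r2_max: float = 0.5, block: int = 50
) -> np.ndarray:
    """Greedy within-block LD pruning.

    Within each non-overlapping ``block``-marker window, pairs are scanned
    in map order; when dosage r^2 exceeds ``r2_max`` the lower-MAF member is
    dropped (ties: the later position).  Monomorphic markers are never
    tested and always retained.  Returns a boolean keep mask."""
    keep = np.ones(G.n_markers, dtype=bool)
    maf = G.maf()
    calls = G.calls.astype(float)
    calls[calls == MISSING] = np.nan
    for b0 in range(0, G.n_markers, block):
        cols = np.arange(b0, min(b0 + block, G.n_markers))
        sub = pd.DataFrame(calls[:, cols])
        std = sub.std(skipna=True)
        poly = std.to_numpy() > 0
        r = sub.corr().to_numpy()  # pairwise-complete Pearson
        for a in range(len(cols)):
            if not keep[cols[a]] or not poly[a]:
                continue
            for bb in range(a + 1, len(cols)):
                if not keep[cols[bb]] or not poly[bb]:
                    continue
                r2 = r[a, bb] ** 2
                if np.isnan(r2) or r2 <= r2_max:
                    continue
                drop = cols[bb] if maf[cols[bb]] <= maf[cols[a]] else cols[a]
                keep[drop] = False
                if drop == cols[a]:
                    break
    return keep


def inbreeding_coefficient(G: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments F from observed vs HWE-expected homozygote counts.

    Per marker the expected heterozygosity uses the small-sample correction
    2 p (1-p) n/(n-1) with cohort allele frequencies; per individual
    F = (O - E)/(L - E) over that individual's non-missing markers."""
    calls = G.calls
    obs_mask = calls != MISSING
    n_j = obs_mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_j > 0, np.where(obs_mask, calls, 0).sum(axis=0) / (2 * n_j), np.nan)
        corr = np.where(n_j > 1, n_j / (n_j - 1.0), 1.0)
    exp_het = 2.0 * p * (1.0 - p) * corr
    exp_hom = 1.0 - exp_het
    hom = obs_mask & (calls != 1)
    rows = []
    for i, ind in enumerate(G.individuals):
        mask = obs_mask[i]
        L = int(mask.sum())
        O = int(hom[i].sum())
        E = float(exp_hom[mask].sum())
        denom = L - E
        F = (O - E) / denom if abs(denom) > 1e-12 else np.nan
        rows.append((ind, O, E, L, F))
    return pd.DataFrame(rows, columns=["individual", "O", "E", "L", "F"])


_CHROM_CLASSES = (("macro", 1, 5), ("intermediate", 6, 10), ("micro", 11, 28))


def chromosome_class(chrom: str) -> str | None:
    if not str(chrom).isdigit():
        return None
    c = int(chrom)
    for name, lo, hi in _CHROM_CLASSES:
        if lo <= c <= hi:
            return name
    return None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan
    return float(stats.pearsonr(x[ok], y[ok])[0])


def feature_correlations(
    rate_track: pd.DataFrame,
    feature_tracks: Mapping[str, pd.DataFrame],
    chromosome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Correlation table: windowwise rate vs each feature (pooled across
    chromosomes), per-chromosome mean rate vs chromosome length, and mean
    rate per chromosome size class."""
    rate = rate_track["c_w"].to_numpy(dtype=float)
    rows = []
    for name, track in feature_tracks.items():
        value_col = [c for c in track.columns if c not in ("chromosome", "start", "end", "covered")][-1]
        if len(track) != len(rate_track):
            raise ValueError(f"feature track {name!r} not aligned with rate track")
        rows.append((f"rate_vs_{name}", _pearson(rate, track[value_col].to_numpy(dtype=float))))
    per_chrom = rate_track.groupby("chromosome")["c_w"].mean()
    lengths = np.array([chromosome_lengths[c] for c in per_chrom.index], dtype=float)
    rows.append(("mean_rate_vs_chromosome_length", _pearson(per_chrom.to_numpy(), lengths)))
    out = pd.DataFrame(rows, columns=["pair", "pearson_r"])
    classes = rate_track["chromosome"].map(chromosome_class)
    class_means = rate_track.groupby(classes)["c_w"].mean()
    for name, _, _ in _CHROM_CLASSES:
        if name in class_means.index:
            out.loc[len(out)] = (f"mean_rate_{name}", float(class_means[name]))
    return out
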