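"""Genotype, marker-map and pedigree I/O plus SNP quality control.

Genotypes are held as allele-dosage codes 0/1/2 with ``-1`` for missing,
together with a physical marker map (1-based base-pair positions).  Two file
dialects are supported: PLINK-style ``.ped``/``.map`` pairs and a simple
dosage-matrix + map TSV pair.  The QC step applies the standard panel
filters for half-sib recombination studies: call rate, minor allele
frequency and per-marker Mendelian inconsistency over genotyped
parent-offspring pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

MAP_COLUMNS = ["marker_id", "chromosome", "position"]
PED_COLUMNS = ["individual", "sire", "dam", "sex"]

_UNKNOWN_PARENT = {"0", "", ".", "-", "na", "nan", "none"}
_SEX_CODES = {
    "m": "M", "1": "M", "male": "M", "sire": "M",
    "f": "F", "2": "F", "female": "F", "dam": "F",
}


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Autosomes in numeric order, then named chromosomes (e.g. Z)."""
    c = str(chrom)
    if c.isdigit():
        return (0, int(c))
    return (1, c)


def sort_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    key = markers["chromosome"].map(_chrom_sort_key)
    order = sorted(range(len(markers)), key=lambda i: (key.iat[i], markers["position"].iat[i]))
    out = markers.iloc[order].reset_index(drop=True)
    out["input_index"] = order
    return out


def validate_marker_map(markers: pd.DataFrame) -> None:
    if markers["marker_id"].duplicated().any():
        dup = markers["marker_id"][markers["marker_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate marker id {dup!r}")
    for chrom, grp in markers.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ParseError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with its marker map.

    ``calls`` is int8 with values in {0, 1, 2, -1}; rows follow
    ``individuals`` and columns follow ``markers`` (sorted by chromosome
    then position).
    """

    individuals: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("calls shape inconsistent with individuals/markers")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be 0, 1, 2 or -1 (missing)")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            raise ValueError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self._index[individual]]

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        markers = self.markers.iloc[keep].reset_index(drop=True)
        return GenotypeMatrix(list(self.individuals), markers, self.calls[:, keep])

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the dosage-counted allele (ignoring missing)."""
        calls = self.calls.astype(float)
        calls[calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)


@dataclass(frozen=True)
class HalfSibFamily:
    """Offspring sharing one genotyped focal parent."""

    focal_parent: str
    focal_sex: str  # "sire" or "dam"
    pairs: tuple[tuple[str, str | None], ...]  # (offspring, other parent or None)

    @property
    def offspring(self) -> list[str]:
        return [o for o, _ in self.pairs]

    @property
    def n_offspring(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) == 4:  # PLINK: chrom, id, cM, bp
            chrom, mid, _, pos = parts
        elif len(parts) == 3:  # chrom, id, bp
            chrom, mid, pos = parts
        else:
            raise ParseError(f"{path}:{ln}: expected 3 or 4 columns, got {len(parts)}")
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad position {pos!r}") from exc
        rows.append((mid, str(chrom), pos_i))
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def read_genotypes(path: str | Path, dialect: str = "pedmap") -> GenotypeMatrix:
    """Read genotypes; markers are returned sorted by (chromosome, position).

    ``dialect="pedmap"``: PLINK whitespace ped/map, two allele columns per
    marker, "0" for a missing allele; dosage counts the lexicographically
    larger of the two alleles seen at the marker.
    ``dialect="matrix"``: ``<prefix>.geno.tsv`` (individual + dosage columns)
    and ``<prefix>.map.tsv`` (marker_id, chromosome, position with header).
    """
    path = Path(path)
    if dialect == "pedmap":
        return _read_pedmap(path)
    if dialect == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_pedmap(path: Path) -> GenotypeMatrix:
    prefix = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
    markers = _read_map(prefix.with_suffix(".map"))
    m = len(markers)
    individuals: list[str] = []
    allele_rows: list[np.ndarray] = []
    ped_path = prefix.with_suffix(".ped")
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} markers, got {len(parts)}"
            )
        individuals.append(parts[1])
        allele_rows.append(np.array(parts[6:], dtype=object))
    alleles = np.array(allele_rows, dtype=object) if allele_rows else np.empty((0, 2 * m), object)
    calls = np.full((len(individuals), m), MISSING, dtype=np.int8)
    for j in range(m):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        seen = sorted({a for a in np.concatenate([a1, a2]) if a != "0"})
        if len(seen) > 2:
            raise ParseError(f"marker {markers['marker_id'][j]!r} has >2 alleles: {seen}")
        counted = seen[-1] if seen else None  # lexicographically larger allele
        ok = (a1 != "0") & (a2 != "0")
        if counted is not None:
            calls[ok, j] = (a1[ok] == counted).astype(np.int8) + (a2[ok] == counted).astype(np.int8)
    order = sort_marker_map(pd.DataFrame(markers))
    validate_marker_map(order)
    return GenotypeMatrix(individuals, order, calls[:, order["input_index"].to_numpy()])


def _read_matrix(path: Path) -> GenotypeMatrix:
    prefix = Path(str(path).replace(".geno.tsv", "").replace(".map.tsv", ""))
    markers = pd.read_csv(f"{prefix}.map.tsv", sep="\t", dtype={"chromosome": str})
    if list(markers.columns[:3]) != MAP_COLUMNS:
        raise ParseError(f"{prefix}.map.tsv: expected columns {MAP_COLUMNS}")
    geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", index_col=0)
    if list(geno.columns) != list(markers["marker_id"]):
        raise ParseError("genotype columns do not match map marker ids")
    calls = geno.to_numpy()
    calls = np.where(np.isnan(calls.astype(float)), MISSING, calls).astype(np.int8)
    order = sort_marker_map(markers[MAP_COLUMNS])
    validate_marker_map(order)
    return GenotypeMatrix(
        [str(i) for i in geno.index], order, calls[:, order["input_index"].to_numpy()]
    )


def write_genotypes(G: GenotypeMatrix, prefix: str | Path, dialect: str = "matrix") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "matrix":
        G.markers[MAP_COLUMNS].to_csv(f"{prefix}.map.tsv", sep="\t", index=False)
        df = pd.DataFrame(
            np.where(G.calls == MISSING, np.nan, G.calls),
            index=G.individuals,
            columns=G.markers["marker_id"],
        )
        df.to_csv(f"{prefix}.geno.tsv", sep="\t", float_format="%.0f")
    elif dialect == "pedmap":
        with open(f"{prefix}.map", "w") as fh:
            for _, r in G.markers.iterrows():
                fh.write(f"{r['chromosome']}\t{r['marker_id']}\t0\t{r['position']}\n")
        code = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}
        with open(f"{prefix}.ped", "w") as fh:
            for i, ind in enumerate(G.individuals):
                geno = " ".join(code[int(c)] for c in G.calls[i])
                fh.write(f"0 {ind} 0 0 0 -9 {geno}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a pedigree table (individual, sire, dam, sex) and sort topologically.

    Unknown parents are normalised to "0".  Raises on cycles (listing the
    cycle) and on unrecognised sex codes.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if not set(PED_COLUMNS) <= set(c.lower() for c in df.columns):
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None)
        if df.shape[1] < 4:
            raise ParseError(f"{path}: expected 4 pedigree columns")
        df.columns = PED_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 4)]
    else:
        df.columns = [c.lower() for c in df.columns]
    df = df[PED_COLUMNS].copy()
    for col in ("sire", "dam"):
        df[col] = df[col].fillna("0").map(
            lambda s: "0" if str(s).strip().lower() in _UNKNOWN_PARENT else str(s).strip()
        )
    sexes = []
    for raw in df["sex"]:
        key = str(raw).strip().lower()
        if key not in _SEX_CODES:
            raise ParseError(f"unknown sex code {raw!r}")
        sexes.append(_SEX_CODES[key])
    df["sex"] = sexes
    df["individual"] = df["individual"].astype(str)
    return topological_sort_pedigree(df)


def topological_sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    ids = list(ped["individual"])
    if len(set(ids)) != len(ids):
        raise ParseError("duplicate individual ids in pedigree")
    known = set(ids)
    parents = {
        r.individual: [p for p in (r.sire, r.dam) if p != "0" and p in known]
        for r in ped.itertuples()
    }
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str, stack: list[str]) -> None:
        state[node] = 1
        stack.append(node)
        for p in parents[node]:
            s = state.get(p, 0)
            if s == 1:
                cyc = stack[stack.index(p):] + [p]
                raise ParseError(f"pedigree cycle: {' -> '.join(cyc)}")
            if s == 0:
                visit(p, stack)
        stack.pop()
        state[node] = 2
        order.append(node)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * len(ids) + 100))
    try:
        for node in ids:
            if state.get(node, 0) == 0:
                visit(node, [])
    finally:
        sys.setrecursionlimit(old_limit)
    return ped.set_index("individual").loc[order].reset_index()


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ped[PED_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def parent_offspring_links(
    ped: pd.DataFrame, genotyped: Iterable[str]
) -> list[tuple[str, str, str]]:
    """(parent, offspring, role) links where both members are genotyped."""
    gset = set(genotyped)
    links = []
    for r in ped.itertuples():
        if r.individual not in gset:
            continue
        if r.sire != "0" and r.sire in gset:
            links.append((r.sire, r.individual, "sire"))
        if r.dam != "0" and r.dam in gset:
            links.append((r.dam, r.individual, "dam"))
    return links


def mendelian_inconsistency_rate(G: GenotypeMatrix, ped: pd.DataFrame) -> np.ndarray:
    """Per-marker fraction of genotyped parent-offspring pairs with an
    impossible dosage combination (0 vs 2).  NaN where no pair is scored."""
    links = parent_offspring_links(ped, G.individuals)
    if not links:
        return np.full(G.n_markers, np.nan)
    p_idx = np.array([G.index_of(p) for p, _, _ in links])
    o_idx = np.array([G.index_of(o) for _, o, _ in links])
    P = G.calls[p_idx]
    O = G.calls[o_idx]
    scored = (P != MISSING) & (O != MISSING)
    impossible = scored & (((P == 0) & (O == 2)) | ((P == 2) & (O == 0)))
    n_scored = scored.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = impossible.sum(axis=0) / n_scored
    rate[n_scored == 0] = np.nan
    return rate


def qc_filter_snps(
    G: GenotypeMatrix,
    ped: pd.DataFrame | None,
    call_rate_min: float = 0.95,
    maf_min: float = 0.025,
    mendel_max: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove markers failing call-rate, MAF or Mendelian-inconsistency rules.

    Returns the filtered matrix and a per-marker report with the metrics and
    the removal reasons.  Markers with no scored parent-offspring pair skip
    the Mendelian rule (reported as ``mendel_rate`` NaN).
    """
    call_rate = G.call_rate()
    maf = G.maf()
    if ped is not None:
        mendel = mendelian_inconsistency_rate(G, ped)
    else:
        mendel = np.full(G.n_markers, np.nan)
    reasons = []
    for j in range(G.n_markers):
        why = []
        if call_rate[j] < call_rate_min:
            why.append("call_rate")
        if np.isnan(maf[j]) or maf[j] < maf_min:
            why.append("maf")
        if not np.isnan(mendel[j]) and mendel[j] > mendel_max:
            why.append("mendel")
        reasons.append(",".join(why))
    report = pd.DataFrame(
        {
            "marker_id": G.markers["marker_id"],
            "chromosome": G.markers["chromosome"],
            "call_rate": call_rate,
            "maf": maf,
            "mendel_rate": mendel,
            "removed": [bool(r) for r in reasons],
            "reason": reasons,
        }
    )
    keep = ~report["removed"].to_numpy()
    return G.subset_markers(keep), report


def build_half_sib_families(
    ped: pd.DataFrame, genotyped: Iterable[str], min_offspring: int = 2
) -> list[HalfSibFamily]:
    """One family per genotyped parent with >= ``min_offspring`` genotyped
    offspring.  An offspring with both parents genotyped appears in both the
    sire's and the dam's family."""
    gset = set(genotyped)
    by_parent: dict[tuple[str, str], list[tuple[str, str | None]]] = {}
    for r in ped.itertuples():
        if r.individual not in gset:
            continue
        for parent, role, other in ((r.sire, "sire", r.dam), (r.dam, "dam", r.sire)):
            if parent != "0" and parent in gset:
                mate = other if other != "0" and other in gset else None
                by_parent.setdefault((parent, role), []).append((r.individual, mate))
    families = [
        HalfSibFamily(parent, role, tuple(pairs))
        for (parent, role), pairs in by_parent.items()
        if len(pairs) >= min_offspring
    ]
    families.sort(key=lambda f: (f.focal_parent, f.focal_sex))
    return families


_TRANSMITTABLE = {0: {0}, 1: {0, 1}, 2: {1}}


def fill_missing_genotypes(G: GenotypeMatrix, ped: pd.DataFrame) -> GenotypeMatrix:
    """Fill missing calls: Mendelian-forced value where unique, else the
    rounded marker mean dosage.  Non-missing calls are never altered."""
    frac_missing = float((G.calls == MISSING).mean())
    if frac_missing > 0.01:
        warnings.warn(f"{frac_missing:.1%} missing genotypes; fill rule designed for sparse gaps")
    if frac_missing == 0.0:
        return G
    calls = G.calls.copy()
    mean_dosage = G.allele_frequency() * 2.0
    parents_of = {r.individual: (r.sire, r.dam) for r in ped.itertuples()}
    children_of: dict[str, list[str]] = {}
    for r in ped.itertuples():
        for p in (r.sire, r.dam):
            if p != "0":
                children_of.setdefault(p, []).append(r.individual)
    rows, cols = np.nonzero(G.calls == MISSING)
    for i, j in zip(rows, cols):
        ind = G.individuals[i]
        possible = {0, 1, 2}
        # constraints from this individual's genotyped parents
        sire, dam = parents_of.get(ind, ("0", "0"))
        pg = [
            calls[G.index_of(p), j]
            for p in (sire, dam)
            if p != "0" and p in G and calls[G.index_of(p), j] != MISSING
        ]
        if len(pg) == 2:
            possible &= {a + b for a in _TRANSMITTABLE[pg[0]] for b in _TRANSMITTABLE[pg[1]]}
        elif len(pg) == 1:
            possible &= {a + b for a in _TRANSMITTABLE[pg[0]] for b in (0, 1)}
        # constraints from genotyped offspring (what must this parent carry?)
        for child in children_of.get(ind, []):
            if child not in G:
                continue
            cg = calls[G.index_of(child), j]
            if cg == MISSING:
                continue
            c_sire, c_dam = parents_of[child]
            other = c_dam if c_sire == ind else c_sire
            og = (
                calls[G.index_of(other), j]
                if other != "0" and other in G and calls[G.index_of(other), j] != MISSING
                else None
            )
            other_alleles = _TRANSMITTABLE[og] if og is not None else {0, 1}
            needed = {cg - a for a in other_alleles} & {0, 1}
            # the focal individual must carry at least one allele in `needed`
            ok = {g for g in possible if _TRANSMITTABLE[g] & needed}
            if ok:
                possible = ok
        if len(possible) == 1:
            calls[i, j] = possible.pop()
        else:
            calls[i, j] = int(np.floor(mean_dosage[j] + 0.5)) if not np.isnan(mean_dosage[j]) else 1
    return GenotypeMatrix(list(G.individuals), G.markers.copy(), calls)


def autosomal_marker_mask(markers: pd.DataFrame) -> np.ndarray:
    """Markers on numeric (autosomal) chromosomes; Z etc. are flagged False."""
    return markers["chromosome"].astype(str).str.isdigit().to_numpy()
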