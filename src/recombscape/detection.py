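"""Crossover detection within half-sib families.

For each family the focal parent's transmitted allele is deduced at every
marker where the parent is heterozygous (Mendelian deduction from the
offspring and the other parent), the parent's chromosome-wide phase is then
reconstructed by minimum-recombinant majority voting over the family, and
each offspring's grand-parental origin sequence is decoded into crossover
intervals with a two-state hidden-path model that absorbs isolated
single-marker flips.  A map-confidence scan flags markers whose origin
pattern looks like a map error (systematic singleton flips or Mendelian
errors) and detection is re-run once without them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    HalfSibFamily,
    autosomal_marker_mask,
    build_half_sib_families,
    mendelian_inconsistency_rate,
)

UNKNOWN = -1


@dataclass
class OriginSequence:
    """Per-offspring grand-parental origin codes at informative markers."""

    parent: str
    offspring: str
    chromosome: str
    marker_index: np.ndarray  # global column indices into the genotype matrix
    positions: np.ndarray  # bp
    codes: np.ndarray  # int8: 0 = hapA, 1 = hapB, -1 = unknown
    segments: np.ndarray | None = None  # phase-segment id per marker
    deduced: np.ndarray | None = None  # transmitted allele deduced (pre-phasing)


@dataclass(frozen=True)
class RecombinationInterval:
    parent: str
    offspring: str
    chromosome: str
    left_pos: int
    right_pos: int

    @property
    def r_mb(self) -> float:
        return (self.right_pos - self.left_pos) / 1e6


@dataclass
class DetectionResult:
    intervals: pd.DataFrame  # parent, offspring, chromosome, left_pos, right_pos, r_mb, parent_sex
    pairs: pd.DataFrame  # parent, offspring, sex -- every meiosis, incl. zero events
    sequences: list[OriginSequence]
    marker_confidence: pd.DataFrame
    removed_markers: list[str]


def transmitted_alleles(
    focal: np.ndarray, offspring: np.ndarray, mate: np.ndarray | None
) -> np.ndarray:
    """Transmitted-allele codes at focal-heterozygous markers.

    1 means the focal parent transmitted the dosage-counted allele, 0 the
    other allele, -1 undeducible.  ``mate`` may be None (ungenotyped)."""
    t = np.full(offspring.shape, UNKNOWN, dtype=np.int8)
    het = focal == 1
    t[het & (offspring == 2)] = 1
    t[het & (offspring == 0)] = 0
    amb = het & (offspring == 1)
    if mate is not None:
        t[amb & (mate == 0)] = 1
        t[amb & (mate == 2)] = 0
    return t


def phase_transmissions(
    t_mat: np.ndarray, max_block: int = 40
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-recombinant phase of the focal parent over informative markers.

    ``t_mat`` is (n_offspring, n_markers) with codes {0, 1, -1}.  Returns
    (phase, reliable, segment): a 0/1 phase vector (phase[j] = haplotype
    label carrying the counted allele at marker j), a reliability mask, and
    a phase-segment id per marker (origin codes are only comparable within
    a segment; the global hapA/hapB swap per segment is unobservable).

    Markers are consumed left to right through an exact dynamic programme
    over offspring origin-state vectors: each marker's phase choice updates
    the origins of the offspring deduced there, at a cost of one per
    implied crossover.  A block of markers is committed as soon as a unique
    minimum-cost final state leads the runner-up by two or more crossovers;
    markers whose phase differs among co-optimal paths to that state (the
    exact position of a switch is then ambiguous) stay unreliable, so the
    crossover is localised between the flanking reliable markers.  A block
    that hits ``max_block`` with tied optima is resolved arbitrarily when
    the tie involves at most two offspring (a two-offspring family only
    identifies the parent-level event, not which offspring recombined) and
    otherwise starts a fresh phase segment: two offspring recombining in
    the same uninformative gap are genuinely unidentifiable from half-sib
    data.  Exact minimisation when every offspring is deduced at every
    marker."""
    n_off, n_mark = t_mat.shape
    phase = np.zeros(n_mark, dtype=np.int8)
    reliable = np.zeros(n_mark, dtype=bool)
    segment = np.zeros(n_mark, dtype=np.int32)

    kmask_col = np.zeros(n_mark, dtype=np.int64)
    tbits_col = np.zeros(n_mark, dtype=np.int64)
    for o in range(n_off):
        bit = 1 << o
        row = t_mat[o]
        kmask_col[row != UNKNOWN] |= bit
        tbits_col[row == 1] |= bit

    seg = 0
    cur = (0, 0)  # (known mask, origin bits)
    dp: dict[tuple[int, int], int] = {cur: 0}
    # per pending marker: {new_state: (cost, [(prev_state, phi), ...])}
    hist: list[dict] = []
    pending: list[int] = []

    def backtrack_commit(target: tuple[int, int]) -> None:
        """Fix phases along co-optimal paths to ``target``; markers with a
        unique phase become reliable."""
        nonlocal dp, hist, pending, cur
        states = {target}
        phis: list[set[int]] = []
        for entry in reversed(hist):
            prev_states: set[tuple[int, int]] = set()
            phi_set: set[int] = set()
            for st in states:
                for prev, phi in entry[st][1]:
                    prev_states.add(prev)
                    phi_set.add(phi)
            phis.append(phi_set)
            states = prev_states
        for j, phi_set in zip(pending, reversed(phis)):
            if len(phi_set) == 1:
                phase[j] = phi_set.pop()
                reliable[j] = True
        cur = target
        dp = {cur: 0}
        hist = []
        pending = []

    def tie_width(best: list[tuple[tuple[int, int], int]]) -> int:
        differ = 0
        for (m1, v1), _ in best:
            for (m2, v2), _ in best:
                differ |= (v1 ^ v2) | (m1 ^ m2)
        return bin(differ).count("1")

    j = 0
    last_replay = -1
    while j < n_mark:
        segment[j] = seg
        kmask = int(kmask_col[j])
        if kmask == 0:
            j += 1
            continue
        tbits = int(tbits_col[j])
        new_dp: dict[tuple[int, int], int] = {}
        back: dict[tuple[int, int], tuple[int, list]] = {}
        for (m, v), c in dp.items():
            phis = (0,) if m == 0 else (0, 1)  # gauge fixed at segment start
            for phi in phis:
                newbits = (tbits ^ (kmask if phi else 0)) & kmask
                cost = c + bin(m & kmask & (v ^ newbits)).count("1")
                st = (m | kmask, (v & ~kmask) | newbits)
                old = new_dp.get(st)
                if old is None or cost < old:
                    new_dp[st] = cost
                    back[st] = (cost, [((m, v), phi)])
                elif cost == old:
                    back[st][1].append(((m, v), phi))
        best_cost = min(new_dp.values())
        dp = {st: c for st, c in new_dp.items() if c <= best_cost + 2}
        hist.append({st: back[st] for st in dp})
        pending.append(j)
        ranked = sorted(dp.items(), key=lambda kv: kv[1])
        if len(ranked) == 1 or ranked[1][1] >= ranked[0][1] + 2:
            backtrack_commit(ranked[0][0])
        elif len(pending) >= max_block:
            best = [kv for kv in ranked if kv[1] == best_cost]
            if tie_width(best) <= 2:
                backtrack_commit(best[0][0])  # parent-level event; arbitrary offspring
            else:
                # Unidentifiable multi-offspring knot: abandon it and replay
                # the blocked markers in a fresh phase segment so events
                # downstream of the knot are still recovered.
                replay_from = pending[1] if pending[0] == last_replay else pending[0]
                last_replay = replay_from
                cur = (0, 0)
                dp = {cur: 0}
                hist = []
                pending = []
                seg += 1
                j = replay_from
                continue
        j += 1
    if pending:
        ranked = sorted(dp.items(), key=lambda kv: kv[1])
        best = [kv for kv in ranked if kv[1] == ranked[0][1]]
        if len(best) == 1 or tie_width(best) <= 2:
            backtrack_commit(best[0][0])
    return phase, reliable, segment


def infer_transmitted_alleles(
    family: HalfSibFamily, G: GenotypeMatrix, chromosomes: list[str] | None = None
) -> list[OriginSequence]:
    """Origin sequences for every offspring of a half-sib family.

    Stage 1 deduces transmitted alleles per focal-heterozygous marker;
    stage 2 phases the focal parent by minimum-recombinant majority vote."""
    if family.n_offspring < 2:
        raise ValueError("half-sib family needs at least two offspring")
    if chromosomes is None:
        mask = autosomal_marker_mask(G.markers)
        chromosomes = list(dict.fromkeys(G.markers.loc[mask, "chromosome"]))
    focal_row = G.row(family.focal_parent)
    chrom_col = G.markers["chromosome"].to_numpy()
    pos_col = G.markers["position"].to_numpy()
    sequences: list[OriginSequence] = []
    for chrom in chromosomes:
        cols = np.flatnonzero(chrom_col == chrom)
        inf = cols[focal_row[cols] == 1]
        if inf.size == 0:
            for off, _ in family.pairs:
                sequences.append(
                    OriginSequence(
                        family.focal_parent, off, chrom,
                        inf, pos_col[inf], np.empty(0, dtype=np.int8),
                        np.empty(0, dtype=np.int32), np.empty(0, dtype=bool),
                    )
                )
            continue
        t_mat = np.empty((family.n_offspring, inf.size), dtype=np.int8)
        for k, (off, mate) in enumerate(family.pairs):
            mate_row = G.row(mate)[inf] if mate is not None and mate in G else None
            t_mat[k] = transmitted_alleles(focal_row[inf], G.row(off)[inf], mate_row)
        phase, reliable, segs = phase_transmissions(t_mat)
        for k, (off, _) in enumerate(family.pairs):
            usable = (t_mat[k] != UNKNOWN) & reliable
            codes = np.where(usable, t_mat[k] ^ phase, UNKNOWN).astype(np.int8)
            sequences.append(
                OriginSequence(
                    family.focal_parent, off, chrom, inf, pos_col[inf], codes, segs,
                    t_mat[k] != UNKNOWN,
                )
            )
    return sequences


def _viterbi_two_state(
    obs: np.ndarray, positions: np.ndarray, miscode: float, cm_per_mb: float
) -> np.ndarray:
    """Most probable origin path for observed codes (0/1) at known markers.

    Switch prior between adjacent markers follows a Haldane-style map at
    ``cm_per_mb``; emissions flip with probability ``miscode``.  Ties prefer
    staying in the previous state."""
    k = obs.size
    le_match = math.log1p(-miscode)
    le_miss = math.log(miscode)
    # delta[s]: best log-prob ending in state s; flat start prior
    d0 = le_match if obs[0] == 0 else le_miss
    d1 = le_match if obs[0] == 1 else le_miss
    back = np.empty((k, 2), dtype=np.int8)
    back[0] = (0, 1)
    for i in range(1, k):
        d_mb = (positions[i] - positions[i - 1]) / 1e6
        theta = 0.5 * (1.0 - math.exp(-2.0 * d_mb * cm_per_mb / 100.0))
        theta = min(max(theta, 1e-12), 0.5 - 1e-12)
        l_stay = math.log1p(-theta)
        l_switch = math.log(theta)
        # state 0
        a, b = d0 + l_stay, d1 + l_switch
        if a >= b:
            n0, p0 = a, 0
        else:
            n0, p0 = b, 1
        # state 1
        a, b = d1 + l_stay, d0 + l_switch
        if a >= b:
            n1, p1 = a, 1
        else:
            n1, p1 = b, 0
        e0 = le_match if obs[i] == 0 else le_miss
        e1 = le_match if obs[i] == 1 else le_miss
        d0, d1 = n0 + e0, n1 + e1
        back[i] = (p0, p1)
    states = np.empty(k, dtype=np.int8)
    states[-1] = 0 if d0 >= d1 else 1
    for i in range(k - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return states


def call_crossovers(
    seq: OriginSequence, smoothing_error: float = 0.005, cm_per_mb: float = 3.0
) -> list[RecombinationInterval]:
    """Crossover intervals for one offspring chromosome.

    Unknown codes are skipped.  With ``smoothing_error`` = 0 every adjacent
    pair of opposite origin codes yields one interval; otherwise the exact
    two-state most-probable path absorbs isolated single-marker flips."""
    if not 0.0 <= smoothing_error < 0.5:
        raise ValueError("smoothing_error must be in [0, 0.5)")
    known = seq.codes != UNKNOWN
    obs_all = seq.codes[known]
    pos_all = seq.positions[known]
    segs_all = (
        seq.segments[known]
        if seq.segments is not None
        else np.zeros(int(known.sum()), dtype=np.int32)
    )
    out: list[RecombinationInterval] = []
    for seg in np.unique(segs_all):
        sel = segs_all == seg
        obs = obs_all[sel]
        pos = pos_all[sel]
        if obs.size < 2:
            continue
        if smoothing_error == 0.0:
            states = obs
        else:
            states = _viterbi_two_state(obs, pos, smoothing_error, cm_per_mb)
        breaks = np.flatnonzero(states[1:] != states[:-1])
        out.extend(
            RecombinationInterval(
                seq.parent, seq.offspring, seq.chromosome, int(pos[i]), int(pos[i + 1])
            )
            for i in breaks
        )
    return out


def map_error_scan(
    sequences: list[OriginSequence],
    n_markers: int,
    mendel_rate: np.ndarray,
    min_informative: int = 20,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-marker map-confidence scores.

    score = 1 - max(singleton-flip rate, phase-conflict rate, Mendelian-error
    rate).  The flip rate is the fraction of informative meioses in which the
    marker's origin differs from both flanking informative markers; the
    conflict rate is the fraction of meioses in which the transmitted allele
    was deduced but family phasing could not assign a consistent origin --
    a misplaced marker manifests as one or the other depending on how many
    offspring it perturbs at once.  Markers with fewer than
    ``min_informative`` deduced meioses keep score 1, flagged unscored."""
    flips = np.zeros(n_markers, dtype=np.int64)
    flip_denom = np.zeros(n_markers, dtype=np.int64)
    deduced = np.zeros(n_markers, dtype=np.int64)
    conflicts = np.zeros(n_markers, dtype=np.int64)
    for seq in sequences:
        known = seq.codes != UNKNOWN
        ded = seq.deduced if seq.deduced is not None else known
        deduced[seq.marker_index[ded]] += 1
        conflicts[seq.marker_index[ded & ~known]] += 1
        segs = (
            seq.segments[known]
            if seq.segments is not None
            else np.zeros(int(known.sum()), dtype=np.int32)
        )
        idx_all = seq.marker_index[known]
        codes_all = seq.codes[known]
        for seg in np.unique(segs):
            sel = segs == seg
            idx = idx_all[sel]
            codes = codes_all[sel]
            if idx.size < 3:
                continue
            mid = idx[1:-1]
            flip_denom[mid] += 1
            is_flip = (codes[1:-1] != codes[:-2]) & (codes[1:-1] != codes[2:])
            flips[mid[is_flip]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        flip_rate = np.where(flip_denom > 0, flips / np.maximum(flip_denom, 1), 0.0)
        conflict_rate = np.where(deduced > 0, conflicts / np.maximum(deduced, 1), 0.0)
    mendel = np.nan_to_num(mendel_rate, nan=0.0)
    score = 1.0 - np.maximum(np.maximum(flip_rate, conflict_rate), mendel)
    unscored = deduced < min_informative
    score[unscored] = 1.0
    return pd.DataFrame(
        {
            "marker_col": np.arange(n_markers),
            "informative_meioses": deduced,
            "flip_rate": flip_rate,
            "conflict_rate": conflict_rate,
            "mendel_rate": mendel_rate,
            "score": score,
            "unscored": unscored,
            "removed": score < threshold,
        }
    )


def detect_crossovers(
    G: GenotypeMatrix,
    ped: pd.DataFrame,
    min_offspring: int = 2,
    smoothing_error: float = 0.005,
    cm_per_mb: float = 3.0,
    map_error_threshold: float = 0.9,
    min_informative_meioses: int = 20,
    scan_map_errors: bool = True,
) -> DetectionResult:
    """Family-by-family crossover detection over all autosomes.

    Runs one detection pass, removes markers failing the map-confidence
    scan, and re-runs once on the cleaned panel (a single cleaning pass)."""
    auto = autosomal_marker_mask(G.markers)
    G_auto = G.subset_markers(auto)

    def one_pass(Gx: GenotypeMatrix):
        families = build_half_sib_families(ped, set(Gx.individuals), min_offspring)
        seqs: list[OriginSequence] = []
        for fam in families:
            seqs.extend(infer_transmitted_alleles(fam, Gx))
        intervals: list[RecombinationInterval] = []
        for seq in seqs:
            intervals.extend(call_crossovers(seq, smoothing_error, cm_per_mb))
        return families, seqs, intervals

    families, seqs, intervals = one_pass(G_auto)
    removed_ids: list[str] = []
    conf = map_error_scan(
        seqs, G_auto.n_markers, mendelian_inconsistency_rate(G_auto, ped),
        min_informative_meioses, map_error_threshold,
    )
    conf.insert(0, "marker_id", G_auto.markers["marker_id"].to_numpy())
    if scan_map_errors and conf["removed"].any():
        removed_ids = list(conf.loc[conf["removed"], "marker_id"])
        keep = ~conf["removed"].to_numpy()
        G_auto = G_auto.subset_markers(keep)
        families, seqs, intervals = one_pass(G_auto)

    sex_of = {}
    for fam in families:
        sex_of[fam.focal_parent] = fam.focal_sex
    pair_rows = [
        (fam.focal_parent, off, fam.focal_sex)
        for fam in families
        for off, _ in fam.pairs
    ]
    pairs = pd.DataFrame(pair_rows, columns=["parent", "offspring", "sex"]).drop_duplicates()
    iv = pd.DataFrame(
        [
            (i.parent, i.offspring, i.chromosome, i.left_pos, i.right_pos, i.r_mb)
            for i in intervals
        ],
        columns=["parent", "offspring", "chromosome", "left_pos", "right_pos", "r_mb"],
    )
    iv["parent_sex"] = iv["parent"].map(sex_of) if len(iv) else pd.Series(dtype=object)
    return DetectionResult(iv, pairs, seqs, conf, removed_ids)
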