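"""Window recombination rates, hotspot/coldspot labels, and per-parent
GRN/GHU summaries.

The window rate is the per-pair average of fractional crossover mass: each
detected interval of length r_i (Mb) contributes overlap/r_i to every
0.5-Mb window it intersects, and the accumulated mass is divided by T, the
number of parent-offspring pairs.  Windows are 0-based half-open
[k*500000, (k+1)*500000); the terminal partial window is kept so that no
base pair is unassigned.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_BP = 500_000

_INTERVAL_COLS = ["parent", "offspring", "chromosome", "left_pos", "right_pos"]


def make_windows(
    chromosome_lengths: Mapping[str, int], width: int = WINDOW_BP
) -> pd.DataFrame:
    rows = []
    for chrom, length in chromosome_lengths.items():
        start = 0
        while start < length:
            rows.append((str(chrom), start, min(start + width, length)))
            start += width
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def mark_covered(windows: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Flag windows containing at least one mapped SNP (windows without any
    SNP cannot show recombination and are excluded from hotspot ranking)."""
    out = windows.copy()
    covered = np.zeros(len(out), dtype=bool)
    for chrom, grp in out.groupby("chromosome", sort=False):
        pos = markers.loc[markers["chromosome"] == chrom, "position"].to_numpy()
        if pos.size == 0:
            continue
        # positions are 1-based; windows 0-based half-open
        counts = np.searchsorted(np.sort(pos - 1), grp["end"].to_numpy()) - np.searchsorted(
            np.sort(pos - 1), grp["start"].to_numpy()
        )
        covered[grp.index] = counts > 0
    out["covered"] = covered
    return out


def _accumulate_mass(
    intervals: pd.DataFrame, windows: pd.DataFrame
) -> np.ndarray:
    """Per-window sum of x_i / r_i (overlap over interval length)."""
    mass = np.zeros(len(windows))
    if len(intervals) == 0:
        return mass
    for chrom, grp in windows.groupby("chromosome", sort=False):
        ivs = intervals[intervals["chromosome"] == chrom]
        if len(ivs) == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        chrom_len = int(ends[-1])
        w_index = grp.index.to_numpy()
        for left, right in zip(ivs["left_pos"].to_numpy(), ivs["right_pos"].to_numpy()):
            if left >= right:
                raise ValueError(f"degenerate interval [{left}, {right})")
            if left < 0 or right > chrom_len:
                raise ValueError(
                    f"interval [{left}, {right}) outside chromosome {chrom} (length {chrom_len})"
                )
            lo = np.searchsorted(ends, left, side="right")
            hi = np.searchsorted(starts, right, side="left")
            ov = np.minimum(ends[lo:hi], right) - np.maximum(starts[lo:hi], left)
            mass[w_index[lo:hi]] += ov / (right - left)
    return mass


def window_rates(
    intervals: pd.DataFrame, T: int, windows: pd.DataFrame
) -> pd.DataFrame:
    """Window recombination-rate track: c_w = (sum_i x_i/r_i) / T.

    Conservation: the sum of c_w over a chromosome equals
    (events on that chromosome) / T."""
    if T <= 0:
        raise ValueError("T (parent-offspring pairs) must be positive")
    track = windows.copy().reset_index(drop=True)
    mass = _accumulate_mass(intervals, track)
    track["event_mass"] = mass
    track["c_w"] = mass / T
    track.attrs["T"] = T
    return track


def classify_hotspots_coldspots(
    track: pd.DataFrame, top_fraction: float = 0.10
) -> pd.DataFrame:
    """Label hotspots (per-chromosome top fraction by c_w, positive rate
    only; ties broken toward the smaller genomic position) and coldspots
    (covered windows with zero accumulated mass).  Windows flagged
    ``covered == False`` are excluded from the ranking denominator."""
    if len(track) == 0:
        raise ValueError("empty window track")
    out = track.copy().reset_index(drop=True)
    if "covered" not in out.columns:
        out["covered"] = True
    labels = np.array(["none"] * len(out), dtype=object)
    for chrom, grp in out.groupby("chromosome", sort=False):
        eligible = grp[grp["covered"]]
        if len(eligible) == 0:
            continue
        k = math.ceil(top_fraction * len(eligible))
        ranked = eligible.sort_values(["c_w", "start"], ascending=[False, True], kind="stable")
        top = ranked.head(k)
        hot_idx = top.index[top["c_w"] > 0]
        labels[hot_idx] = "hotspot"
        cold_idx = eligible.index[(eligible["event_mass"] == 0)]
        labels[[i for i in cold_idx if i not in set(hot_idx)]] = "coldspot"
    out["label"] = labels
    return out


def meiosis_pair_table(pairs: pd.DataFrame) -> pd.DataFrame:
    required = {"parent", "offspring", "sex"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    return pairs


def parent_grn(intervals: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide recombination number: per parent, mean detected events
    per meiosis over all autosomes, counting zero-event offspring."""
    pairs = meiosis_pair_table(pairs)
    n = pairs.groupby("parent").size()
    events = (
        intervals.groupby("parent").size() if len(intervals) else pd.Series(dtype=int)
    )
    sex = pairs.drop_duplicates("parent").set_index("parent")["sex"]
    out = pd.DataFrame(
        {
            "parent": n.index,
            "sex": sex.reindex(n.index).to_numpy(),
            "n": n.to_numpy(),
            "events": events.reindex(n.index).fillna(0).astype(int).to_numpy(),
        }
    )
    out["grn"] = out["events"] / out["n"]
    return out.reset_index(drop=True)


def interval_hotspot_mass(intervals: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Per-interval fractional mass falling inside hotspot windows."""
    hot = track[track["label"] == "hotspot"]
    mass = np.zeros(len(intervals))
    if len(hot) == 0 or len(intervals) == 0:
        return mass
    for chrom, grp in hot.groupby("chromosome", sort=False):
        sel = np.flatnonzero((intervals["chromosome"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        hs = grp["start"].to_numpy()
        he = grp["end"].to_numpy()
        left = intervals["left_pos"].to_numpy()[sel]
        right = intervals["right_pos"].to_numpy()[sel]
        for k, i in enumerate(sel):
            ov = np.minimum(he, right[k]) - np.maximum(hs, left[k])
            mass[i] += float(np.clip(ov, 0, None).sum()) / (right[k] - left[k])
    return mass


def parent_ghu(
    intervals: pd.DataFrame, track: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Genome-wide hotspot usage: a parent's fractional event mass inside
    hotspot windows divided by the parent's event count.  Parents with zero
    events get a missing (NaN) GHU, not zero."""
    grn = parent_grn(intervals, pairs)
    hot_mass = pd.Series(interval_hotspot_mass(intervals, track))
    by_parent = (
        hot_mass.groupby(intervals["parent"].to_numpy()).sum()
        if len(intervals)
        else pd.Series(dtype=float)
    )
    grn["hotspot_mass"] = by_parent.reindex(grn["parent"]).fillna(0.0).to_numpy()
    grn["ghu"] = np.where(grn["events"] > 0, grn["hotspot_mass"] / grn["events"], np.nan)
    return grn


def stratified_maps(
    intervals: pd.DataFrame,
    pairs: pd.DataFrame,
    windows: pd.DataFrame,
    strata: Sequence[str] = ("all", "sire", "dam"),
) -> dict[str, pd.DataFrame]:
    """Window tracks for all parents and for sires/dams separately, each with
    T equal to the number of pairs in the stratum."""
    pairs = meiosis_pair_table(pairs)
    out: dict[str, pd.DataFrame] = {}
    for stratum in strata:
        if stratum == "all":
            sub_pairs = pairs
        else:
            sub_pairs = pairs[pairs["sex"] == stratum]
        if len(sub_pairs) == 0:
            raise ValueError(f"stratum {stratum!r} has no parent-offspring pairs")
        keep_parents = set(sub_pairs["parent"])
        sub_iv = intervals[intervals["parent"].isin(keep_parents)]
        track = window_rates(sub_iv, len(sub_pairs), windows)
        track.attrs["stratum"] = stratum
        out[stratum] = track
    return out
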