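"""Pedigree repeatability model, record weights, and Bayesian whole-genome
regression (BayesC pi=0 / BayesB) with window variance partitioning.

The repeatability animal model

    y = Xb + Zu + Zp + e,   Var(u) = A sigma_a^2,  Var(p) = I sigma_p^2

is fitted by a blocked Gibbs sampler (flat prior on the sex means b,
scaled-inverse-chi-square priors on the variance components), giving
posterior means and SDs for heritability h^2 and repeatability t.  Parent
means built from n repeated records enter the marker models with the
record weight

    En = (1 - h^2) / ((1 + (n - 1) t)/n - h^2),

modelled as record residual variance sigma_e^2 / En.

The marker model y = Xb + M alpha + e is sampled single-site: BayesC(pi=0)
gives every SNP a common normal prior; BayesB gives each SNP a
point-mass-at-zero (fraction pi) plus a per-marker variance with a
scaled-inverse-chi-square prior, i.e. a univariate-t effect distribution.
The indicator is sampled from its marginal likelihood with the effect
integrated out, so no Metropolis step is needed.  Inner loops are
numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

# ---------------------------------------------------------------------------
# Pedigree relationship matrix
# ---------------------------------------------------------------------------

def build_A_matrix(
    ped: pd.DataFrame, subjects: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Numerator relationship matrix by the tabular method.

    The full pedigree is processed in topological order (A_ii = 1 + F_i);
    if ``subjects`` is given the matrix is restricted to them (their
    ancestors still contribute)."""
    ids = list(ped["individual"])
    index = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [index.get(s, -1) for s in ped["sire"]]
    dams = [index.get(d, -1) for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= i or d >= i:
            raise ValueError("pedigree is not topologically sorted")
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    if subjects is None:
        return ids, A
    missing = [s for s in subjects if s not in index]
    if missing:
        raise KeyError(f"subjects absent from pedigree: {missing[:5]}")
    sel = [index[s] for s in subjects]
    return list(subjects), A[np.ix_(sel, sel)]


# ---------------------------------------------------------------------------
# Repeatability model (Gibbs)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_p: float
    sigma2_e: float
    h2: float
    repeatability: float
    sd: dict[str, float] = field(default_factory=dict)
    samples: pd.DataFrame | None = None


def fit_repeatability_model(
    records: pd.DataFrame,
    A: np.ndarray,
    parent_ids: Sequence[str],
    n_iter: int = 4000,
    burn_in: int = 1000,
    seed: int = 0,
    prior_df: float = 4.0,
) -> VarianceComponents:
    """Gibbs sampler for the repeatability animal model.

    ``records`` has columns parent, sex, y (one row per meiosis/observation);
    ``A`` is the relationship matrix over ``parent_ids``.  Raises if no
    parent has repeated records (t is then unidentifiable)."""
    required = {"parent", "sex", "y"}
    if not required <= set(records.columns):
        raise ValueError(f"records needs columns {sorted(required)}")
    parent_ids = list(parent_ids)
    pindex = {p: i for i, p in enumerate(parent_ids)}
    z = records["parent"].map(pindex)
    if z.isna().any():
        raise KeyError("record parent missing from parent_ids")
    z = z.to_numpy(dtype=int)
    counts = np.bincount(z, minlength=len(parent_ids)).astype(float)
    if counts.max() < 2:
        raise ValueError("all parents have a single record; repeatability unidentifiable")
    y = records["y"].to_numpy(dtype=float)
    sex_levels = sorted(records["sex"].unique())
    sex_idx = records["sex"].map({s: i for i, s in enumerate(sex_levels)}).to_numpy()
    n_rec, q = len(y), len(parent_ids)

    Ainv = np.linalg.inv(A + 1e-8 * np.eye(q))
    rng = np.random.default_rng(seed)
    vy = float(np.var(y)) or 1.0
    s2a = s2p = s2e = vy / 3.0
    prior_scale = vy / 6.0  # prior mean vy/3 at prior_df = 4
    b = np.zeros(len(sex_levels))
    u = np.zeros(q)
    p_eff = np.zeros(q)
    out = np.empty((n_iter - burn_in, 5))

    for it in range(n_iter):
        # sex means (flat prior)
        resid_b = y - u[z] - p_eff[z]
        for s in range(len(sex_levels)):
            mask = sex_idx == s
            nn = mask.sum()
            b[s] = rng.normal(resid_b[mask].mean(), np.sqrt(s2e / nn))
        yc = y - b[sex_idx]
        # additive values u (joint draw)
        Zt_r = np.bincount(z, weights=yc - p_eff[z], minlength=q)
        C = Ainv / s2a + np.diag(counts / s2e)
        L = np.linalg.cholesky(C)
        mu = np.linalg.solve(C, Zt_r / s2e)
        u = mu + np.linalg.solve(L.T, rng.standard_normal(q))
        # permanent environment p (diagonal)
        Zt_r = np.bincount(z, weights=yc - u[z], minlength=q)
        var_p = 1.0 / (counts / s2e + 1.0 / s2p)
        p_eff = rng.normal(var_p * Zt_r / s2e, np.sqrt(var_p))
        # variance components
        s2a = (u @ Ainv @ u + prior_df * prior_scale) / rng.chisquare(q + prior_df)
        s2p = (p_eff @ p_eff + prior_df * prior_scale) / rng.chisquare(q + prior_df)
        e = yc - u[z] - p_eff[z]
        s2e = (e @ e + prior_df * prior_scale) / rng.chisquare(n_rec + prior_df)
        if it >= burn_in:
            tot = s2a + s2p + s2e
            out[it - burn_in] = (s2a, s2p, s2e, s2a / tot, (s2a + s2p) / tot)

    samples = pd.DataFrame(out, columns=["sigma2_a", "sigma2_p", "sigma2_e", "h2", "t"])
    mean = samples.mean()
    sd = samples.std()
    return VarianceComponents(
        sigma2_a=float(mean["sigma2_a"]),
        sigma2_p=float(mean["sigma2_p"]),
        sigma2_e=float(mean["sigma2_e"]),
        h2=float(mean["h2"]),
        repeatability=float(mean["t"]),
        sd={k: float(sd[k]) for k in samples.columns},
        samples=samples,
    )


def repeatability_anova(records: pd.DataFrame) -> float:
    """Method-of-moments repeatability from the one-way random ANOVA
    (unbalanced); a quick cross-check for the Gibbs point estimate."""
    groups = [g["y"].to_numpy(dtype=float) for _, g in records.groupby("parent")]
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    grand = np.concatenate(groups).mean()
    ss_b = float(np.sum(n_i * (np.array([g.mean() for g in groups]) - grand) ** 2))
    ss_w = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    var_b = max((ms_b - ms_w) / n0, 0.0)
    return var_b / (var_b + ms_w)


def en_weights(h2: float, t: float, n: np.ndarray | Sequence[int]) -> np.ndarray:
    """Record weight for a parent mean of n observations:
    En = (1 - h^2) / ((1 + (n-1) t)/n - h^2).  At t = h2 this reduces to n
    exactly; at n = 1 it is 1 for any (h2, t)."""
    n = np.asarray(n, dtype=float)
    denom = (1.0 + (n - 1.0) * t) / n - h2
    bad = denom <= 0
    if np.any(bad):
        raise ValueError(f"non-positive En denominator for n = {n[bad][:5]}")
    return (1.0 - h2) / denom


# ---------------------------------------------------------------------------
# Whole-genome regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WGRConfig:
    """Sampler settings for the marker model.

    ``pi`` is the prior fraction of zero-effect SNPs (0 -> BayesC with a
    common effect variance; > 0 -> BayesB with per-marker variances).
    ``genetic_variance`` and ``residual_variance`` seed the prior scales
    (in practice taken from the pedigree repeatability fit)."""

    pi: float = 0.99
    chain: int = 11_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0
    nu_a: float = 4.2
    nu_e: float = 4.0
    s2_a: float | None = None  # per-marker variance prior scale; derived if None
    genetic_variance: float = 1.0
    residual_variance: float = 1.0
    fix_variances: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.chain <= self.burn_in:
            raise ValueError("chain must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class MarkerEffectsPosterior:
    alpha_samples: np.ndarray  # (S, m) float32; zero where excluded
    include_samples: np.ndarray  # (S, m) bool
    sigma_e_samples: np.ndarray  # (S,)
    genetic_var_samples: np.ndarray  # (S,) Var over individuals of M alpha
    b_samples: np.ndarray  # (S, p)
    marker_ids: list[str]
    y_variance: float
    config: WGRConfig

    @property
    def n_samples(self) -> int:
        return self.alpha_samples.shape[0]

    @property
    def sppi(self) -> np.ndarray:
        """Per-SNP posterior probability of inclusion."""
        return self.include_samples.mean(axis=0)

    @property
    def marker_h2_samples(self) -> np.ndarray:
        return self.genetic_var_samples / (self.genetic_var_samples + self.sigma_e_samples)

    def summary(self) -> dict[str, float]:
        h2 = self.marker_h2_samples
        return {
            "marker_h2_mean": float(h2.mean()),
            "marker_h2_sd": float(h2.std()),
            "genetic_variance_mean": float(self.genetic_var_samples.mean()),
            "residual_variance_mean": float(self.sigma_e_samples.mean()),
        }


@njit(cache=True)
def _wgr_chain(
    M, mtm, X, xtx, y, alpha, delta, sigma2j, b,
    pi, nu_a, s2a, nu_e, se2_scale, sigma_e0, sigma_alpha0,
    bayesb, fix_variances, chain, burn_in, thin, seed,
    alpha_out, include_out, sigma_e_out, b_out,
):  # pragma: no cover - exercised via fit_wgr
    np.random.seed(seed)
    n, m = M.shape
    p = X.shape[1]
    sigma_e = sigma_e0
    sigma_alpha = sigma_alpha0
    e = y.copy()
    for c in range(p):
        for i in range(n):
            e[i] -= X[i, c] * b[c]
    for j in range(m):
        if alpha[j] != 0.0:
            for i in range(n):
                e[i] -= M[i, j] * alpha[j]
    log_pi = np.log(pi) if pi > 0.0 else -np.inf
    log_1mpi = np.log(1.0 - pi) if pi < 1.0 else -np.inf
    s_idx = 0
    for it in range(chain):
        # fixed effects, flat prior
        for c in range(p):
            r = 0.0
            for i in range(n):
                r += X[i, c] * e[i]
            r += xtx[c] * b[c]
            mean = r / xtx[c]
            bn = mean + np.sqrt(sigma_e / xtx[c]) * np.random.standard_normal()
            diff = bn - b[c]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= X[i, c] * diff
            b[c] = bn
        # marker effects
        for j in range(m):
            if mtm[j] <= 0.0:
                continue
            r = 0.0
            for i in range(n):
                r += M[i, j] * e[i]
            r += mtm[j] * alpha[j]
            if bayesb:
                if pi >= 1.0:
                    include = False
                elif pi <= 0.0:
                    include = True
                else:
                    v0 = mtm[j] * sigma_e
                    v1 = mtm[j] * mtm[j] * sigma2j[j] + v0
                    log_odds = (
                        log_1mpi - log_pi
                        + 0.5 * (np.log(v0) - np.log(v1))
                        + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
                    )
                    if log_odds > 35.0:
                        include = True
                    elif log_odds < -35.0:
                        include = False
                    else:
                        include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
                if include:
                    cj = mtm[j] + sigma_e / sigma2j[j]
                    an = r / cj + np.sqrt(sigma_e / cj) * np.random.standard_normal()
                else:
                    an = 0.0
                delta[j] = include
            else:
                cj = mtm[j] + sigma_e / sigma_alpha
                an = r / cj + np.sqrt(sigma_e / cj) * np.random.standard_normal()
                delta[j] = True
            diff = an - alpha[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= M[i, j] * diff
            alpha[j] = an
        # variances
        if not fix_variances:
            if bayesb:
                for j in range(m):
                    if delta[j]:
                        sigma2j[j] = (nu_a * s2a + alpha[j] * alpha[j]) / np.random.chisquare(
                            nu_a + 1.0
                        )
                    else:
                        sigma2j[j] = nu_a * s2a / np.random.chisquare(nu_a)
            else:
                ssa = 0.0
                for j in range(m):
                    ssa += alpha[j] * alpha[j]
                sigma_alpha = (nu_a * s2a + ssa) / np.random.chisquare(nu_a + m)
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma_e = (sse + nu_e * se2_scale) / np.random.chisquare(n + nu_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                alpha_out[s_idx, j] = alpha[j]
                include_out[s_idx, j] = delta[j]
            for c in range(p):
                b_out[s_idx, c] = b[c]
            sigma_e_out[s_idx] = sigma_e
            s_idx += 1
    return s_idx


def fit_wgr(
    y: np.ndarray,
    M: np.ndarray,
    cfg: WGRConfig,
    weights: np.ndarray | None = None,
    X: np.ndarray | None = None,
    marker_ids: Sequence[str] | None = None,
) -> MarkerEffectsPosterior:
    """Weighted single-site Gibbs sampler for y = Xb + M alpha + e.

    Record residual variances are sigma_e^2 / w; rows are pre-multiplied by
    sqrt(w) so the kernel sees homoscedastic residuals.  Genetic-variance
    samples are Var over individuals of M_c alpha on the unweighted scale."""
    y = np.asarray(y, dtype=float)
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    if m == 0:
        raise ValueError("no markers to fit")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains missing values")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)

    p_freq = M.mean(axis=0) / 2.0
    sum_2pq = float(np.sum(2.0 * p_freq * (1.0 - p_freq)))
    Mc = M - M.mean(axis=0)
    sw = np.sqrt(weights)
    Mw = np.asfortranarray(Mc * sw[:, None])
    Xw = np.asfortranarray(X * sw[:, None])
    yw = y * sw
    mtm = np.einsum("ij,ij->j", Mw, Mw)
    xtx = np.einsum("ij,ij->j", Xw, Xw)

    pi_eff = max(1.0 - cfg.pi, 1.0 / m)
    var_per_marker = cfg.genetic_variance / max(pi_eff * sum_2pq, 1e-12)
    if cfg.s2_a is not None:
        s2a = cfg.s2_a
    else:
        s2a = var_per_marker * (cfg.nu_a - 2.0) / cfg.nu_a
    n_samples = (cfg.chain - cfg.burn_in + cfg.thin - 1) // cfg.thin
    alpha_out = np.zeros((n_samples, m), dtype=np.float32)
    include_out = np.zeros((n_samples, m), dtype=np.bool_)
    sigma_e_out = np.zeros(n_samples)
    b_out = np.zeros((n_samples, X.shape[1]))
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.bool_)
    sigma2j = np.full(m, var_per_marker)
    b0 = np.zeros(X.shape[1])
    got = _wgr_chain(
        Mw, mtm, Xw, xtx, yw, alpha, delta, sigma2j, b0,
        cfg.pi, cfg.nu_a, s2a, cfg.nu_e, cfg.residual_variance, cfg.residual_variance,
        var_per_marker, cfg.pi > 0.0, cfg.fix_variances,
        cfg.chain, cfg.burn_in, cfg.thin, cfg.seed % (2**31),
        alpha_out, include_out, sigma_e_out, b_out,
    )
    assert got == n_samples
    if not np.isfinite(sigma_e_out).all():
        raise FloatingPointError("divergent residual-variance samples")
    # genetic variance per stored sample on the unweighted scale
    Gv = Mc @ alpha_out.T.astype(float)
    genetic_var = Gv.var(axis=0)
    ids = list(marker_ids) if marker_ids is not None else [f"m{j}" for j in range(m)]
    return MarkerEffectsPosterior(
        alpha_out, include_out, sigma_e_out, genetic_var, b_out, ids,
        float(np.var(y)), cfg,
    )


# ---------------------------------------------------------------------------
# Window variance partition and QTL calling
# ---------------------------------------------------------------------------

def window_variance_partition(
    post: MarkerEffectsPosterior,
    M: np.ndarray,
    markers: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window share of genetic variance, WPPA, and lead SNP.

    Windows are non-overlapping physical bins actually carrying >= 1 marker.
    For each posterior sample the window's genetic values g_w = M_w alpha_w
    are computed across individuals; the window share is
    Var(g_w) / sum_w Var(g_w), so shares sum to one in every sample
    (samples with zero total genetic variance are skipped for shares but
    counted for WPPA).  ``gv_pct`` is the posterior mean share x 100;
    ``gv_pheno_pct`` anchors the same window variance to the phenotypic
    variance as an absolute-scale diagnostic."""
    M = np.asarray(M, dtype=float)
    Mc = M - M.mean(axis=0)
    if len(markers) != M.shape[1]:
        raise ValueError("marker table does not match M")
    win_id = markers["chromosome"].astype(str) + ":" + (
        markers["position"] // window_bp
    ).astype(str)
    order = []
    groups: dict[str, np.ndarray] = {}
    for wid in win_id:
        if wid not in groups:
            order.append(wid)
            groups[wid] = None  # fill later
    for wid in order:
        groups[wid] = np.flatnonzero((win_id == wid).to_numpy())
    S = post.n_samples
    alpha = post.alpha_samples.astype(float)
    include = post.include_samples
    var_w = np.zeros((len(order), S))
    wppa = np.zeros(len(order))
    lead = []
    sppi_all = post.sppi
    for k, wid in enumerate(order):
        cols = groups[wid]
        Gw = Mc[:, cols] @ alpha[:, cols].T
        var_w[k] = Gw.var(axis=0)
        wppa[k] = include[:, cols].any(axis=1).mean()
        sppi_w = sppi_all[cols]
        lead_local = int(np.argmax(sppi_w))
        lead.append((post.marker_ids[cols[lead_local]], float(sppi_w[lead_local])))
    total = var_w.sum(axis=0)
    nonzero = total > 0
    shares = np.zeros_like(var_w)
    if nonzero.any():
        shares[:, nonzero] = var_w[:, nonzero] / total[nonzero]
    gv_pct = shares[:, nonzero].mean(axis=1) * 100 if nonzero.any() else np.zeros(len(order))
    chrom = [w.split(":")[0] for w in order]
    start = [int(w.split(":")[1]) * window_bp for w in order]
    return pd.DataFrame(
        {
            "window": order,
            "chromosome": chrom,
            "start": start,
            "end": [s + window_bp for s in start],
            "n_markers": [groups[w].size for w in order],
            "gv_pct": gv_pct,
            "gv_pheno_pct": var_w.mean(axis=1) / post.y_variance * 100,
            "wppa": wppa,
            "lead_snp": [l[0] for l in lead],
            "lead_sppi": [l[1] for l in lead],
        }
    )


def call_qtl(
    window_results: pd.DataFrame,
    gv_threshold: float = 0.8,
    flank_bp: int = 1_000_000,
) -> pd.DataFrame:
    """QTL regions: each window with gv_pct >= threshold seeds a region
    extended by one flanking window on each side; overlapping or adjacent
    seeded regions are merged."""
    seeds = window_results[window_results["gv_pct"] >= gv_threshold]
    regions = []
    for chrom, grp in seeds.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, row in grp.iterrows():
            lo = max(int(row["start"]) - flank_bp, 0)
            hi = int(row["end"]) + flank_bp
            if cur is not None and lo <= cur["end"]:
                cur["end"] = max(cur["end"], hi)
                if row["gv_pct"] > cur["gv_pct"]:
                    cur.update(
                        gv_pct=row["gv_pct"], wppa=row["wppa"],
                        lead_snp=row["lead_snp"], lead_sppi=row["lead_sppi"],
                        peak_window=row["window"],
                    )
            else:
                if cur is not None:
                    regions.append(cur)
                cur = dict(
                    chromosome=chrom, start=lo, end=hi, peak_window=row["window"],
                    gv_pct=row["gv_pct"], wppa=row["wppa"],
                    lead_snp=row["lead_snp"], lead_sppi=row["lead_sppi"],
                )
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(
        regions,
        columns=["chromosome", "start", "end", "peak_window", "gv_pct", "wppa",
                 "lead_snp", "lead_sppi"],
    )


def lead_snp_refit(
    y: np.ndarray,
    M: np.ndarray,
    markers: pd.DataFrame,
    lead_snp: str,
    region: Mapping[str, object],
    cfg: WGRConfig,
    weights: np.ndarray | None = None,
    X: np.ndarray | None = None,
) -> dict[str, float]:
    """Re-fit with the lead SNP isolated from its QTL region.

    All other markers inside the region are dropped, so the lead SNP alone
    carries the region's signal; returns the SNP's share of genetic
    variance (and its inclusion probability)."""
    ids = list(markers["marker_id"])
    if lead_snp not in ids:
        raise KeyError(f"lead SNP {lead_snp!r} absent from marker set")
    in_region = (
        (markers["chromosome"].astype(str) == str(region["chromosome"]))
        & (markers["position"] >= int(region["start"]))
        & (markers["position"] < int(region["end"]))
    ).to_numpy()
    keep = ~in_region
    keep[ids.index(lead_snp)] = True
    cols = np.flatnonzero(keep)
    post = fit_wgr(y, M[:, cols], cfg, weights=weights, X=X,
                   marker_ids=[ids[c] for c in cols])
    j = [ids[c] for c in cols].index(lead_snp)
    Mc = M[:, cols] - M[:, cols].mean(axis=0)
    g_snp = np.outer(Mc[:, j], post.alpha_samples[:, j].astype(float))
    var_snp = g_snp.var(axis=0)
    total = (Mc @ post.alpha_samples.T.astype(float)).var(axis=0)
    nz = total > 0
    share = float((var_snp[nz] / total[nz]).mean() * 100) if nz.any() else 0.0
    return {
        "snp_gv_pct": share,
        "snp_gv_pheno_pct": float(var_snp.mean() / post.y_variance * 100),
        "sppi": float(post.include_samples[:, j].mean()),
    }


def single_snp_mixed_model(
    y: np.ndarray,
    snp: np.ndarray,
    A: np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    X: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """GLS fixed-effect test of one SNP in an animal model.

    V = sigma2_a A + diag(sigma2_e / w); the SNP estimate and Wald p-value
    come from (W' V^-1 W)^-1 with W = [X snp]."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    if weights is None:
        weights = np.ones(n)
    V = sigma2_a * A + np.diag(sigma2_e / np.asarray(weights, dtype=float))
    W = np.column_stack([X, np.asarray(snp, dtype=float)])
    Vi_W = np.linalg.solve(V, W)
    WtVW = W.T @ Vi_W
    try:
        cov = np.linalg.inv(WtVW)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular GLS system for SNP test") from exc
    beta = cov @ (Vi_W.T @ y)
    se = float(np.sqrt(cov[-1, -1]))
    est = float(beta[-1])
    z = est / se
    return {"estimate": est, "se": se, "z": z, "p_value": float(2 * stats.norm.sf(abs(z)))}
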