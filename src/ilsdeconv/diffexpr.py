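"""Differential expression for two-group contrasts of NB count data.

Implements, from the published method definitions, the analysis stack a
count-based RNA-seq comparison needs:

* abundance filtering (keep genes with CPM >= C in at least m samples and
  total count >= 15, where m is the smallest group size and
  C = 10 / median library size in millions);
* TMM between-sample normalization (doubly trimmed, precision-weighted
  mean of per-gene log ratios against a reference sample);
* negative-binomial dispersion estimation by Cox-Reid adjusted profile
  likelihood, with per-gene estimates shrunk toward the common value by
  weighted likelihood (10 prior degrees of freedom by default);
* per-gene NB log-linear models fitted by Fisher scoring with library
  size offsets, compared by a quasi-likelihood F-test whose residual
  variances are squeezed by empirical-Bayes moment matching to a scaled
  inverse-chi-square prior;
* Benjamini-Hochberg step-up adjustment.

Counts may be non-integer (EM expected counts); all likelihoods are the
continuous NB extensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_MIN_PHI = 1e-4
_MAX_PHI = 10.0


class DEError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Filtering


def filter_low_abundance(
    counts: pd.DataFrame,
    groups: Sequence[str],
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> Tuple[pd.DataFrame, List[str]]:
    """Remove genes too weakly expressed to test.

    Keep a gene iff its CPM is >= C in at least m samples AND its total
    count is >= `min_total`, where m is the size of the smallest group
    and C = `min_count` / (median library size in millions).
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise DEError("every sample needs a positive library size")
    m = min(pd.Series(groups).value_counts())
    cpm_cutoff = min_count / (np.median(lib) / 1e6)
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = ((cpm >= cpm_cutoff).sum(axis=1) >= m) & (
        counts.sum(axis=1).to_numpy() >= min_total
    )
    if not keep.any():
        raise DEError(
            "all genes removed by the abundance filter; lower min_count "
            "or check library sizes"
        )
    kept = list(counts.index[keep])
    return counts.loc[kept], kept


# ---------------------------------------------------------------------------
# TMM


@dataclass
class NormalizationFactors:
    samples: List[str]
    library_size: np.ndarray
    factor: np.ndarray

    @property
    def effective(self) -> np.ndarray:
        return self.library_size * self.factor

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "library_size": self.library_size,
                "tmm_factor": self.factor,
                "effective_library_size": self.effective,
            }
        )


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    Reference sample: the one whose 75th-percentile CPM is closest to the
    mean 75th percentile. Per sample vs reference, over genes positive in
    both: M = log2((y/N)/(yr/Nr)), A = 0.5*log2(y*yr/(N*Nr)); the top and
    bottom `log_ratio_trim` of M and `abundance_trim` of A are dropped;
    the factor is 2**(weighted mean M) with inverse asymptotic binomial
    variance weights; factors are rescaled to geometric mean 1.
    """
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise DEError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise DEError("TMM needs positive library sizes")
    q75 = np.array(
        [np.quantile(y[:, j][y[:, j] >= 0] / lib[j], 0.75) for j in range(y.shape[1])]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    yr, nr = y[:, ref], lib[ref]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        pos = (yj > 0) & (yr > 0)
        if not pos.any():
            warnings.warn(
                f"sample {counts.columns[j]} shares no positive genes with "
                "the TMM reference; factor set to 1"
            )
            continue
        pj, pr = yj[pos] / nj, yr[pos] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = 1.0 / (
            (nj - yj[pos]) / (nj * yj[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        )
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        m_lo, m_hi = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
        a_lo, a_hi = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            continue
        factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        samples=list(counts.columns), library_size=lib, factor=factors
    )


def cpm(
    counts: pd.DataFrame, norm: Optional[NormalizationFactors] = None,
) -> pd.DataFrame:
    """Counts per million on (TMM-)effective library sizes."""
    lib = (
        norm.effective if norm is not None
        else counts.sum(axis=0).to_numpy(dtype=float)
    )
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorised over genes, one-factor designs)


def _group_indices(groups: Sequence[str]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    for level in dict.fromkeys(groups):
        out[level] = np.flatnonzero(np.asarray(groups) == level)
    return out


def _fit_means(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray,
    blocks: Sequence[np.ndarray], max_iter: int = 50, tol: float = 1e-10,
) -> np.ndarray:
    """Fit mu for an NB GLM whose design is a partition of samples.

    Each block (set of sample indices) has its own intercept; mu_j =
    exp(beta_block + offset_j). Fisher scoring per block, vectorised over
    genes. Returns mu (genes x samples).
    """
    G, S = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1), (G,))
    mu = np.zeros((G, S))
    for idx in blocks:
        yb = y[:, idx]
        ob = offsets[idx]
        tot = yb.sum(axis=1)
        nonzero = tot > 0
        beta = np.where(
            nonzero, np.log(np.maximum(tot, 1e-300)) - np.log(np.sum(np.exp(ob))), -np.inf
        )
        active = nonzero.copy()
        for _ in range(max_iter):
            if not active.any():
                break
            mub = np.exp(beta[active, None] + ob[None, :])
            denom = 1.0 + phi[active, None] * mub
            score = ((yb[active] - mub) / denom).sum(axis=1)
            info = (mub / denom).sum(axis=1)
            step = score / np.maximum(info, 1e-300)
            step = np.clip(step, -5.0, 5.0)
            beta[active] = beta[active] + step
            done = np.abs(step) < tol
            sub = np.flatnonzero(active)
            active[sub[done]] = False
        mu[:, idx] = np.where(
            np.isfinite(beta)[:, None], np.exp(beta[:, None] + ob[None, :]), 0.0
        )
    return mu


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB residual deviance (continuous in y; Poisson at phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * (np.log(np.maximum(y, 1e-300)) - np.log(mu)), 0.0)
        poisson = term1 - (y - mu)
        r = 1.0 / np.maximum(phi, 1e-300)
        nb = term1 - (y + r) * (np.log(y + r) - np.log(mu + r))
        unit = np.where(phi > 1e-10, nb, poisson)
    return 2.0 * unit.sum(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood, continuous-y gamma form."""
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    mu = np.maximum(mu, 1e-300)
    r = 1.0 / np.maximum(phi, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            special.gammaln(y + r) - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - r * np.log1p(phi * mu)
        )
        pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
        ll = np.where(phi > 1e-10, ll, pois)
    return ll.sum(axis=1)


def _adjusted_profile_loglik(
    y: np.ndarray, offsets: np.ndarray, phi_scalar: float,
    blocks: Sequence[np.ndarray],
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at one phi."""
    G = y.shape[0]
    phi = np.full(G, phi_scalar)
    mu = _fit_means(y, offsets, phi, blocks)
    ll = _nb_loglik(y, mu, phi)
    # block-diagonal X'WX for a partition design: det = prod of block sums
    cr = np.zeros(G)
    for idx in blocks:
        w = mu[:, idx] / (1.0 + phi[:, None] * mu[:, idx])
        cr += np.log(np.maximum(w.sum(axis=1), 1e-300))
    return ll - 0.5 * cr


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    prior_df: float


def estimate_dispersions(
    counts: pd.DataFrame,
    norm: NormalizationFactors,
    groups: Sequence[str],
    prior_df: float = 10.0,
    grid_points: int = 41,
) -> DispersionEstimate:
    """Common + shrunk per-gene NB dispersions via Cox-Reid APL.

    The common dispersion maximises the summed APL over genes (1-D search
    on log phi in [1e-4, 10]). Per-gene dispersions maximise the weighted
    likelihood APL_g(phi) + (prior_df / residual df) * mean_g' APL(phi),
    which shrinks each gene toward the common maximiser; estimates are
    refined by quadratic interpolation on the log-phi grid.
    """
    y = counts.to_numpy(dtype=float)
    blocks = list(_group_indices(groups).values())
    df_res = y.shape[1] - len(blocks)
    if df_res < 1:
        raise DEError("no residual degrees of freedom for dispersion")
    offsets = np.log(norm.effective)

    grid = np.linspace(np.log(_MIN_PHI), np.log(_MAX_PHI), grid_points)
    apl = np.empty((y.shape[0], grid_points))
    for k, lphi in enumerate(grid):
        apl[:, k] = _adjusted_profile_loglik(y, offsets, float(np.exp(lphi)), blocks)

    total = apl.sum(axis=0)
    k0 = int(np.argmax(total))
    common = float(np.exp(_quad_refine(grid, total, k0)))

    weight = prior_df / df_res
    score = apl + weight * apl.mean(axis=0)[None, :]
    kbest = np.argmax(score, axis=1)
    log_tag = np.array(
        [_quad_refine(grid, score[g], int(kbest[g])) for g in range(y.shape[0])]
    )
    tagwise = pd.Series(
        np.exp(log_tag), index=counts.index, name="dispersion"
    ).clip(_MIN_PHI, _MAX_PHI)
    return DispersionEstimate(common=common, tagwise=tagwise, prior_df=prior_df)


def _quad_refine(x: np.ndarray, fx: np.ndarray, k: int) -> float:
    """Vertex of the parabola through three neighbouring grid points."""
    if k == 0 or k == len(x) - 1:
        return float(x[k])
    x0, x1, x2 = x[k - 1], x[k], x[k + 1]
    f0, f1, f2 = fx[k - 1], fx[k], fx[k + 1]
    denom = (f0 - 2 * f1 + f2)
    if denom >= 0 or not np.isfinite(denom):
        return float(x1)
    return float(x1 + 0.5 * (f0 - f2) / denom * (x1 - x0))


# ---------------------------------------------------------------------------
# Quasi-likelihood F-test


def _squeeze_var(
    s2: np.ndarray, df: float
) -> Tuple[np.ndarray, float, float]:
    """Empirical-Bayes moment matching of residual variances.

    Matches the distribution of log s2 to s0^2 * F(df, d0): returns
    (squeezed variances, d0, s0^2). Degenerate spreads give d0 = inf (no
    squeezing beyond the common value), with a warning.
    """
    ok = np.isfinite(s2) & (s2 > 1e-12)
    if ok.sum() < 2:
        warnings.warn("degenerate residual variance distribution; no squeezing")
        s0 = float(np.nanmedian(np.maximum(s2, 1e-12)))
        return np.full_like(s2, s0), np.inf, s0
    z = np.log(s2[ok])
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = np.inf
        log_s0 = float(np.mean(z)) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        log_s0 = (
            float(np.mean(z))
            - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
            + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0)
        )
    s0 = float(np.exp(log_s0))
    if np.isinf(d0):
        sq = np.full_like(s2, s0)
    else:
        s2c = np.where(ok, s2, s0)
        sq = (d0 * s0 + df * s2c) / (d0 + df)
    return sq, d0, s0


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return y


def ql_f_test(
    counts: pd.DataFrame,
    norm: NormalizationFactors,
    groups: Sequence[str],
    dispersions: DispersionEstimate,
    contrast: Tuple[str, str],
) -> pd.DataFrame:
    """Quasi-likelihood F-test of group2 vs group1 per gene.

    Fits null (intercept) and full (group) NB models with effective
    library-size offsets and the shrunk dispersions, forms the raw
    quasi-dispersion s2 = residual deviance / residual df, squeezes it
    across genes, and refers F = (dev_null - dev_full) / s2~ to
    F(1, d0 + residual df). Returns a table with log2FC (group2 vs
    group1), average log2 CPM, F, p and BH FDR.
    """
    g1, g2 = contrast
    idx = _group_indices(groups)
    if set(idx) != {g1, g2}:
        raise DEError(
            f"design groups {sorted(idx)} do not match contrast {contrast}"
        )
    y = counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective)
    phi = dispersions.tagwise.reindex(counts.index).to_numpy()
    blocks_full = [idx[g1], idx[g2]]
    blocks_null = [np.arange(y.shape[1])]

    mu_full = _fit_means(y, offsets, phi, blocks_full)
    mu_null = _fit_means(y, offsets, phi, blocks_null)
    dev_full = nb_deviance(y, mu_full, phi)
    dev_null = nb_deviance(y, mu_null, phi)

    df_res = y.shape[1] - 2
    df_test = 1
    if df_res < 1:
        raise DEError("need at least 3 samples across two groups")
    s2 = dev_full / df_res
    s2_sq, d0, _ = _squeeze_var(s2, df_res)

    f_stat = np.maximum(dev_null - dev_full, 0.0) / (df_test * np.maximum(s2_sq, 1e-12))
    dfd = min(d0 + df_res, 1e6)
    p = stats.f.sf(f_stat, df_test, dfd)

    # log2FC from the fitted group abundances (offset-adjusted)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate1 = mu_full[:, idx[g1]].sum(axis=1) / np.exp(offsets[idx[g1]]).sum()
        rate2 = mu_full[:, idx[g2]].sum(axis=1) / np.exp(offsets[idx[g2]]).sum()
        log2fc = np.log2(np.maximum(rate2, 1e-300)) - np.log2(
            np.maximum(rate1, 1e-300)
        )
    ave_cpm = np.log2((y / np.exp(offsets) * 1e6).mean(axis=1) + 0.25)

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2FC": log2fc,
            "avg_log2CPM": ave_cpm,
            "F": f_stat,
            "p_value": p,
            "FDR": bh_adjust(p),
        }
    ).set_index("gene_id")
    out.attrs["prior_df_d0"] = d0
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of min(1, m * p_(j) / j) in sorted order;
    NaNs propagate and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return adj
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    cummin = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.minimum(cummin, 1.0)
    restored = np.empty(m)
    restored[order] = out
    adj[ok] = restored
    return adj


# ---------------------------------------------------------------------------
# Contrast driver


@dataclass
class ContrastSpec:
    """One pair-wise contrast: a count matrix plus its two-group design."""

    name: str
    counts: pd.DataFrame
    groups: List[str]
    contrast: Tuple[str, str]  # (reference group, comparison group)


def run_de(
    spec: ContrastSpec,
    prior_df: float = 10.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Filter -> TMM -> dispersions -> QL F-test for one contrast."""
    sizes = pd.Series(spec.groups).value_counts()
    if len(sizes) != 2 or (sizes < 2).any():
        raise DEError(
            f"contrast {spec.name}: need exactly two groups with >= 2 "
            f"samples each, got {sizes.to_dict()}"
        )
    filtered, _ = filter_low_abundance(spec.counts, spec.groups)
    norm = tmm_factors(filtered)
    disp = estimate_dispersions(filtered, norm, spec.groups, prior_df=prior_df)
    return ql_f_test(filtered, norm, spec.groups, disp, spec.contrast)


def run_contrasts(
    specs: Sequence[ContrastSpec],
    fdr: float = 0.05,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Run every configured contrast; summarise up/down DEG counts.

    Returns ({contrast name: DE table}, summary frame with up/down counts
    at the FDR threshold).
    """
    tables: Dict[str, pd.DataFrame] = {}
    rows = []
    for spec in specs:
        if spec.counts is None or spec.counts.empty:
            raise DEError(f"missing count matrix for contrast {spec.name}")
        table = run_de(spec, fdr=fdr)
        tables[spec.name] = table
        sig = table["FDR"] < fdr
        rows.append(
            {
                "contrast": spec.name,
                "n_tested": len(table),
                "up": int((sig & (table["log2FC"] > 0)).sum()),
                "down": int((sig & (table["log2FC"] < 0)).sum()),
            }
        )
    return tables, pd.DataFrame(rows)
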