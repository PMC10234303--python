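"""Windowed Watterson's theta from population SNPs and its link to the
predicted mutation rate.

Theta is computed with a per-site sample-size correction so strains with
missing calls are handled without discarding sites: a site with ``n_i``
called alleles contributes ``1 / a_{n_i}`` (``a_n`` the harmonic number
``sum_{k<n} 1/k``) if it segregates among the called alleles, and window
theta is the sum over sites divided by the callable window length.
Windows are then regressed on the log10 per-window mutation rate
predicted by a fitted window rate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import PosteriorSummary, hpdi, rw_metropolis, summarize
from .ma_rates import FittedRateModel

__all__ = [
    "SNPMatrix", "harmonic_number", "watterson_theta", "theta_windows",
    "predict_mu", "DiversityRegression", "diversity_regression",
    "hurdle_regression", "domain_theta_contrast", "read_vcf",
]


def harmonic_number(n: int) -> float:
    """a_n = sum_{k=1}^{n-1} 1/k; zero for n < 2."""
    if n < 2:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class SNPMatrix:
    """Haploid genotype calls: sites x strains, -1 marking missing calls."""

    sites: pd.DataFrame       # contig, pos (0-based), ref, alt
    gts: np.ndarray           # (n_sites, n_strains) int8
    n_strains: int

    def __post_init__(self):
        if self.gts.shape != (len(self.sites), self.n_strains):
            raise ValueError("genotype matrix shape mismatch")

    def n_called(self) -> np.ndarray:
        return (self.gts >= 0).sum(axis=1)

    def segregating(self) -> np.ndarray:
        """Per site: >= 2 distinct alleles among called strains.

        Any multiallelic pattern counts as segregating.
        """
        out = np.zeros(len(self.sites), dtype=bool)
        for i, row in enumerate(self.gts):
            called = row[row >= 0]
            out[i] = called.size >= 2 and np.unique(called).size >= 2
        return out


def read_vcf(path) -> SNPMatrix:
    """Read haploid genotypes from a VCF ('.' or ./. = missing)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, gt_rows = [], []
    for rec in vf:
        gts = np.full(len(samples), -1, dtype=np.int8)
        for j, s in enumerate(samples):
            call = rec.samples[s].get("GT", (None,))
            allele = call[0] if call else None
            if allele is not None:
                gts[j] = allele
        rows.append((rec.chrom, rec.pos - 1, rec.ref,
                     ",".join(rec.alts or ("",))))
        gt_rows.append(gts)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    gts = (np.array(gt_rows, dtype=np.int8) if gt_rows
           else np.empty((0, len(samples)), dtype=np.int8))
    return SNPMatrix(sites=sites, gts=gts, n_strains=len(samples))


def from_site_table(sites: pd.DataFrame, n_strains: int) -> SNPMatrix:
    """Build an SNPMatrix from a synthetic site table with a 'gts' column."""
    gts = (np.vstack(sites["gts"].to_numpy()) if len(sites)
           else np.empty((0, n_strains), dtype=np.int8))
    return SNPMatrix(sites=sites.drop(columns="gts"), gts=gts,
                     n_strains=n_strains)


def watterson_theta(n_called, segregating, length: float) -> float:
    """Per-bp theta from per-site called sample sizes and segregation flags.

    Sites with fewer than 2 called alleles are skipped.  With complete
    data this reduces to the classic S / (a_n * L).
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    n_called = np.asarray(n_called)
    segregating = np.asarray(segregating, dtype=bool)
    total = 0.0
    for n, s in zip(n_called, segregating):
        if n >= 2 and s:
            total += 1.0 / harmonic_number(int(n))
    return total / length


def theta_windows(snp: SNPMatrix, window_table: pd.DataFrame,
                  min_callable_frac: float = 0.5) -> pd.DataFrame:
    """Per-window theta over a window table.

    Adds columns theta_w (NaN when callable bases fall below
    ``min_callable_frac`` of the window span), n_segregating and
    mean_n_called.  Theta is per callable bp.
    """
    seg = snp.segregating()
    ncall = snp.n_called()
    out = window_table.copy()
    theta = np.full(len(out), np.nan)
    nseg = np.zeros(len(out), dtype=int)
    mean_n = np.full(len(out), np.nan)
    by_contig = {}
    for contig, grp in snp.sites.groupby("contig"):
        idx = grp.index.to_numpy()
        by_contig[contig] = (grp["pos"].to_numpy(), idx)
    for i, w in enumerate(out.itertuples(index=False)):
        span = w.end - w.start
        if w.callable_bp < min_callable_frac * span or w.callable_bp == 0:
            continue
        pos, idx = by_contig.get(
            w.contig, (np.array([], dtype=int), np.array([], dtype=int)))
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        sel = idx[lo:hi]
        usable = sel[ncall[sel] >= 2]
        theta[i] = watterson_theta(ncall[usable], seg[usable],
                                   float(w.callable_bp))
        nseg[i] = int(seg[usable].sum())
        if usable.size:
            mean_n[i] = float(ncall[usable].mean())
    out["theta_w"] = theta
    out["n_segregating"] = nseg
    out["mean_n_called"] = mean_n
    return out


def predict_mu(window_table: pd.DataFrame, model: FittedRateModel
               ) -> np.ndarray:
    """Posterior-median log10 per-bp per-mitosis rate per window.

    Windows with missing GC get NaN and are excluded downstream.
    """
    ok = np.isfinite(window_table["gc_fraction"].to_numpy())
    out = np.full(len(window_table), np.nan)
    if ok.any():
        log_mu = model.predict_log_mu(window_table.loc[ok])
        out[ok] = log_mu / np.log(10.0)
    return out


@dataclass
class DiversityRegression:
    """Bayesian linear regression of window theta on log10 predicted rate."""

    slope: PosteriorSummary
    intercept: PosteriorSummary
    r2: PosteriorSummary           # Bayesian R^2
    n_windows: int


def diversity_regression(theta: np.ndarray, log10_mu: np.ndarray,
                         n_draws: int = 12000, seed: int = 0
                         ) -> DiversityRegression:
    """Regress theta on log10 predicted mutation rate.

    Conjugate normal regression with the reference prior p(beta, s^2)
    proportional to 1/s^2; Bayesian R^2 is the draw-wise ratio of fitted
    variance to fitted-plus-residual variance.
    """
    theta = np.asarray(theta, dtype=float)
    log10_mu = np.asarray(log10_mu, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(log10_mu)
    y, x = theta[ok], log10_mu[ok]
    n = y.size
    if n < 100:
        raise ValueError(f"need >= 100 windows for the regression, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    resid = y - X @ beta_hat
    s2 = float(resid @ resid) / (n - 2)
    rng = np.random.default_rng(seed)
    sigma2 = (n - 2) * s2 / rng.chisquare(n - 2, size=n_draws)
    L = np.linalg.cholesky(XtX_inv)
    betas = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * \
        (rng.standard_normal((n_draws, 2)) @ L.T)
    fitted_var = np.var(betas @ X.T, axis=1)
    r2 = fitted_var / (fitted_var + sigma2)
    return DiversityRegression(
        slope=summarize(betas[:, 1]),
        intercept=summarize(betas[:, 0]),
        r2=summarize(r2),
        n_windows=n,
    )


def hurdle_regression(theta: np.ndarray, log10_mu: np.ndarray,
                      seed: int = 0, chains: int = 2, warmup: int = 500,
                      draws: int = 1000) -> dict:
    """Two-part robustness variant for the excess of zero-theta windows.

    Part 1: Bayesian logistic regression of P(theta > 0) on log10 mu;
    part 2: the linear regression restricted to positive windows.  Both
    slopes should agree in sign with the single linear fit when diversity
    genuinely tracks the mutation rate.
    """
    theta = np.asarray(theta, dtype=float)
    log10_mu = np.asarray(log10_mu, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(log10_mu)
    y, x = theta[ok], log10_mu[ok]
    z = (y > 0).astype(float)
    xc = x - x.mean()

    def logpost(b):
        eta = b[0] + b[1] * xc
        ll = np.sum(z * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum((b / 10.0) ** 2)

    pooled, _ = rw_metropolis(logpost, np.zeros(2), seed=seed, chains=chains,
                              warmup=warmup, draws=draws)
    pos = y > 0
    positive_part = diversity_regression(y[pos], x[pos], seed=seed + 1)
    return {
        "zero_slope": summarize(pooled[:, 1]),
        "positive_slope": positive_part.slope,
        "positive_r2": positive_part.r2,
    }


def domain_theta_contrast(theta_table: pd.DataFrame, n_boot: int = 2000,
                          seed: int = 0) -> pd.DataFrame:
    """Median theta per domain and bootstrap differences vs euchromatin.

    Domains are the window labels with the centromere overlay split out.
    """
    rng = np.random.default_rng(seed)
    ok = theta_table[np.isfinite(theta_table["theta_w"])]
    groups = {}
    for label in ("euchromatin", "H3K9me3", "H3K27me3"):
        sel = ok[ok["domain_label"] == label]
        if label == "H3K9me3":
            groups["centromeric"] = sel[sel["centromeric"]]["theta_w"].to_numpy()
            sel = sel[~sel["centromeric"]]
        groups[label] = sel["theta_w"].to_numpy()

    def boot_medians(v):
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        return np.median(v[idx], axis=1)

    med_draws = {k: boot_medians(v) for k, v in groups.items() if v.size}
    rows = []
    for label, v in groups.items():
        if v.size == 0:
            continue
        lo, hi = hpdi(med_draws[label])
        row = {"domain": label, "median_theta": float(np.median(v)),
               "median_low": lo, "median_high": hi,
               "n_windows": int(v.size)}
        if label != "euchromatin" and "euchromatin" in med_draws:
            diff = med_draws[label] - med_draws["euchromatin"]
            dlo, dhi = hpdi(diff)
            row.update({"diff_vs_eu": float(np.median(diff)),
                        "diff_low": dlo, "diff_high": dhi})
        rows.append(row)
    return pd.DataFrame(rows)
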