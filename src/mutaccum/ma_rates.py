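"""Per-mitosis mutation-rate estimation for mutation-accumulation lines.

The basic model treats the mutation count of line *i* as
``y_i ~ Poisson(lambda_i)`` with ``log(lambda_i) = alpha`` and a diffuse
``N(0, 10)`` prior on the intercept.  The per-base per-mitosis rate is
then ``mu = exp(alpha) / (N * t * m)`` where ``N`` is the number of
callable bases, ``t`` the number of single-spore transfers and ``m`` the
number of mitoses per transfer; dropping ``N`` gives a per-genome rate.
``m`` is itself estimated from nuclei counts and enters as posterior
draws, so its uncertainty propagates into every rate.

Window-level rate variation is modelled as a Poisson regression with a
log-exposure offset and GC-content, H3K9me3, H3K27me3 and centromere
predictors (plus a GC x H3K9me3 interaction); candidate predictor sets
are compared with WAIC-based pseudo-BMA model weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import (
    PoissonGLMPosterior,
    PosteriorSummary,
    hpdi,
    pseudo_bma_weights,
    sample_poisson_glm,
    summarize,
    waic,
)

__all__ = [
    "ExperimentDesign", "NucleiCounts", "RateEstimate", "RatioSummary",
    "FittedRateModel", "MitosisEstimate",
    "estimate_mitoses", "fit_poisson_rate", "to_rate",
    "fit_domain_gc_model", "model_weights", "rate_ratio", "hpdi",
]

GENOME_SIZE = 41_108_926          # reference assembly length, bp
CALLED_FRACTION = 0.987           # fraction of bases with confident calls
DEFAULT_N_LINES = 39
DEFAULT_TRANSFERS = 40
DEFAULT_MITOSES_PER_TRANSFER = 1015 / 40


@dataclass
class ExperimentDesign:
    """Design constants of a mutation-accumulation experiment."""

    n_lines: int = DEFAULT_N_LINES
    t_transfers: int = DEFAULT_TRANSFERS
    m_draws: np.ndarray = field(
        default_factory=lambda: np.full(12000, DEFAULT_MITOSES_PER_TRANSFER))
    callable_bp: dict = field(
        default_factory=lambda: {"genome": GENOME_SIZE * CALLED_FRACTION})

    def __post_init__(self):
        self.m_draws = np.asarray(self.m_draws, dtype=float).ravel()
        if self.n_lines < 1 or self.t_transfers < 1:
            raise ValueError("n_lines and t_transfers must be >= 1")
        if np.any(self.m_draws <= 0):
            raise ValueError("all mitosis draws must be positive")
        for k, v in self.callable_bp.items():
            if v <= 0:
                raise ValueError(f"callable_bp[{k!r}] must be positive")

    @property
    def m_median(self) -> float:
        return float(np.median(self.m_draws))

    @property
    def total_mitoses(self) -> float:
        """Median mitoses over the whole experiment, t * m."""
        return self.t_transfers * self.m_median


@dataclass
class NucleiCounts:
    """Replicate (initial, final) nuclei counts per phase of a transfer."""

    phases: dict[str, list[tuple[float, float]]]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("need at least one phase")
        for name, reps in self.phases.items():
            if not reps:
                raise ValueError(f"phase {name!r} has no replicates")
            for ini, fin in reps:
                if ini < 1 or fin < 1:
                    raise ValueError(f"phase {name!r}: counts must be >= 1")


@dataclass
class MitosisEstimate:
    """Posterior for mitoses per transfer and for the whole experiment."""

    per_transfer: PosteriorSummary
    total: PosteriorSummary
    per_phase: dict[str, PosteriorSummary]


def estimate_mitoses(nuclei: NucleiCounts, t_transfers: int = DEFAULT_TRANSFERS,
                     n_draws: int = 12000, seed: int = 0,
                     noise_scale_prior: float = 0.25) -> MitosisEstimate:
    """Estimate mitoses per transfer from nuclei counts.

    Each phase of a transfer contributes ``d_p = log2(final / initial)``
    doublings.  Observed log2 fold-changes carry lognormal measurement
    error on the counts, so ``x_r ~ Normal(d_p, sqrt(2) * sigma)`` with a
    half-normal prior on the per-count noise scale ``sigma`` and a
    positive-truncated ``N(10, 10)`` prior on ``d_p``.  The posterior is
    evaluated on a dense (d, sigma) grid per phase — phases are
    independent — and ``m = sum_p d_p``.
    """
    rng = np.random.default_rng(seed)
    d_grid = np.linspace(0.0, 40.0, 1601)
    s_grid = np.linspace(1e-3, 1.2 * max(noise_scale_prior * 4, 0.2), 240)
    log_prior_d = -0.5 * ((d_grid - 10.0) / 10.0) ** 2
    log_prior_s = -0.5 * (s_grid / noise_scale_prior) ** 2

    per_phase = {}
    m_draws = np.zeros(n_draws)
    for name, reps in nuclei.phases.items():
        x = np.array([np.log2(fin / ini) for ini, fin in reps])
        if np.all(x < 0):
            raise ValueError(
                f"phase {name!r}: final < initial in all replicates "
                "(negative growth unsupported)")
        sd = np.sqrt(2.0) * s_grid  # per-ratio sd from per-count noise
        # log posterior on the (d, sigma) grid
        resid = x[None, None, :] - d_grid[:, None, None]
        ll = (-0.5 * (resid / sd[None, :, None]) ** 2
              - np.log(sd)[None, :, None]).sum(axis=2)
        lp = ll + log_prior_d[:, None] + log_prior_s[None, :]
        lp -= lp.max()
        w = np.exp(lp).sum(axis=1)  # marginal over sigma
        w /= w.sum()
        idx = rng.choice(d_grid.size, size=n_draws, p=w)
        jitter = (d_grid[1] - d_grid[0]) * (rng.random(n_draws) - 0.5)
        draws = np.clip(d_grid[idx] + jitter, 0.0, None)
        per_phase[name] = summarize(draws)
        m_draws += draws

    per_transfer = summarize(m_draws)
    total = summarize(t_transfers * m_draws)
    return MitosisEstimate(per_transfer=per_transfer, total=total,
                           per_phase=per_phase)


def fit_poisson_rate(counts, exposure=1.0, prior_sd: float = 10.0,
                     seed: int = 0, chains: int = 4, warmup: int = 1000,
                     draws: int = 3000) -> PosteriorSummary:
    """Posterior of the intercept alpha for counts ~ Poisson(exposure * e^alpha).

    The default prior is the diffuse N(0, 10) used for single-rate
    estimates.  Convergence (split-R-hat) is attached to the summary.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    exposure = np.broadcast_to(np.asarray(exposure, dtype=float),
                               counts.shape).copy()
    if np.any(exposure <= 0):
        raise ValueError("exposures must be positive")
    post = sample_poisson_glm(
        counts, np.ones((counts.size, 1)), np.log(exposure),
        prior_sd=prior_sd, seed=seed, chains=chains, warmup=warmup,
        draws=draws, coef_names=["alpha"])
    return post.coef("alpha")


@dataclass
class RateEstimate(PosteriorSummary):
    """A mutation rate posterior with explicit units."""

    per: str = "bp"   # "bp" -> /bp/mitosis, "genome" -> /genome/mitosis


def to_rate(alpha: PosteriorSummary, N: float | None = None,
            t: int = DEFAULT_TRANSFERS, m_draws=None, per: str = "bp",
            seed: int = 0) -> RateEstimate:
    """Convert an intercept posterior to a per-mitosis mutation rate.

    ``mu = exp(alpha) / (N * t * m)`` per bp, or ``exp(alpha) / (t * m)``
    per genome.  Draws of ``m`` are paired with the alpha draws by
    resampling so that mitosis-count uncertainty propagates.
    """
    if per not in ("bp", "genome"):
        raise ValueError(f"per must be 'bp' or 'genome', got {per!r}")
    if per == "bp" and (N is None or N <= 0):
        raise ValueError("per-bp rates need a positive callable-base total N")
    if m_draws is None:
        m_draws = np.array([DEFAULT_MITOSES_PER_TRANSFER])
    m_draws = np.asarray(m_draws, dtype=float).ravel()
    a = alpha.draws
    rng = np.random.default_rng(seed)
    if m_draws.size == a.size:
        m = m_draws
    elif m_draws.size == 1:
        m = np.full(a.size, m_draws[0])
    else:
        m = rng.choice(m_draws, size=a.size)
    denom = t * m if per == "genome" else N * t * m
    mu = np.exp(a) / denom
    unit = "mutations/bp/mitosis" if per == "bp" else "mutations/genome/mitosis"
    lo, hi = hpdi(mu)
    return RateEstimate(draws=mu, median=float(np.median(mu)), hpdi_low=lo,
                        hpdi_high=hi, unit=unit, rhat=alpha.rhat, per=per)


@dataclass
class RatioSummary(PosteriorSummary):
    """Posterior ratio of two rates; ``different`` flags 1 outside the HPDI."""

    different: bool = False


def rate_ratio(a: PosteriorSummary, b: PosteriorSummary,
               seed: int = 0) -> RatioSummary:
    """Draw-wise posterior ratio a/b with a different-from-one flag."""
    if isinstance(a, RateEstimate) and isinstance(b, RateEstimate):
        if a.unit != b.unit:
            raise ValueError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
    da, db = a.draws, b.draws
    if da.size != db.size:
        rng = np.random.default_rng(seed)
        db = rng.choice(db, size=da.size)
    ratio = da / db
    lo, hi = hpdi(ratio)
    return RatioSummary(draws=ratio, median=float(np.median(ratio)),
                        hpdi_low=lo, hpdi_high=hi,
                        different=not (lo <= 1.0 <= hi))


# ---------------------------------------------------------------------------
# window-level GC / chromatin-domain model

PREDICTOR_SETS = {
    "intercept": (),
    "gc": ("gc",),
    "domains": ("k9", "k27", "cen"),
    "gc_domains": ("gc", "k9", "k27", "cen"),
    "gc_k9_k27_cen_gcxk9": ("gc", "k9", "k27", "cen", "gc_k9"),
    "gc_k9_k27_cen_gcxk9_gcxk27": ("gc", "k9", "k27", "cen", "gc_k9", "gc_k27"),
}


@dataclass
class FittedRateModel:
    """Posterior of a window-level Poisson rate model.

    ``exp(X beta)`` is the per-bp per-mitosis mutation rate; the offset
    absorbed ``callable_bp * n_lines * t * m``.  GC enters standardized
    (mean 0, sd 1 over the fitted windows).
    """

    predictors: tuple[str, ...]
    posterior: PoissonGLMPosterior
    gc_mean: float
    gc_sd: float
    window_index: np.ndarray           # rows of the window table used
    name: str = ""

    def coef(self, name: str) -> PosteriorSummary:
        return self.posterior.coef(name)

    def design_matrix(self, windows: pd.DataFrame) -> np.ndarray:
        gc = (windows["gc_fraction"].to_numpy() - self.gc_mean) / self.gc_sd
        k9 = (windows["domain_label"] == "H3K9me3").to_numpy(float)
        k27 = (windows["domain_label"] == "H3K27me3").to_numpy(float)
        cen = windows["centromeric"].to_numpy(float)
        cols = {"gc": gc, "k9": k9, "k27": k27, "cen": cen,
                "gc_k9": gc * k9, "gc_k27": gc * k27}
        X = [np.ones(len(windows))]
        X += [cols[p] for p in self.predictors]
        return np.column_stack(X)

    def stratum_contrast(self, windows: pd.DataFrame, stratum: str,
                         reference: str = "euchromatin",
                         exclude_cen: bool = True) -> PosteriorSummary:
        """Posterior fold change of a domain's realized rate vs a reference.

        Computed as the draw-wise difference between the mean linear
        predictor over the windows of each stratum, so it reflects the
        rate at the strata's own GC compositions rather than a single
        coefficient; with a GC x domain interaction the two differ.
        """
        def rows(label):
            if label == "centromeric":
                m = windows["centromeric"].to_numpy()
            else:
                m = (windows["domain_label"] == label).to_numpy()
                if exclude_cen:
                    m &= ~windows["centromeric"].to_numpy()
            m &= np.isfinite(windows["gc_fraction"].to_numpy())
            if not m.any():
                raise ValueError(f"no windows in stratum {label!r}")
            return windows.loc[m]

        Xa = self.design_matrix(rows(stratum)).mean(axis=0)
        Xb = self.design_matrix(rows(reference)).mean(axis=0)
        diff = self.posterior.draws @ (Xa - Xb)
        return summarize(np.exp(diff))

    def predict_log_mu(self, windows: pd.DataFrame) -> np.ndarray:
        """Posterior-median natural-log per-bp per-mitosis rate per window."""
        X = self.design_matrix(windows)
        eta = self.posterior.linpred_draws(X, thin=10)
        return np.median(eta, axis=0)

    def elpd(self) -> float:
        return waic(self.posterior.pointwise_loglik())[0]


def fit_domain_gc_model(window_counts, window_table: pd.DataFrame,
                        design: ExperimentDesign,
                        predictors=("gc", "k9", "k27", "cen", "gc_k9"),
                        prior_sd_intercept: float = 10.0,
                        prior_sd_coef: float = 5.0,
                        seed: int = 0, chains: int = 4, warmup: int = 1000,
                        draws: int = 3000, name: str = "") -> FittedRateModel:
    """Fit the windowed mutation-rate model with a log-exposure offset.

    ``window_counts`` are mutation counts per window summed over lines;
    the exposure is ``callable_bp * n_lines * t * m`` (posterior median of
    m; its coefficient of variation is under 2%, so the simplification is
    immaterial at window level while `to_rate` keeps full propagation).
    Windows with zero callable bases or missing GC are dropped.
    """
    y = np.asarray(window_counts, dtype=float).ravel()
    if len(y) != len(window_table):
        raise ValueError("window_counts and window_table length mismatch")
    ok = (window_table["callable_bp"].to_numpy() > 0) & \
        np.isfinite(window_table["gc_fraction"].to_numpy())
    if not np.all(ok):
        import logging
        logging.getLogger(__name__).info(
            "dropping %d windows with no callable bases or missing GC",
            int((~ok).sum()))
    wt = window_table.loc[ok]
    y = y[ok]
    gc_raw = wt["gc_fraction"].to_numpy()
    gc_mean, gc_sd = float(gc_raw.mean()), float(gc_raw.std())
    if gc_sd == 0:
        gc_sd = 1.0
    model = FittedRateModel(
        predictors=tuple(predictors), posterior=None,  # type: ignore
        gc_mean=gc_mean, gc_sd=gc_sd,
        window_index=np.flatnonzero(ok),
        name=name or "+".join(("alpha",) + tuple(predictors)))
    X = model.design_matrix(wt)
    exposure = (wt["callable_bp"].to_numpy() * design.n_lines
                * design.t_transfers * design.m_median)
    prior_sd = np.full(X.shape[1], prior_sd_coef)
    prior_sd[0] = prior_sd_intercept
    post = sample_poisson_glm(
        y, X, np.log(exposure), prior_sd=prior_sd, seed=seed,
        chains=chains, warmup=warmup, draws=draws,
        coef_names=["intercept", *predictors])
    model.posterior = post
    return model


def model_weights(models: list[FittedRateModel]) -> pd.DataFrame:
    """WAIC-based pseudo-BMA weights for models fitted to identical rows."""
    ref = models[0].posterior.y
    for m in models[1:]:
        if m.posterior.y.shape != ref.shape or not np.array_equal(
                m.posterior.y, ref):
            raise ValueError("models were not fitted to identical data rows")
    elpds = [m.elpd() for m in models]
    w = pseudo_bma_weights(elpds)
    out = pd.DataFrame({
        "model": [m.name for m in models],
        "elpd_waic": elpds,
        "weight": w,
    })
    return out.sort_values("weight", ascending=False, ignore_index=True)
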