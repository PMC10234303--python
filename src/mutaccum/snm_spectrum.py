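"""Single-nucleotide mutation spectra and sequence-context effects.

Because the mutated strand is unknown, substitutions are collapsed into 6
base-pair classes (C:G→T:A, A:T→G:C, C:G→A:T, C:G→G:C, A:T→C:G, A:T→T:A)
and trinucleotide contexts into 32 strand-collapsed classes.  Relative
rates are frequency-corrected: each class count gets a Poisson posterior
with the source base-pair (or trinucleotide) census times the mitosis
exposure as offset, and the corrected rates are renormalized draw-wise to
sum to one, so equal mutability puts every class at 1/6 (or 1/32).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import PosteriorSummary, hpdi, rw_metropolis, summarize
from .genome_context import (
    SNM_CLASSES, TRINUC_CLASSES, CompositionTable,
    trinuc_focal_pair, trinuc_pyrimidine_context,
)
from .ma_rates import ExperimentDesign, RatioSummary, fit_poisson_rate

logger = logging.getLogger(__name__)

__all__ = [
    "classify_snm", "SpectrumCounts", "spectrum_counts", "RelativeRates",
    "relative_rates", "ts_tv", "domain_spectrum_ratio", "TrinucRates",
    "trinuc_model", "FlankingModelFit", "flanking_effects",
]

_CLASS_OF = {
    ("C", "T"): "C:G→T:A", ("G", "A"): "C:G→T:A",
    ("A", "G"): "A:T→G:C", ("T", "C"): "A:T→G:C",
    ("C", "A"): "C:G→A:T", ("G", "T"): "C:G→A:T",
    ("C", "G"): "C:G→G:C", ("G", "C"): "C:G→G:C",
    ("A", "C"): "A:T→C:G", ("T", "G"): "A:T→C:G",
    ("A", "T"): "A:T→T:A", ("T", "A"): "A:T→T:A",
}

TRANSITIONS = ("C:G→T:A", "A:T→G:C")
TRANSVERSIONS = ("C:G→A:T", "C:G→G:C", "A:T→C:G", "A:T→T:A")


def classify_snm(ref: str, alt: str) -> str:
    """Map a substitution to its strand-collapsed base-pair class."""
    key = (str(ref).upper(), str(alt).upper())
    if key not in _CLASS_OF:
        raise ValueError(f"not a valid substitution: {ref!r} -> {alt!r}")
    return _CLASS_OF[key]


def _source_pair(cls: str) -> str:
    return cls.split("→")[0]


@dataclass
class SpectrumCounts:
    """Per-stratum counts of the 6 SNM classes and source base pairs."""

    counts: pd.DataFrame   # strata x 6 classes
    pairs: pd.DataFrame    # strata x [at_pairs, cg_pairs]

    def __post_init__(self):
        if list(self.counts.columns) != list(SNM_CLASSES):
            raise ValueError("counts columns must be the 6 SNM classes")

    def total(self, stratum: str) -> int:
        return int(self.counts.loc[stratum].sum())


def spectrum_counts(annotated: pd.DataFrame, composition: CompositionTable,
                    strata=("genome", "euchromatin", "H3K9me3", "H3K27me3",
                            "centromeric", "H3K9me3_ex_cen")) -> SpectrumCounts:
    """Tabulate SNM class counts per stratum from an annotated mutation table."""
    snm = annotated[annotated["kind"] == "SNM"]
    rows = {}
    for stratum in strata:
        if stratum == "genome":
            sel = snm
        elif stratum == "centromeric":
            sel = snm[snm["centromeric"]]
        elif stratum == "H3K9me3_ex_cen":
            sel = snm[(snm["domain_label"] == "H3K9me3") & ~snm["centromeric"]]
        else:
            sel = snm[snm["domain_label"] == stratum]
        counts = sel["snm_class"].value_counts()
        rows[stratum] = [int(counts.get(c, 0)) for c in SNM_CLASSES]
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(SNM_CLASSES))
    pairs = composition.base_pairs.loc[list(strata), ["at_pairs", "cg_pairs"]]
    return SpectrumCounts(counts=counts, pairs=pairs)


@dataclass
class RelativeRates:
    """Frequency-corrected relative rates for the 6 SNM classes.

    ``raw_draws`` are per-class corrected rates (count / (census *
    exposure) posteriors); ``norm_draws`` are renormalized draw-wise to
    sum to 1.
    """

    stratum: str
    table: pd.DataFrame            # class, count, census, median, lo, hi
    raw_draws: np.ndarray = field(repr=False)    # (6, S)
    norm_draws: np.ndarray = field(repr=False)   # (6, S)

    def summary(self, cls: str) -> PosteriorSummary:
        i = SNM_CLASSES.index(cls)
        return summarize(self.norm_draws[i])


def _class_rate_draws(counts: dict, offsets: dict, seed: int,
                      chains: int, warmup: int, draws: int) -> np.ndarray:
    """(6, S) posterior draws of frequency-corrected per-class rates."""
    out = []
    for j, cls in enumerate(SNM_CLASSES):
        count, offset = counts[cls], offsets[cls]
        if offset <= 0:
            if count > 0:
                raise ValueError(
                    f"class {cls}: nonzero count with zero census")
            out.append(np.zeros(chains * draws))
            continue
        alpha = fit_poisson_rate([count], exposure=[offset],
                                 seed=seed + 13 * j, chains=chains,
                                 warmup=warmup, draws=draws)
        out.append(np.exp(alpha.draws))
    return np.array(out)


def relative_rates(spec: SpectrumCounts, exposure: float,
                   stratum: str = "genome", seed: int = 0,
                   chains: int = 4, warmup: int = 1000,
                   draws: int = 3000) -> RelativeRates:
    """Posterior relative rates of the 6 classes, corrected for base-pair
    frequencies and normalized so equal mutability gives 1/6 per class.

    ``exposure`` is the per-base mitosis exposure, ``n_lines * t * m``.
    """
    counts = {c: int(spec.counts.loc[stratum, c]) for c in SNM_CLASSES}
    pair_bp = {"A:T": float(spec.pairs.loc[stratum, "at_pairs"]),
               "C:G": float(spec.pairs.loc[stratum, "cg_pairs"])}
    offsets = {c: pair_bp[_source_pair(c)] * exposure for c in SNM_CLASSES}
    raw = _class_rate_draws(counts, offsets, seed, chains, warmup, draws)
    norm = raw / raw.sum(axis=0, keepdims=True)
    rows = []
    for i, c in enumerate(SNM_CLASSES):
        lo, hi = hpdi(norm[i])
        rows.append({"class": c, "count": counts[c],
                     "census_bp": pair_bp[_source_pair(c)],
                     "median": float(np.median(norm[i])),
                     "hpdi_low": lo, "hpdi_high": hi})
    return RelativeRates(stratum=stratum, table=pd.DataFrame(rows),
                         raw_draws=raw, norm_draws=norm)


def ts_tv(spec: SpectrumCounts, exposure: float, stratum: str = "genome",
          corrected: bool = True, seed: int = 0, chains: int = 4,
          warmup: int = 1000, draws: int = 3000) -> PosteriorSummary:
    """Posterior transition/transversion rate ratio for a stratum.

    With ``corrected=True`` (default) class rates are frequency-corrected
    before summing; otherwise raw counts are used with equal offsets.
    """
    counts = {c: int(spec.counts.loc[stratum, c]) for c in SNM_CLASSES}
    if sum(counts[c] for c in TRANSVERSIONS) == 0:
        raise ValueError("no transversions observed; Ts/Tv undefined")
    if corrected:
        pair_bp = {"A:T": float(spec.pairs.loc[stratum, "at_pairs"]),
                   "C:G": float(spec.pairs.loc[stratum, "cg_pairs"])}
        offsets = {c: pair_bp[_source_pair(c)] * exposure
                   for c in SNM_CLASSES}
    else:
        offsets = {c: exposure for c in SNM_CLASSES}
    raw = _class_rate_draws(counts, offsets, seed, chains, warmup, draws)
    idx = {c: i for i, c in enumerate(SNM_CLASSES)}
    ts = raw[[idx[c] for c in TRANSITIONS]].sum(axis=0)
    tv = raw[[idx[c] for c in TRANSVERSIONS]].sum(axis=0)
    return summarize(ts / tv)


def _trinuc_weights(trinuc_counts: pd.Series, trinuc_census: pd.Series
                    ) -> pd.Series:
    """Genome-wide per-trinucleotide mutability weights (rate per bp)."""
    w = trinuc_counts.reindex(TRINUC_CLASSES).fillna(0.0) / \
        trinuc_census.reindex(TRINUC_CLASSES).replace(0, np.nan)
    return w.fillna(0.0)


def domain_spectrum_ratio(spec: SpectrumCounts, domain_a: str, domain_b: str,
                          exposure: float, correction: str = "nucleotide",
                          composition: CompositionTable | None = None,
                          genome_trinuc_counts: pd.Series | None = None,
                          seed: int = 0, chains: int = 4, warmup: int = 1000,
                          draws: int = 3000) -> pd.DataFrame:
    """Per-class ratio of relative (frequency-corrected, within-domain
    normalized) rates in domain A over B.

    ``correction='nucleotide'`` uses source base-pair censuses as offsets;
    ``correction='trinucleotide'`` weights each domain's trinucleotide
    census by genome-wide per-trinucleotide mutability, so that domains
    with mutability-skewed trinucleotide composition are compared fairly.
    Classes with zero counts in both domains are flagged undefined.
    """
    if correction not in ("nucleotide", "trinucleotide"):
        raise ValueError(f"unknown correction {correction!r}")

    def offsets_for(domain):
        if correction == "nucleotide":
            pair_bp = {"A:T": float(spec.pairs.loc[domain, "at_pairs"]),
                       "C:G": float(spec.pairs.loc[domain, "cg_pairs"])}
            return {c: pair_bp[_source_pair(c)] * exposure
                    for c in SNM_CLASSES}
        if composition is None or genome_trinuc_counts is None:
            raise ValueError("trinucleotide correction needs composition and "
                             "genome-wide trinucleotide counts")
        census = composition.trinuc.loc[domain]
        w = _trinuc_weights(genome_trinuc_counts,
                            composition.trinuc.loc["genome"])
        out = {}
        for c in SNM_CLASSES:
            pair = _source_pair(c)
            classes = [t for t in TRINUC_CLASSES
                       if trinuc_focal_pair(t) == pair]
            out[c] = float(sum(census[t] * w[t] for t in classes)) * exposure
        return out

    counts_a = {c: int(spec.counts.loc[domain_a, c]) for c in SNM_CLASSES}
    counts_b = {c: int(spec.counts.loc[domain_b, c]) for c in SNM_CLASSES}
    ra = _class_rate_draws(counts_a, offsets_for(domain_a), seed,
                           chains, warmup, draws)
    rb = _class_rate_draws(counts_b, offsets_for(domain_b), seed + 1,
                           chains, warmup, draws)
    # compare spectrum shapes: normalize the corrected rates within each
    # domain so the overall domain rate fold cancels
    ra = ra / ra.sum(axis=0, keepdims=True)
    rb = rb / rb.sum(axis=0, keepdims=True)
    rows = []
    for i, c in enumerate(SNM_CLASSES):
        if counts_a[c] == 0 and counts_b[c] == 0:
            rows.append({"class": c, "median": np.nan, "hpdi_low": np.nan,
                         "hpdi_high": np.nan, "different": False,
                         "undefined": True})
            continue
        ratio = ra[i] / rb[i]
        lo, hi = hpdi(ratio)
        rows.append({"class": c, "median": float(np.median(ratio)),
                     "hpdi_low": lo, "hpdi_high": hi,
                     "different": not (lo <= 1.0 <= hi), "undefined": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 32-class trinucleotide model

@dataclass
class TrinucRates:
    """Relative rates for the 32 trinucleotide classes + domain folds."""

    table: pd.DataFrame                # class, count, census, median, lo, hi
    domain_effects: dict               # name -> PosteriorSummary of the fold
    class_draws: np.ndarray = field(repr=False)   # (32, S) normalized
    log_class_draws: np.ndarray = field(repr=False)  # (32, S) raw log rates


def trinuc_model(counts32: pd.DataFrame, census32: pd.DataFrame,
                 design: ExperimentDesign, seed: int = 0, chains: int = 4,
                 warmup: int = 1000, draws: int = 3000) -> TrinucRates:
    """Poisson model of 32 trinucleotide class effects + domain effects.

    ``counts32`` and ``census32`` are (domain stratum x 32) tables over the
    mutually exclusive strata euchromatin / H3K9me3_ex_cen / centromeric /
    H3K27me3 (missing strata are allowed).  The linear predictor has one
    effect per class (no intercept) plus H3K9me3, centromere and H3K27me3
    indicators — no class-by-domain interactions.  Offsets are
    ``log(census * n_lines * t * m)``.  Relative class rates are
    normalized draw-wise to sum to 1 (equal mutability = 1/32).
    """
    from ._stats import sample_poisson_glm

    strata = [s for s in ("euchromatin", "H3K9me3_ex_cen", "centromeric",
                          "H3K27me3") if s in counts32.index]
    rows_y, rows_X, rows_off = [], [], []
    kept_classes = [c for c in TRINUC_CLASSES
                    if (census32.loc[strata, c] > 0).any()]
    dropped = set(TRINUC_CLASSES) - set(kept_classes)
    if dropped:
        logger.warning("dropping structurally empty trinucleotide classes: %s",
                       sorted(dropped))
    p_class = len(kept_classes)
    for stratum in strata:
        k9 = 1.0 if stratum in ("H3K9me3_ex_cen", "centromeric") else 0.0
        cen = 1.0 if stratum == "centromeric" else 0.0
        k27 = 1.0 if stratum == "H3K27me3" else 0.0
        for j, cls in enumerate(kept_classes):
            census = float(census32.loc[stratum, cls])
            if census <= 0:
                continue
            x = np.zeros(p_class + 3)
            x[j] = 1.0
            x[p_class:] = [k9, cen, k27]
            rows_y.append(float(counts32.loc[stratum, cls]))
            rows_X.append(x)
            rows_off.append(np.log(census * design.n_lines
                                   * design.t_transfers * design.m_median))
    y = np.array(rows_y)
    X = np.array(rows_X)
    off = np.array(rows_off)
    prior_sd = np.concatenate([np.full(p_class, 10.0), np.full(3, 5.0)])
    post = sample_poisson_glm(
        y, X, off, prior_sd=prior_sd, seed=seed, chains=chains,
        warmup=warmup, draws=draws,
        coef_names=[*kept_classes, "k9", "cen", "k27"])
    log_rates = post.draws[:, :p_class].T          # (32, S)
    rates = np.exp(log_rates)
    norm = rates / rates.sum(axis=0, keepdims=True)
    tab_rows = []
    for j, cls in enumerate(kept_classes):
        lo, hi = hpdi(norm[j])
        tab_rows.append({
            "class": cls,
            "count": int(counts32.loc[strata, cls].sum()),
            "census_bp": float(census32.loc[strata, cls].sum()),
            "median": float(np.median(norm[j])),
            "hpdi_low": lo, "hpdi_high": hi,
        })
    effects = {}
    for name in ("k9", "cen", "k27"):
        fold = np.exp(post.coef(name).draws)
        effects[name] = summarize(fold)
    return TrinucRates(table=pd.DataFrame(tab_rows), domain_effects=effects,
                       class_draws=norm, log_class_draws=log_rates)


# ---------------------------------------------------------------------------
# flanking-base measurement-error regression

@dataclass
class FlankingModelFit:
    """Flanking-base effects on log relative trinucleotide mutation rates.

    Coefficients: ``beta_b`` (focal C:G vs A:T), ``beta_5`` / ``beta_3``
    (5'/3' flank C:G vs A:T) and the interactions ``beta_I5`` / ``beta_I3``
    of a C:G flank when the focal pair is C:G.  The response of each class
    is its posterior mean log relative rate with its posterior sd as known
    measurement error; a residual scale is estimated alongside.
    """

    coefficients: dict                 # name -> PosteriorSummary
    residual_scale: PosteriorSummary
    design: pd.DataFrame
    significant: dict                  # name -> bool (0 outside 95% HPDI)


FLANKING_COEFS = ["intercept", "beta_b", "beta_5", "beta_3",
                  "beta_I5", "beta_I3"]


def flanking_design(classes) -> pd.DataFrame:
    """Indicator design for focal/flanking base-pair identity per class.

    Each collapsed class is oriented with its pyrimidine (C or T) focal
    base so that 5' and 3' are defined consistently across strands.
    """
    rows = []
    for cls in classes:
        ctx = trinuc_pyrimidine_context(cls)
        b = 1.0 if ctx[1] == "C" else 0.0
        f5 = 1.0 if ctx[0] in "CG" else 0.0
        f3 = 1.0 if ctx[2] in "CG" else 0.0
        rows.append({"class": cls, "intercept": 1.0, "beta_b": b,
                     "beta_5": f5, "beta_3": f3,
                     "beta_I5": b * f5, "beta_I3": b * f3})
    return pd.DataFrame(rows).set_index("class")


def flanking_effects(trinuc: TrinucRates, seed: int = 0, chains: int = 4,
                     warmup: int = 1000, draws: int = 3000,
                     sd_floor: float = 1e-3) -> FlankingModelFit:
    """Measurement-error regression of log relative rate on flank identity.

    The response for each trinucleotide class is its posterior mean log
    relative rate; the class's posterior sd enters as known measurement
    error.
    """
    classes = list(trinuc.table["class"])
    log_rel = np.log(trinuc.class_draws)
    return flanking_regression(classes, log_rel.mean(axis=1),
                               log_rel.std(axis=1), seed=seed, chains=chains,
                               warmup=warmup, draws=draws, sd_floor=sd_floor)


def flanking_regression(classes, z, sd, seed: int = 0, chains: int = 4,
                        warmup: int = 1000, draws: int = 3000,
                        sd_floor: float = 1e-3) -> FlankingModelFit:
    """Fit the flanking-base model to responses ``z`` with measurement sd.

    ``z_t ~ Normal(X_t beta, sd_t^2 + s^2)`` with a half-normal prior on
    the residual scale ``s`` and N(0, 2) priors on the coefficients.
    """
    z = np.asarray(z, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < sd_floor):
        logger.info("flooring %d degenerate measurement sds at %g",
                    int((sd < sd_floor).sum()), sd_floor)
        sd = np.maximum(sd, sd_floor)
    des = flanking_design(classes)
    X = des[FLANKING_COEFS].to_numpy()
    prior_sd_beta = 2.0
    resid_prior = 0.5

    def logpost(theta):
        beta, log_s = theta[:-1], theta[-1]
        s2 = np.exp(2 * log_s)
        var = sd**2 + s2
        resid = z - X @ beta
        ll = -0.5 * np.sum(resid**2 / var + np.log(var))
        lp = -0.5 * np.sum((beta / prior_sd_beta) ** 2)
        lp += -0.5 * (np.exp(log_s) / resid_prior) ** 2 + log_s
        return ll + lp

    x0 = np.concatenate([np.linalg.lstsq(X, z, rcond=None)[0], [-2.0]])
    pooled, rhat = rw_metropolis(logpost, x0, seed=seed, chains=chains,
                                 warmup=warmup, draws=draws,
                                 step=np.full(x0.size, 0.05))
    coefs, signif = {}, {}
    for j, name in enumerate(FLANKING_COEFS):
        s = summarize(pooled[:, j], rhat=float(rhat[j]))
        coefs[name] = s
        signif[name] = not (s.hpdi_low <= 0.0 <= s.hpdi_high)
    resid = summarize(np.exp(pooled[:, -1]))
    return FlankingModelFit(coefficients=coefs, residual_scale=resid,
                            design=des, significant=signif)
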