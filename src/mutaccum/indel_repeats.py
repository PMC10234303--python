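"""Insertion/deletion classification by repeat context and indel rate models.

Indels are assigned exactly one category — homopolymer, microsatellite,
other_repeat or nonrepeat — with homopolymers taking precedence.  Rates
are per-genome per-mitosis Poisson posteriors; homopolymer slippage is
modelled per locus with a shared length slope for A:T and C:G tracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import PosteriorSummary, summarize
from .genome_context import GenomeAnnotation
from .ma_rates import (
    ExperimentDesign, RateEstimate, RatioSummary, fit_poisson_rate,
    rate_ratio, to_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "classify_indels", "indel_rate_table", "HomopolymerRateFit",
    "homopolymer_model", "domain_indel_rates",
]

CATEGORIES = ["homopolymer", "microsatellite", "other_repeat", "nonrepeat"]


def _in_microsatellite(seq: str, pos: int, length: int) -> bool:
    """True if the indel changes whole units of a 2-6 bp tandem repeat.

    A tandem repeat is >= 3 contiguous copies of a motif covering the
    affected position, and the indel length is a multiple of the motif
    length.
    """
    for mlen in range(2, 7):
        if length % mlen != 0:
            continue
        for anchor in range(max(0, pos - mlen + 1), pos + 1):
            motif = seq[anchor : anchor + mlen]
            if len(motif) < mlen or len(set(motif)) == 1:
                continue
            # extend copies left and right of the anchor
            s = anchor
            while s - mlen >= 0 and seq[s - mlen : s] == motif:
                s -= mlen
            e = anchor + mlen
            while e + mlen <= len(seq) and seq[e : e + mlen] == motif:
                e += mlen
            if (e - s) // mlen >= 3 and s <= pos and pos + 1 <= e:
                return True
    return False


def classify_indels(annotated: pd.DataFrame, catalog: pd.DataFrame,
                    ann: GenomeAnnotation,
                    other_repeats: dict | None = None) -> pd.DataFrame:
    """Classify every insertion/deletion record by repeat context.

    ``catalog`` is the homopolymer catalog (minimum length 5 by default).
    A deletion is homopolymer-class when the deleted bases lie inside a
    catalog run; an insertion when its insertion point is strictly inside
    a run and the inserted sequence consists of the run base.  Otherwise
    3-bp-motif-style tandem changes are microsatellite, intervals in the
    optional ``other_repeats`` BED dict are other_repeat, and the rest
    nonrepeat.
    """
    indels = annotated[annotated["kind"].isin(["insertion", "deletion"])].copy()
    runs_by_contig = {}
    if not catalog.empty:
        for contig, grp in catalog.groupby("contig"):
            runs_by_contig[contig] = (
                grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp["base"].to_numpy(), grp["length"].to_numpy())

    cats, ptypes, plens = [], [], []
    for _, rec in indels.iterrows():
        contig, pos = rec["contig"], int(rec["pos"])
        length = int(rec["length"])
        seq = ann.sequence.contigs[contig]
        category, ptype, plen = "nonrepeat", "none", 0

        runs = runs_by_contig.get(contig)
        if runs is not None:
            starts, ends, bases, lens = runs
            j = np.searchsorted(starts, pos, side="right") - 1
            if j >= 0 and pos < ends[j]:
                base = bases[j]
                if rec["kind"] == "deletion":
                    inside = pos + length <= ends[j] and \
                        seq[pos : pos + length] == base * length
                else:
                    ins = str(rec.get("alt", "") or "")
                    ins_seq = ins[1:] if len(ins) > 1 else ins
                    inside = (starts[j] < pos < ends[j]
                              and (not ins_seq or set(ins_seq) == {base}))
                if inside:
                    category = "homopolymer"
                    ptype = "A:T" if base in "AT" else "C:G"
                    plen = int(lens[j])
        if category == "nonrepeat" and _in_microsatellite(seq, pos, length):
            category = "microsatellite"
        if category == "nonrepeat" and other_repeats:
            for s, e in other_repeats.get(contig, []):
                if s <= pos < e:
                    category = "other_repeat"
                    break
        cats.append(category)
        ptypes.append(ptype)
        plens.append(plen)

    indels["category"] = cats
    indels["polymer_type"] = ptypes
    indels["polymer_length"] = plens
    return indels


def _per_line_counts(records: pd.DataFrame, design: ExperimentDesign
                     ) -> np.ndarray:
    """Counts per MA line as a dense vector (absent lines count zero)."""
    counts = records.groupby("line_id").size()
    if len(counts) > design.n_lines:
        raise ValueError(
            f"{len(counts)} line ids exceed design n_lines={design.n_lines}")
    out = np.zeros(design.n_lines)
    out[: len(counts)] = counts.to_numpy()
    return out


SUBSETS = {
    "all": lambda df: df,
    "excl_repeats": lambda df: df[df["category"] == "nonrepeat"],
    "repeats_only": lambda df: df[df["category"] != "nonrepeat"],
}


def indel_rate_table(records: pd.DataFrame, design: ExperimentDesign,
                     subsets=("all", "excl_repeats", "repeats_only"),
                     seed: int = 0, chains: int = 4, warmup: int = 1000,
                     draws: int = 3000) -> dict:
    """Deletion/insertion per-genome rates and their ratio per subset.

    Returns {subset: {"deletion": RateEstimate, "insertion": RateEstimate,
    "ratio": RatioSummary (deletion/insertion), "mean_length": {...},
    "net_bp": int}}.
    """
    out = {}
    for si, name in enumerate(subsets):
        sel = SUBSETS[name](records)
        if len(sel) == 0:
            raise ValueError(f"subset {name!r} is empty")
        rates = {}
        for ki, kind in enumerate(("deletion", "insertion")):
            sub = sel[sel["kind"] == kind]
            counts = _per_line_counts(sub, design)
            if counts.sum() == 0:
                logger.warning("no %s records in subset %s; rate is "
                               "prior-dominated", kind, name)
            alpha = fit_poisson_rate(counts, seed=seed + 7 * si + ki,
                                     chains=chains, warmup=warmup,
                                     draws=draws)
            rates[kind] = to_rate(alpha, t=design.t_transfers,
                                  m_draws=design.m_draws, per="genome",
                                  seed=seed + 7 * si + ki)
        dels = sel[sel["kind"] == "deletion"]["length"]
        ins = sel[sel["kind"] == "insertion"]["length"]
        out[name] = {
            "deletion": rates["deletion"],
            "insertion": rates["insertion"],
            "ratio": rate_ratio(rates["deletion"], rates["insertion"]),
            "mean_length": {"deletion": float(dels.mean()) if len(dels) else np.nan,
                            "insertion": float(ins.mean()) if len(ins) else np.nan},
            "net_bp": int(ins.sum() - dels.sum()),
        }
    return out


@dataclass
class HomopolymerRateFit:
    """Slippage-rate model over homopolymer type and length.

    Per-locus Poisson regression with predictors: A:T-type indicator and a
    length slope shared by both types.  ``rate_at`` / ``rate_cg`` are
    marginal per-locus per-mitosis rates; ``type_ratio`` is A:T over C:G.
    """

    intercept: PosteriorSummary
    type_effect: PosteriorSummary      # log fold A:T vs C:G
    length_slope: PosteriorSummary     # per extra base of tract length
    rate_at: RateEstimate
    rate_cg: RateEstimate
    type_ratio: RatioSummary


def homopolymer_model(records: pd.DataFrame, hp_census: pd.DataFrame,
                      design: ExperimentDesign, max_length: int = 15,
                      seed: int = 0, chains: int = 4, warmup: int = 1000,
                      draws: int = 3000) -> HomopolymerRateFit:
    """Fit the homopolymer type x length slippage model.

    ``records`` must be classified indels; ``hp_census`` has columns
    polymer_type, length, n_loci.  Length strata above ``max_length`` are
    pooled (at their census-weighted mean length) to avoid empty cells.
    Offsets are ``log(n_loci * n_lines * t * m)``.
    """
    from ._stats import sample_poisson_glm

    hp = records[records["category"] == "homopolymer"]
    census = hp_census.copy()
    census["length_cap"] = census["length"].clip(upper=max_length)
    exposure = design.n_lines * design.t_transfers * design.m_median

    rows = []
    for (ptype, lcap), grp in census.groupby(["polymer_type", "length_cap"]):
        n_loci = int(grp["n_loci"].sum())
        if n_loci == 0:
            continue
        mean_len = float(np.average(grp["length"], weights=grp["n_loci"]))
        sel = hp[(hp["polymer_type"] == ptype)
                 & (hp["polymer_length"].clip(upper=max_length) == lcap)]
        rows.append({"polymer_type": ptype, "length": mean_len,
                     "n_loci": n_loci, "count": len(sel)})
    tab = pd.DataFrame(rows)
    if tab.empty:
        raise ValueError("no homopolymer strata with loci")
    X = np.column_stack([
        np.ones(len(tab)),
        (tab["polymer_type"] == "A:T").to_numpy(float),
        tab["length"].to_numpy() - 5.0,
    ])
    post = sample_poisson_glm(
        tab["count"].to_numpy(), X, np.log(tab["n_loci"].to_numpy() * exposure),
        prior_sd=[10.0, 5.0, 5.0], seed=seed, chains=chains, warmup=warmup,
        draws=draws, coef_names=["intercept", "at_type", "length"])

    # marginal per-type per-locus rates
    marg = {}
    for i, ptype in enumerate(("A:T", "C:G")):
        n_loci = int(census.loc[census["polymer_type"] == ptype,
                                "n_loci"].sum())
        count = int(len(hp[hp["polymer_type"] == ptype]))
        alpha = fit_poisson_rate([count], exposure=[n_loci * design.n_lines],
                                 seed=seed + 31 + i, chains=chains,
                                 warmup=warmup, draws=draws)
        # exp(alpha) is per-locus per-line over the experiment; convert
        marg[ptype] = to_rate(alpha, t=design.t_transfers,
                              m_draws=design.m_draws, per="genome",
                              seed=seed + 31 + i)
        marg[ptype].unit = "mutations/locus/mitosis"
    return HomopolymerRateFit(
        intercept=post.coef("intercept"),
        type_effect=post.coef("at_type"),
        length_slope=post.coef("length"),
        rate_at=marg["A:T"], rate_cg=marg["C:G"],
        type_ratio=rate_ratio(marg["A:T"], marg["C:G"]),
    )


def domain_indel_rates(records: pd.DataFrame, design: ExperimentDesign,
                       composition, seed: int = 0, chains: int = 4,
                       warmup: int = 1000, draws: int = 3000) -> pd.DataFrame:
    """Per-domain per-bp deletion and insertion rates and folds vs euchromatin.

    Deletions are reported both for all records and excluding repeats;
    empty-domain folds are flagged undefined.
    """
    strata = ["euchromatin", "H3K9me3", "H3K27me3", "centromeric"]
    rows = []
    variants = [("deletion", "all"), ("deletion", "excl_repeats"),
                ("insertion", "all")]
    for vi, (kind, subset) in enumerate(variants):
        sel = SUBSETS[subset](records)
        sel = sel[sel["kind"] == kind]
        rates = {}
        for si, stratum in enumerate(strata):
            if stratum == "centromeric":
                sub = sel[sel["centromeric"]]
            else:
                sub = sel[sel["domain_label"] == stratum]
                if stratum == "H3K9me3":
                    pass  # includes centromeric bases, as in the domain label
            bp = float(composition.base_pairs.loc[stratum, "callable_bp"])
            exposure = bp * design.n_lines * design.t_transfers * design.m_median
            alpha = fit_poisson_rate([len(sub)], exposure=[exposure],
                                     seed=seed + 101 * vi + si, chains=chains,
                                     warmup=warmup, draws=draws)
            rates[stratum] = summarize(np.exp(alpha.draws))
        for stratum in strata:
            if stratum == "euchromatin":
                continue
            fold = rate_ratio(rates[stratum], rates["euchromatin"])
            rows.append({
                "kind": kind, "subset": subset, "domain": stratum,
                "rate_median": rates[stratum].median,
                "fold_vs_eu": fold.median,
                "fold_low": fold.hpdi_low, "fold_high": fold.hpdi_high,
                "different": fold.different,
            })
    return pd.DataFrame(rows)
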