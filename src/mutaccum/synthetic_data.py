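"""Synthetic genomes, mutation-accumulation experiments and population SNPs.

The generator emulates the structure of the real study system at desk
scale: a multi-contig genome whose H3K9me3 / centromeric blocks are
low-GC and whose euchromatin is high-GC (the two GC distributions barely
overlap), Poisson mutation counts per line with domain-specific rates
(~10x higher in H3K9me3), domain-specific 6-class substitution spectra,
homopolymer tracts with length-dependent slippage indels, and per-window
polymorphism proportional to the local mutation rate with per-call
missingness.

Default rates are the study's: euchromatic SNM rate 2.46e-10 and H3K9me3
rate 2.43e-9 /bp/mitosis, an H3K27me3 fold of 1.4, homopolymer per-locus
rates of 1.79e-8 (A:T) and 8.15e-9 (C:G) /locus/mitosis, 39 lines, 40
transfers and 25.375 mitoses per transfer.  The default genome is 2 Mb
over 4 contigs, and per-bp rates are multiplied by ``rate_scale``
(default: 41.1 Mb / simulated length) so that expected mutation counts —
and hence posterior widths — match the real experiment (~30 per line).

Every public entry point is deterministic for a fixed seed and returns a
sidecar dict recording the generating parameters for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import genome_context as gc_mod
from .genome_context import (
    EU, K9, K27, LABELS, GenomeAnnotation, GenomeSequence, DomainPartition,
    SNM_CLASSES, merge_intervals,
)
from .ma_rates import ExperimentDesign, NucleiCounts, GENOME_SIZE

__all__ = [
    "SimConfig", "simulate_genome", "simulate_ma_experiment",
    "simulate_population", "simulate_nuclei_counts", "write_fasta",
    "write_bed", "write_mutations_tsv", "write_vcf", "design_from_config",
]

# 6-class spectrum weights (relative rates per source base pair, summing
# to 1) chosen to realize euchromatic Ts/Tv ~1.49 with the A:T→G:C over
# C:G→T:A transition ratio at 1.23, and H3K9me3 Ts/Tv ~0.93 with C:G→G:C
# transversions enriched twofold.
EU_SPECTRUM = {
    "C:G→T:A": 0.2684, "A:T→G:C": 0.3302, "C:G→A:T": 0.1004,
    "C:G→G:C": 0.1004, "A:T→C:G": 0.1004, "A:T→T:A": 0.1004,
}
K9_SPECTRUM = {
    "C:G→T:A": 0.2409, "A:T→G:C": 0.2409, "C:G→A:T": 0.1036,
    "C:G→G:C": 0.2073, "A:T→C:G": 0.1036, "A:T→T:A": 0.1036,
}


@dataclass
class SimConfig:
    """Generating parameters for the synthetic study system."""

    seed: int = 0
    contig_lengths: tuple = (600_000, 500_000, 500_000, 400_000)
    k9_fraction: float = 0.20
    k27_fraction: float = 0.10
    cen_within_k9: float = 0.30
    gc_targets: dict = field(default_factory=lambda: {
        "euchromatin": 0.54, "H3K9me3": 0.38, "H3K27me3": 0.50})
    # SNM rates, /bp/mitosis (before desk-scale multiplication)
    snm_rate_eu: float = 2.46e-10
    snm_rate_k9: float = 2.43e-9
    k27_fold: float = 1.4
    cen_fold: float = 1.5          # additional fold on top of H3K9me3
    spectrum: dict = field(default_factory=lambda: {
        "euchromatin": dict(EU_SPECTRUM), "H3K9me3": dict(K9_SPECTRUM),
        "H3K27me3": dict(EU_SPECTRUM)})
    # homopolymers: planted tract density and per-locus slippage rates
    planted_hp_per_kb: float = 0.5
    hp_rate_at: float = 1.79e-8    # /locus/mitosis at reference length 5
    hp_rate_cg: float = 8.15e-9
    hp_length_slope: float = 0.25  # shared log-rate increase per extra base
    hp_insertion_frac: float = 0.65
    # microsatellites
    planted_ms_per_kb: float = 0.1
    ms_rate: float = 4.0e-9        # /locus/mitosis
    # non-repeat indels, /genome/mitosis
    del_nonrepeat_rate: float = 7.5e-4
    ins_nonrepeat_rate: float = 2.5e-4
    translocation_rate: float = 1.19e-4
    complex_rate: float = 5.42e-12   # /bp/mitosis
    # experiment design
    n_lines: int = 39
    t_transfers: int = 40
    m_per_transfer: float = 1015 / 40
    rate_scale: float | None = None  # default: 41.1 Mb / simulated length
    # population sample
    n_strains: int = 57
    theta_slope: float = 0.0096      # theta per log10(mu)
    theta_intercept: float = 0.0946  # euchromatin theta ~0.015 at defaults
    missing_rate: float = 0.10
    # nuclei counting
    true_m: float = 25.375
    phase_fractions: tuple = (0.45, 0.35, 0.20)
    nuclei_replicates: int = 6
    nuclei_base_count: float = 200.0
    nuclei_cv: float = 0.05

    def scale(self) -> float:
        if self.rate_scale is not None:
            return self.rate_scale
        return GENOME_SIZE / sum(self.contig_lengths)

    @property
    def total_mitoses(self) -> float:
        return self.t_transfers * self.m_per_transfer

    def domain_rate(self, label: str, centromeric: bool = False) -> float:
        """Scaled SNM rate (/bp/mitosis) for a domain stratum."""
        base = {
            "euchromatin": self.snm_rate_eu,
            "H3K9me3": self.snm_rate_k9,
            "H3K27me3": self.snm_rate_eu * self.k27_fold,
        }[label]
        if centromeric:
            base *= self.cen_fold
        return base * self.scale()


def design_from_config(cfg: SimConfig, annotation=None) -> ExperimentDesign:
    callable_bp = {"genome": float(sum(cfg.contig_lengths))}
    return ExperimentDesign(
        n_lines=cfg.n_lines, t_transfers=cfg.t_transfers,
        m_draws=np.full(12000, cfg.m_per_transfer), callable_bp=callable_bp)


# ---------------------------------------------------------------------------
# genome

def _random_bases(rng, n, gc):
    return rng.choice(np.array(list("ACGT")), size=n,
                      p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def simulate_genome(cfg: SimConfig, seed: int | None = None) -> tuple[
        GenomeAnnotation, dict]:
    """Simulate a chromatin-annotated genome.

    Each contig carries one central H3K9me3 block (with a centromeric core)
    and one H3K27me3 block in the euchromatic remainder; bases are drawn
    i.i.d. at the domain GC target, then homopolymer and microsatellite
    tracts are planted at the configured densities.
    """
    if not (0 <= cfg.k9_fraction <= 1 and 0 <= cfg.k27_fraction <= 1
            and 0 <= cfg.cen_within_k9 <= 1
            and cfg.k9_fraction + cfg.k27_fraction <= 0.9):
        raise ValueError("infeasible domain layout fractions")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    contigs, k9d, k27d, cend, eud = {}, {}, {}, {}, {}
    planted = {"homopolymers": 0, "microsatellites": 0}
    for i, length in enumerate(cfg.contig_lengths):
        name = f"contig_{i + 1}"
        k9_len = int(round(cfg.k9_fraction * length))
        k27_len = int(round(cfg.k27_fraction * length))
        cen_len = int(round(cfg.cen_within_k9 * k9_len))
        k9_start = int(length * 0.4)
        k9_iv = [(k9_start, k9_start + k9_len)] if k9_len else []
        cen_start = k9_start + (k9_len - cen_len) // 2
        cen_iv = [(cen_start, cen_start + cen_len)] if cen_len else []
        k27_start = int(length * 0.05)
        k27_iv = [(k27_start, k27_start + k27_len)] if k27_len else []
        if k27_iv and k9_iv and k27_iv[0][1] > k9_iv[0][0]:
            raise ValueError("infeasible layout: K27 block reaches K9 block")

        lab = np.zeros(length, dtype=np.uint8)
        for s, e in k9_iv:
            lab[s:e] = K9
        for s, e in k27_iv:
            lab[s:e] = K27
        bases = np.empty(length, dtype="<U1")
        for code, label in LABELS.items():
            m = lab == code
            if m.any():
                bases[m] = _random_bases(rng, int(m.sum()),
                                         cfg.gc_targets[label])
        # plant homopolymer tracts (lengths 5..14, geometric-ish)
        n_hp = rng.poisson(cfg.planted_hp_per_kb * length / 1000)
        for _ in range(n_hp):
            tl = int(np.clip(5 + rng.geometric(0.45) - 1, 5, 14))
            p0 = rng.integers(0, length - tl)
            base = rng.choice(list("ACGT"))
            bases[p0 : p0 + tl] = base
            planted["homopolymers"] += 1
        # plant microsatellite tracts (motif 2-3 bp, 4-8 copies)
        n_ms = rng.poisson(cfg.planted_ms_per_kb * length / 1000)
        for _ in range(n_ms):
            motif = "".join(rng.choice(list("ACGT"),
                                       size=int(rng.integers(2, 4))))
            copies = int(rng.integers(4, 9))
            tract = (motif * copies)
            p0 = rng.integers(0, length - len(tract))
            bases[p0 : p0 + len(tract)] = list(tract)
            planted["microsatellites"] += 1

        contigs[name] = "".join(bases)
        k9d[name] = k9_iv
        k27d[name] = k27_iv
        cend[name] = cen_iv
        both = merge_intervals(k9_iv + k27_iv)
        eud[name] = gc_mod.complement_intervals(both, length)

    part = DomainPartition(k9=k9d, k27=k27d, eu=eud, centromeres=cend,
                           lengths={c: len(s) for c, s in contigs.items()})
    part.validate()
    ann = GenomeAnnotation(sequence=GenomeSequence(contigs), partition=part)
    sidecar = {"config": _cfg_dict(cfg), "planted": planted}
    return ann, sidecar


def _cfg_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["contig_lengths"] = list(cfg.contig_lengths)
    d["phase_fractions"] = list(cfg.phase_fractions)
    d["rate_scale_effective"] = cfg.scale()
    return d


# ---------------------------------------------------------------------------
# MA experiment

# class -> {observed ref base: alt base}; the second entry of each map is
# the same change read off the complementary strand
_ALT_FOR_CLASS = {
    "C:G→T:A": {"C": "T", "G": "A"},
    "A:T→G:C": {"A": "G", "T": "C"},
    "C:G→A:T": {"C": "A", "G": "T"},
    "C:G→G:C": {"C": "G", "G": "C"},
    "A:T→C:G": {"A": "C", "T": "G"},
    "A:T→T:A": {"A": "T", "T": "A"},
}


def _stratum_positions(ann: GenomeAnnotation):
    """Per (stratum, pair) arrays of genomic positions, concatenated.

    Strata are ('euchromatin'|'H3K9me3'|'H3K27me3', centromeric_flag).
    """
    index = {}
    for contig in ann.contigs:
        codes = ann.codes(contig)
        lab = ann.labels(contig)
        cen = ann.cen_mask(contig)
        is_at = (codes == 0) | (codes == 3)
        is_cg = (codes == 1) | (codes == 2)
        for code, label in LABELS.items():
            for cflag in (False, True):
                m = (lab == code) & (cen == cflag)
                if not m.any():
                    continue
                key = (label, cflag)
                for pair, pm in (("A:T", is_at), ("C:G", is_cg)):
                    pos = np.flatnonzero(m & pm)
                    if pos.size:
                        index.setdefault(key, {}).setdefault(pair, []).append(
                            (contig, pos))
    return index


def simulate_ma_experiment(ann: GenomeAnnotation, cfg: SimConfig,
                           seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate per-line mutation tables under the configured rates.

    SNM counts per line and stratum are Poisson with mean
    ``rate * bp * t * m``; sites are uniform within the stratum, with the
    stratum's 6-class spectrum applied as per-source-pair relative rates.
    Homopolymer and microsatellite indels follow per-locus slippage rates
    (length-dependent for homopolymers); non-repeat indels, complex
    mutations and translocations are placed uniformly.  Returns the
    mutation table (internal 0-based coordinates) and a sidecar of every
    generating parameter.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    exposure = cfg.total_mitoses
    strata = _stratum_positions(ann)
    catalog = gc_mod.find_homopolymers(ann, min_len=5)
    records = []

    pair_of_class = {c: c.split("→")[0] for c in SNM_CLASSES}

    for line in range(cfg.n_lines):
        line_id = f"MA{line + 1:02d}"
        # --- SNMs per stratum
        for (label, cflag), pairs in strata.items():
            rate = cfg.domain_rate(label, cflag)
            counts = {p: sum(pos.size for _, pos in lst)
                      for p, lst in pairs.items()}
            spec = cfg.spectrum[label]
            # expected count per class: rate weight * source pair bp
            weights = np.array([spec[c] * counts.get(pair_of_class[c], 0)
                                for c in SNM_CLASSES], dtype=float)
            norm = sum(counts.values())
            if norm == 0 or weights.sum() == 0:
                continue
            # total expected count is rate * bp * exposure; classes split
            # proportionally to (spectrum weight x source-pair census)
            lam = rate * exposure * norm * weights / weights.sum()
            n_by_class = rng.poisson(lam)
            for cls, n_mut in zip(SNM_CLASSES, n_by_class):
                if n_mut == 0:
                    continue
                pool = pairs.get(pair_of_class[cls])
                if not pool:
                    continue
                sizes = np.array([p.size for _, p in pool])
                cum = np.cumsum(sizes)
                picks = rng.integers(0, cum[-1], size=n_mut)
                for pk in picks:
                    j = int(np.searchsorted(cum, pk, side="right"))
                    contig, positions = pool[j]
                    pos = int(positions[pk - (cum[j - 1] if j else 0)])
                    ref = ann.sequence.contigs[contig][pos]
                    alt = _ALT_FOR_CLASS[cls][ref]
                    records.append((line_id, contig, pos, "SNM", ref, alt, 1))

        # --- homopolymer slippage indels
        if not catalog.empty:
            base_rate = np.where(catalog["polymer_type"] == "A:T",
                                 cfg.hp_rate_at, cfg.hp_rate_cg)
            lam = (base_rate * np.exp(cfg.hp_length_slope
                                      * (catalog["length"] - 5))
                   * cfg.scale() * exposure)
            hits = rng.poisson(lam)
            for ri in np.flatnonzero(hits):
                run = catalog.iloc[ri]
                for _ in range(int(hits[ri])):
                    is_ins = rng.random() < cfg.hp_insertion_frac
                    pos = int(rng.integers(run["start"] + 1, run["end"] - 1)) \
                        if run["length"] > 2 else int(run["start"])
                    kind = "insertion" if is_ins else "deletion"
                    ref = run["base"]
                    alt = ref + ref if is_ins else ""
                    records.append((line_id, run["contig"], pos, kind,
                                    ref, alt, 1))

        # --- non-repeat indels, translocations, complex events
        total_len = sum(len(s) for s in ann.sequence.contigs.values())
        contig_names = list(ann.sequence.contigs)
        contig_lens = np.array([len(ann.sequence.contigs[c])
                                for c in contig_names])
        p_contig = contig_lens / contig_lens.sum()

        def place(kind, length, n):
            for _ in range(n):
                c = rng.choice(len(contig_names), p=p_contig)
                contig = contig_names[c]
                ln = int(length() if callable(length) else length)
                ln = max(1, min(ln, contig_lens[c] // 4))
                pos = int(rng.integers(0, contig_lens[c] - ln))
                records.append((line_id, contig, pos, kind, "", "", ln))

        place("deletion", lambda: _del_length(rng),
              rng.poisson(cfg.del_nonrepeat_rate * exposure))
        place("insertion", lambda: int(np.clip(rng.lognormal(2.4, 1.0), 1, 130)),
              rng.poisson(cfg.ins_nonrepeat_rate * exposure))
        place("translocation", 316,
              rng.poisson(cfg.translocation_rate * exposure))
        place("complex", 2,
              rng.poisson(cfg.complex_rate * cfg.scale() * total_len
                          * exposure))

        # --- microsatellite indels
        # planted tracts are not individually tracked; emulate by placing
        # motif-length indels at planted density
        n_ms_mut = rng.poisson(cfg.ms_rate * cfg.scale()
                               * cfg.planted_ms_per_kb * total_len / 1000
                               * exposure)
        place("deletion", lambda: int(rng.integers(2, 4)), n_ms_mut)

    df = pd.DataFrame(records, columns=[
        "line_id", "contig", "pos", "kind", "ref", "alt", "length"])
    df = df.sort_values(["line_id", "contig", "pos"], ignore_index=True)
    sidecar = {
        "config": _cfg_dict(cfg),
        "exposure_mitoses": exposure,
        "n_records": len(df),
        "true_rates": {
            "snm_eu": cfg.domain_rate("euchromatin"),
            "snm_k9": cfg.domain_rate("H3K9me3"),
            "snm_k9_cen": cfg.domain_rate("H3K9me3", True),
            "snm_k27": cfg.domain_rate("H3K27me3"),
            "k9_fold": (cfg.snm_rate_k9 / cfg.snm_rate_eu
                        if cfg.snm_rate_eu else np.nan),
            "k27_fold": cfg.k27_fold,
            "cen_fold": cfg.cen_fold,
            "hp_ratio_at_cg": (cfg.hp_rate_at / cfg.hp_rate_cg
                               if cfg.hp_rate_cg else np.nan),
            "hp_length_slope": cfg.hp_length_slope,
        },
    }
    return df, sidecar


def _del_length(rng) -> int:
    # mostly short deletions with a heavy tail of multi-kb events
    if rng.random() < 0.10:
        return int(rng.integers(2_000, 18_000))
    return int(np.clip(rng.lognormal(2.5, 1.3), 1, 500))


# ---------------------------------------------------------------------------
# population sample

def simulate_population(windows: pd.DataFrame, mu_per_window: np.ndarray,
                        cfg: SimConfig, seed: int | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate haploid population SNPs with theta tied to the local rate.

    For each window the target diversity is
    ``theta = slope * log10(mu) + intercept`` (clamped at 0).  Sites are
    made polymorphic with probability ``theta * a_n`` per bp, with derived
    allele counts from the neutral 1/k frequency spectrum, then per-call
    missingness is applied i.i.d.  Under this scheme the missing-data
    Watterson estimator stays unbiased at any missingness level.

    Returns a site table (contig, pos, ref, alt, gts: int8 array with -1
    for missing) and the sidecar.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    n = cfg.n_strains
    a_n = np.sum(1.0 / np.arange(1, n))
    k_values = np.arange(1, n)
    k_probs = (1.0 / k_values) / np.sum(1.0 / k_values)

    mu = np.asarray(mu_per_window, dtype=float)
    theta = cfg.theta_slope * np.log10(np.clip(mu, 1e-300, None)) \
        + cfg.theta_intercept
    n_clamped = int((theta < 0).sum())
    theta = np.clip(theta, 0.0, None)

    rows = []
    for (_, w), th in zip(windows.iterrows(), theta):
        span = int(w["end"] - w["start"])
        p_poly = min(th * a_n, 1.0)
        n_sites = rng.binomial(span, p_poly)
        if n_sites == 0:
            continue
        positions = np.sort(rng.choice(span, size=n_sites, replace=False))
        ks = rng.choice(k_values, size=n_sites, p=k_probs)
        for pos, k in zip(positions, ks):
            gts = np.zeros(n, dtype=np.int8)
            gts[rng.choice(n, size=int(k), replace=False)] = 1
            if cfg.missing_rate > 0:
                gts[rng.random(n) < cfg.missing_rate] = -1
            rows.append((w["contig"], int(w["start"]) + int(pos),
                         "A", "T", gts))
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "gts"])
    sidecar = {
        "theta_slope": cfg.theta_slope, "theta_intercept": cfg.theta_intercept,
        "n_strains": n, "missing_rate": cfg.missing_rate,
        "n_windows_clamped": n_clamped, "n_sites": len(sites),
    }
    return sites, sidecar


def simulate_nuclei_counts(cfg: SimConfig, seed: int | None = None
                           ) -> tuple[NucleiCounts, dict]:
    """Replicate nuclei counts whose phase doublings sum to ``true_m``."""
    if cfg.true_m <= 0:
        raise ValueError("true_m must be positive")
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    fr = np.asarray(cfg.phase_fractions, dtype=float)
    fr = fr / fr.sum()
    phases = {}
    for i, f in enumerate(fr):
        d = cfg.true_m * f
        reps = []
        for _ in range(cfg.nuclei_replicates):
            noise = (np.exp(rng.normal(0, cfg.nuclei_cv, size=2))
                     if cfg.nuclei_cv > 0 else np.ones(2))
            ini = cfg.nuclei_base_count * noise[0]
            fin = cfg.nuclei_base_count * 2.0 ** d * noise[1]
            reps.append((float(ini), float(fin)))
        phases[f"phase_{i + 1}"] = reps
    sidecar = {"true_m": cfg.true_m,
               "phase_doublings": list(cfg.true_m * fr),
               "cv": cfg.nuclei_cv}
    return NucleiCounts(phases=phases), sidecar


# ---------------------------------------------------------------------------
# writers (plain-text formats)

def write_fasta(ann: GenomeAnnotation, path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in ann.sequence.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: dict, path):
    with open(path, "w") as fh:
        for contig in sorted(intervals):
            for s, e in intervals[contig]:
                fh.write(f"{contig}\t{s}\t{e}\n")


def write_mutations_tsv(df: pd.DataFrame, path):
    """Write a mutation table with 1-based positions."""
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def write_vcf(sites: pd.DataFrame, n_strains: int, path,
              contig_lengths: dict | None = None):
    """Write haploid genotypes as an uncompressed VCF ('.' = missing)."""
    samples = [f"strain_{i + 1:03d}" for i in range(n_strains)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutaccum-synthetic\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, row in sites.iterrows():
            gts = ["." if g < 0 else str(int(g)) for g in row["gts"]]
            fh.write(f"{row['contig']}\t{int(row['pos']) + 1}\t.\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def save_sidecar(sidecar: dict, path):
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
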