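"""Genome sequence, chromatin-domain annotation, and sequence-context tables.

The genome is partitioned into three mutually exclusive chromatin domains:
H3K9me3 (constitutive heterochromatin), H3K27me3 (facultative
heterochromatin) and euchromatin (everything else).  Centromeric regions
are modelled as a boolean overlay on H3K9me3 rather than a fourth label,
because every centromeric base lies inside an H3K9me3 domain and the rate
models treat the centromere effect as additive on top of the H3K9me3
effect.

All internal coordinates are 0-based half-open.  BED input is read
natively; tabular mutation files and VCF carry 1-based positions and are
converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

EU, K9, K27 = 0, 1, 2
LABELS = {EU: "euchromatin", K9: "H3K9me3", K27: "H3K27me3"}
LABEL_CODES = {v: k for k, v in LABELS.items()}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SNM_CLASSES = [
    "C:G→T:A", "A:T→G:C", "C:G→A:T", "C:G→G:C", "A:T→C:G", "A:T→T:A",
]


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_trinuc(tri: str) -> str:
    """Collapse a trinucleotide with its reverse complement.

    The class is named ``MIN:REVCOMP`` where MIN is the lexicographically
    smaller of the two strand-paired trinucleotides.
    """
    rc = revcomp(tri)
    lo = min(tri, rc)
    return f"{lo}:{revcomp(lo)}"


#: the 32 strand-collapsed trinucleotide classes, in lexicographic order
TRINUC_CLASSES = sorted(
    {canonical_trinuc(a + b + c)
     for a in "ACGT" for b in "ACGT" for c in "ACGT"}
)
_TRINUC_INDEX = {c: i for i, c in enumerate(TRINUC_CLASSES)}

# lookup: packed 3-mer code (base4) -> class index; N-containing -> -1
_TRI_LUT = np.full(125, -1, dtype=np.int32)
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            _code = (_BASE_CODE[_a] * 25 + _BASE_CODE[_b] * 5
                     + _BASE_CODE[_c])
            _TRI_LUT[_code] = _TRINUC_INDEX[canonical_trinuc(_a + _b + _c)]


def trinuc_focal_pair(cls: str) -> str:
    """Focal base pair ('A:T' or 'C:G') of a collapsed trinucleotide class."""
    mid = cls.split(":")[0][1]
    return "C:G" if mid in "CG" else "A:T"


def trinuc_pyrimidine_context(cls: str) -> str:
    """Orientation of the class with a pyrimidine (C or T) focal base.

    Used to define 5'/3' flanking bases consistently across the two
    strands: for each collapsed class exactly one orientation has C or T
    in the centre.
    """
    a, b = cls.split(":")
    return a if a[1] in "CT" else b


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences over {A, C, G, T, N} per contig."""

    contigs: dict[str, str]

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} has zero length")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)!r}"
                )

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name {rec.id!r} in FASTA")
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def codes(self, contig: str) -> np.ndarray:
        """Base codes A=0 C=1 G=2 T=3 N=4 as a uint8 array."""
        raw = np.frombuffer(self.contigs[contig].encode("ascii"), dtype=np.uint8)
        out = np.full(raw.size, 4, dtype=np.uint8)
        for base, code in _BASE_CODE.items():
            out[raw == ord(base)] = code
        return out


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open)

def merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(a, b) -> list[tuple[int, int]]:
    """Set difference a \\ b for merged, sorted interval lists."""
    out = []
    j = 0
    b = list(b)
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(iv, length) -> list[tuple[int, int]]:
    return subtract_intervals([(0, length)], merge_intervals(iv))


@dataclass
class DomainPartition:
    """Per contig: H3K9me3 / H3K27me3 / euchromatin tiling + centromere overlay."""

    k9: dict[str, list[tuple[int, int]]]
    k27: dict[str, list[tuple[int, int]]]
    eu: dict[str, list[tuple[int, int]]]
    centromeres: dict[str, list[tuple[int, int]]]
    lengths: dict[str, int]

    def label_array(self, contig: str) -> np.ndarray:
        arr = np.zeros(self.lengths[contig], dtype=np.uint8)
        for s, e in self.k9.get(contig, []):
            arr[s:e] = K9
        for s, e in self.k27.get(contig, []):
            arr[s:e] = K27
        return arr

    def centromere_mask(self, contig: str) -> np.ndarray:
        m = np.zeros(self.lengths[contig], dtype=bool)
        for s, e in self.centromeres.get(contig, []):
            m[s:e] = True
        return m

    def validate(self):
        for contig, length in self.lengths.items():
            total = sum(e - s for lab in (self.k9, self.k27, self.eu)
                        for s, e in lab.get(contig, []))
            if total != length:
                raise AssertionError(
                    f"domain labels do not tile contig {contig!r}: "
                    f"{total} != {length}"
                )
            k9set = merge_intervals(self.k9.get(contig, []))
            leftover = subtract_intervals(
                merge_intervals(self.centromeres.get(contig, [])), k9set)
            if leftover:
                raise AssertionError(
                    f"centromeric bases outside H3K9me3 on {contig!r}: {leftover}"
                )


@dataclass
class GenomeAnnotation:
    sequence: GenomeSequence
    partition: DomainPartition
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _labels: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _cen: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def codes(self, contig):
        if contig not in self._codes:
            self._codes[contig] = self.sequence.codes(contig)
        return self._codes[contig]

    def labels(self, contig):
        if contig not in self._labels:
            self._labels[contig] = self.partition.label_array(contig)
        return self._labels[contig]

    def cen_mask(self, contig):
        if contig not in self._cen:
            self._cen[contig] = self.partition.centromere_mask(contig)
        return self._cen[contig]

    @property
    def contigs(self):
        return list(self.sequence.contigs)


def read_bed(path, lengths: dict[str, int]) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3 file, validating against contig bounds."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed BED line (fewer than 3 fields)")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates") from exc
            if contig not in lengths:
                raise ValueError(
                    f"{path}:{lineno}: contig {contig!r} not present in FASTA")
            if not (0 <= start < end <= lengths[contig]):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"contig {contig!r} (length {lengths[contig]})")
            out.setdefault(contig, []).append((start, end))
    return {c: merge_intervals(iv) for c, iv in out.items()}


def load_annotation(fasta_path, k9_bed, k27_bed, cen_bed) -> GenomeAnnotation:
    """Load genome + chromatin BEDs and build the domain partition.

    Overlaps between the H3K9me3 and H3K27me3 inputs are resolved with
    H3K9me3 priority (K27 truncated).  Centromeric intervals are forced to
    lie inside H3K9me3: where a centromere extends beyond the K9 input,
    the K9 domain is extended to cover it and a warning is logged.
    """
    seq = GenomeSequence.from_fasta(fasta_path)
    lengths = {c: len(s) for c, s in seq.contigs.items()}
    k9 = read_bed(k9_bed, lengths)
    k27_raw = read_bed(k27_bed, lengths)
    cen = read_bed(cen_bed, lengths)

    for contig, iv in cen.items():
        outside = subtract_intervals(iv, k9.get(contig, []))
        if outside:
            logger.warning(
                "extending H3K9me3 on %s to cover centromeric intervals %s",
                contig, outside)
            k9[contig] = merge_intervals(k9.get(contig, []) + list(iv))

    k27 = {}
    for contig, iv in k27_raw.items():
        trimmed = subtract_intervals(iv, k9.get(contig, []))
        if trimmed != iv:
            logger.info("H3K27me3 intervals on %s truncated where they "
                        "overlap H3K9me3", contig)
        if trimmed:
            k27[contig] = trimmed

    eu = {}
    for contig, length in lengths.items():
        both = merge_intervals(k9.get(contig, []) + k27.get(contig, []))
        comp = complement_intervals(both, length)
        if comp:
            eu[contig] = comp

    part = DomainPartition(k9=k9, k27=k27, eu=eu, centromeres=cen,
                           lengths=lengths)
    part.validate()
    return GenomeAnnotation(sequence=seq, partition=part)


# ---------------------------------------------------------------------------
# composition tables

STRATA = ["euchromatin", "H3K9me3", "H3K27me3", "centromeric",
          "H3K9me3_ex_cen", "genome"]


@dataclass
class CompositionTable:
    """Base-pair, trinucleotide and homopolymer censuses per stratum.

    ``base_pairs`` rows are strata; columns ``callable_bp`` (non-N bases),
    ``at_pairs``, ``cg_pairs``.  ``trinuc`` is strata x 32 collapsed
    classes, counting interior non-N positions by the domain of the centre
    base.  ``homopolymers`` counts loci per (stratum, type, length).
    """

    base_pairs: pd.DataFrame
    trinuc: pd.DataFrame
    homopolymers: pd.DataFrame | None = None

    def to_tsv(self, path):
        with open(path, "w") as fh:
            self.base_pairs.to_csv(fh, sep="\t")
            fh.write("#\n")
            self.trinuc.to_csv(fh, sep="\t")


def _stratum_masks(ann: GenomeAnnotation, contig: str) -> dict[str, np.ndarray]:
    lab = ann.labels(contig)
    cen = ann.cen_mask(contig)
    return {
        "euchromatin": lab == EU,
        "H3K9me3": lab == K9,
        "H3K27me3": lab == K27,
        "centromeric": cen,
        "H3K9me3_ex_cen": (lab == K9) & ~cen,
        "genome": np.ones(lab.size, dtype=bool),
    }


def trinucleotide_census(ann: GenomeAnnotation) -> CompositionTable:
    """Count callable bases, base pairs and collapsed trinucleotides per stratum."""
    bp = pd.DataFrame(0, index=STRATA,
                      columns=["callable_bp", "at_pairs", "cg_pairs"],
                      dtype=np.int64)
    tri = pd.DataFrame(0, index=STRATA, columns=TRINUC_CLASSES, dtype=np.int64)
    for contig in ann.contigs:
        codes = ann.codes(contig)
        masks = _stratum_masks(ann, contig)
        is_at = (codes == 0) | (codes == 3)
        is_cg = (codes == 1) | (codes == 2)
        non_n = codes != 4
        if codes.size >= 3:
            packed = (codes[:-2].astype(np.int32) * 25
                      + codes[1:-1] * 5 + codes[2:])
            cls = _TRI_LUT[packed]          # class of centre position i+1
            valid = cls >= 0
        for name, m in masks.items():
            bp.loc[name, "callable_bp"] += int((m & non_n).sum())
            bp.loc[name, "at_pairs"] += int((m & is_at).sum())
            bp.loc[name, "cg_pairs"] += int((m & is_cg).sum())
            if codes.size >= 3:
                sel = valid & m[1:-1]
                if sel.any():
                    counts = np.bincount(cls[sel], minlength=32)
                    tri.loc[name] += counts
    return CompositionTable(base_pairs=bp, trinuc=tri)


def find_homopolymers(ann: GenomeAnnotation, min_len: int = 5) -> pd.DataFrame:
    """Catalog maximal single-base runs of length >= ``min_len``.

    Returns columns: contig, start, end, base, polymer_type (A:T / C:G),
    length, domain_label, centromeric.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    rows = []
    for contig in ann.contigs:
        codes = ann.codes(contig)
        if codes.size == 0:
            continue
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [codes.size]])
        lens = ends - starts
        keep = (lens >= min_len) & (codes[starts] != 4)
        lab = ann.labels(contig)
        cen = ann.cen_mask(contig)
        for s, e in zip(starts[keep], ends[keep]):
            base = "ACGT"[codes[s]]
            rows.append({
                "contig": contig, "start": int(s), "end": int(e),
                "base": base,
                "polymer_type": "A:T" if base in "AT" else "C:G",
                "length": int(e - s),
                "domain_label": LABELS[lab[s]],
                "centromeric": bool(cen[s]),
            })
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "base", "polymer_type",
                       "length", "domain_label", "centromeric"])


def homopolymer_census(catalog: pd.DataFrame) -> pd.DataFrame:
    """Locus counts per (polymer_type, length)."""
    if catalog.empty:
        return pd.DataFrame(columns=["polymer_type", "length", "n_loci"])
    out = (catalog.groupby(["polymer_type", "length"]).size()
           .rename("n_loci").reset_index())
    return out


def make_windows(ann: GenomeAnnotation, width: int = 200) -> pd.DataFrame:
    """Tile the genome with fixed-width windows (last window may be short).

    Columns: contig, start, end, gc_fraction (NaN if window is all N),
    domain_label (majority base overlap; ties broken K9 > K27 > eu),
    centromeric (strict majority of bases), callable_bp.
    """
    if width < 50:
        raise ValueError("window width must be >= 50")
    frames = []
    for contig in ann.contigs:
        codes = ann.codes(contig)
        lab = ann.labels(contig)
        cen = ann.cen_mask(contig)
        n = codes.size
        is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
        non_n = (codes != 4).astype(np.int64)
        cum = {
            "gc": np.concatenate([[0], np.cumsum(is_gc)]),
            "nn": np.concatenate([[0], np.cumsum(non_n)]),
            "k9": np.concatenate([[0], np.cumsum((lab == K9).astype(np.int64))]),
            "k27": np.concatenate([[0], np.cumsum((lab == K27).astype(np.int64))]),
            "cen": np.concatenate([[0], np.cumsum(cen.astype(np.int64))]),
        }
        starts = np.arange(0, n, width)
        ends = np.minimum(starts + width, n)
        span = ends - starts
        nn = cum["nn"][ends] - cum["nn"][starts]
        gc = cum["gc"][ends] - cum["gc"][starts]
        k9 = cum["k9"][ends] - cum["k9"][starts]
        k27 = cum["k27"][ends] - cum["k27"][starts]
        cenc = cum["cen"][ends] - cum["cen"][starts]
        eu = span - k9 - k27
        # majority label with ties broken toward the rarer label
        label = np.where(
            (k9 >= k27) & (k9 >= eu), K9,
            np.where(k27 >= eu, K27, EU)).astype(np.uint8)
        with np.errstate(invalid="ignore"):
            gcf = np.where(nn > 0, gc / np.maximum(nn, 1), np.nan)
        frames.append(pd.DataFrame({
            "contig": contig, "start": starts, "end": ends,
            "gc_fraction": gcf,
            "domain_label": [LABELS[l] for l in label],
            "centromeric": cenc * 2 > span,
            "callable_bp": nn,
        }))
    return pd.concat(frames, ignore_index=True)


def window_purity(ann: GenomeAnnotation, windows: pd.DataFrame) -> np.ndarray:
    """True for windows lying entirely within one domain/centromere state.

    Boundary-straddling windows carry a majority label but mixed true
    rates; excluding them avoids label measurement error in window-level
    rate models.
    """
    out = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows.itertuples(index=False)):
        lab = ann.labels(w.contig)[w.start : w.end]
        cen = ann.cen_mask(w.contig)[w.start : w.end]
        out[i] = bool((lab == lab[0]).all() and (cen == cen[0]).all())
    return out


# ---------------------------------------------------------------------------
# mutation tables

MUTATION_KINDS = ["SNM", "insertion", "deletion", "translocation", "complex"]


def read_mutations(path) -> pd.DataFrame:
    """Read a mutation table (TSV with 1-based ``pos``) into internal form.

    Required columns: line_id, contig, pos, kind.  SNMs need ref and alt;
    indels need length.  Positions are converted to 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "line_id": str})
    required = {"line_id", "contig", "pos", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    bad = set(df["kind"]) - set(MUTATION_KINDS)
    if bad:
        raise ValueError(f"unknown mutation kinds: {sorted(bad)}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    if "length" not in df.columns:
        df["length"] = 1
    df["length"] = df["length"].fillna(1).astype(int)
    return df


def annotate_mutations(mutations: pd.DataFrame,
                       ann: GenomeAnnotation,
                       window_width: int = 200) -> pd.DataFrame:
    """Attach genomic context to each mutation record.

    Adds: domain_label, centromeric, trinuc_class + snm_class (SNMs),
    homopolymer run info (indels: hp_base, hp_length), window_gc.
    An SNM whose stated ref allele disagrees with the genome is a hard
    error, listing the offending records.
    """
    from .snm_spectrum import classify_snm

    df = mutations.copy()
    domains, cens, trinucs, snm_cls = [], [], [], []
    hp_base, hp_len, window_gc = [], [], []
    errors = []
    for idx, rec in df.iterrows():
        contig, pos = rec["contig"], int(rec["pos"])
        if contig not in ann.sequence.contigs:
            raise ValueError(f"record {idx}: unknown contig {contig!r}")
        seq = ann.sequence.contigs[contig]
        if not (0 <= pos < len(seq)):
            raise ValueError(f"record {idx}: position {pos} outside {contig!r}")
        lab = ann.labels(contig)
        domains.append(LABELS[lab[pos]])
        cens.append(bool(ann.cen_mask(contig)[pos]))

        if rec["kind"] == "SNM":
            ref, alt = str(rec["ref"]), str(rec["alt"])
            if seq[pos] != ref:
                errors.append((idx, contig, pos + 1, ref, seq[pos]))
            if 1 <= pos <= len(seq) - 2 and "N" not in seq[pos - 1 : pos + 2]:
                trinucs.append(canonical_trinuc(seq[pos - 1 : pos + 2]))
            else:
                trinucs.append(None)
            snm_cls.append(classify_snm(ref, alt))
        else:
            trinucs.append(None)
            snm_cls.append(None)

        if rec["kind"] in ("insertion", "deletion"):
            b, l = _containing_run(seq, pos, int(rec["length"]), rec["kind"],
                                   str(rec.get("alt", "") or ""))
            hp_base.append(b)
            hp_len.append(l)
        else:
            hp_base.append(None)
            hp_len.append(0)

        w0 = (pos // window_width) * window_width
        wseq = seq[w0 : w0 + window_width]
        nn = sum(1 for ch in wseq if ch != "N")
        gc = sum(1 for ch in wseq if ch in "GC")
        window_gc.append(gc / nn if nn else np.nan)

    if errors:
        msgs = "; ".join(
            f"record {i} at {c}:{p} ref={r!r} genome={g!r}"
            for i, c, p, r, g in errors)
        raise ValueError(f"SNM reference allele mismatches: {msgs}")

    df["domain_label"] = domains
    df["centromeric"] = cens
    df["trinuc_class"] = trinucs
    df["snm_class"] = snm_cls
    df["hp_base"] = hp_base
    df["hp_length"] = hp_len
    df["window_gc"] = window_gc
    return df


def _containing_run(seq: str, pos: int, length: int, kind: str,
                    alt: str) -> tuple[str | None, int]:
    """Maximal single-base run containing an indel, if any.

    A deletion lies in a run when the deleted bases and the run base agree
    and the deleted interval is inside the run; an insertion when the
    insertion point is strictly inside the run and the inserted sequence
    consists of the run base.
    """
    if kind == "deletion":
        segment = seq[pos : pos + length]
        if len(set(segment)) != 1 or not segment:
            return None, 0
        base = segment[0]
    else:
        ins = alt[1:] if len(alt) > 1 else alt  # VCF-style or bare insert
        if not ins or len(set(ins)) != 1:
            return None, 0
        base = ins[0]
        if seq[pos] != base:
            return None, 0
    s = pos
    while s > 0 and seq[s - 1] == base:
        s -= 1
    e = pos
    while e < len(seq) and seq[e] == base:
        e += 1
    run_len = e - s
    if kind == "deletion" and (pos < s or pos + length > e):
        return None, 0
    if run_len < 2:
        return None, 0
    return base, run_len
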