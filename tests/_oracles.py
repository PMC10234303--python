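"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (dictionary tallies, regex scans,
dense grids) and shares no code with the package internals it checks.
"""

import re

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_str(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_trinuc_tally(seq: str) -> dict:
    """Dictionary tally of interior 3-mers with reverse-complement collapse."""
    out: dict = {}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if "N" in tri:
            continue
        rc = revcomp_str(tri)
        lo = min(tri, rc)
        key = f"{lo}:{revcomp_str(lo)}"
        out[key] = out.get(key, 0) + 1
    return out


def regex_homopolymers(seq: str, min_len: int = 5) -> list:
    """Maximal single-base runs via regex; (start, end, base) tuples."""
    out = []
    for m in re.finditer(r"A+|C+|G+|T+", seq):
        if m.end() - m.start() >= min_len:
            out.append((m.start(), m.end(), m.group()[0]))
    return out


def grid_poisson_posterior(total_count: float, total_exposure: float,
                           prior_sd: float = 10.0, span: float = 12.0,
                           n_grid: int = 400_001):
    """Dense-grid posterior of alpha for counts ~ Poisson(exposure e^alpha).

    Returns (median_alpha, (hpd_lo, hpd_hi), quantile_fn) computed by
    direct numerical integration; the HPD interval is the highest-density
    region holding 95% of the mass.
    """
    if total_count > 0:
        center = np.log(total_count / total_exposure)
    else:
        center = np.log(1.0 / total_exposure) - 4.0
    grid = np.linspace(center - span, center + span, n_grid)
    logpost = (total_count * grid - total_exposure * np.exp(grid)
               - 0.5 * (grid / prior_sd) ** 2)
    logpost -= logpost.max()
    pdf = np.exp(logpost)
    pdf /= pdf.sum()
    cdf = np.cumsum(pdf)

    def quantile(q):
        return float(grid[np.searchsorted(cdf, q)])

    median = quantile(0.5)
    # highest-density region: lower the threshold until 95% mass is inside
    order = np.argsort(pdf)[::-1]
    mass = np.cumsum(pdf[order])
    k = int(np.searchsorted(mass, 0.95))
    inside = np.sort(order[: k + 1])
    hpd = (float(grid[inside[0]]), float(grid[inside[-1]]))
    return median, hpd, quantile


def brute_watterson(gts: np.ndarray, length: float) -> float:
    """Watterson's theta with per-site sample sizes, from first principles.

    ``gts``: (n_sites, n_strains) with -1 for missing; any site with >= 2
    called alleles and >= 2 distinct alleles contributes 1/a_{n_called}.
    """
    total = 0.0
    for row in gts:
        called = row[row >= 0]
        if called.size < 2:
            continue
        if len(set(called.tolist())) < 2:
            continue
        a_n = sum(1.0 / k for k in range(1, called.size))
        total += 1.0 / a_n
    return total / length
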