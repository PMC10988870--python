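"""Per-site population-genetic statistics.

Hudson F_ST (Bhatia et al. sample-size-corrected form, numerator and
denominator kept separate so windows and genome-wide values can be
aggregated as a ratio of averages), Weir & Cockerham (1984) variance
components a/b/c for the two-population case, per-window nucleotide
diversity pi, Watterson's theta and Tajima's D, and pairwise LD r^2 on
phased haplotypes.

Per-site F_ST values are deliberately not clamped to [0, 1]: negative
per-site estimates are informative noise that cancels in the
ratio-of-averages aggregate, and clamping would bias windows upward.
Sites where a statistic is undefined are reported as NaN and masked by
downstream consumers, never zero-filled (zero-filling distorts empirical
quantile thresholds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix

__all__ = [
    "hudson_fst_site", "hudson_fst_arrays", "hudson_fst_ratio",
    "wc_components_site", "wc_components_arrays",
    "site_stat_table",
    "pi_from_counts", "pi_window", "watterson_theta", "tajimas_d",
    "DiversityStats", "ld_r2_pair", "ld_r2_from_haplotypes",
]


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def hudson_fst_site(n1: int, x1: int, n2: int, x2: int,
                    ) -> tuple[float, float]:
    """Hudson estimator components at one site.

    ``n_i`` are called allele counts (2 x called diploids) and ``x_i``
    ALT allele counts.  Returns ``(numerator, denominator)`` of the
    sample-size-corrected estimator

        num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    so callers can aggregate ratio-of-averages.  Requires ``n_i >= 2``
    (the correction divides by ``n_i - 1``).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 alleles per population, got {n1}, {n2}")
    p1, p2 = x1 / n1, x2 / n2
    num = ((p1 - p2) ** 2
           - p1 * (1.0 - p1) / (n1 - 1)
           - p2 * (1.0 - p2) / (n2 - 1))
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def hudson_fst_arrays(n1: np.ndarray, x1: np.ndarray,
                      n2: np.ndarray, x2: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`hudson_fst_site`; NaN where ``n_i < 2``."""
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, x1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(ok, x2 / np.maximum(n2, 1), np.nan)
        num = ((p1 - p2) ** 2
               - p1 * (1.0 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1.0 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def hudson_fst_ratio(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-averages Hudson F_ST over a set of sites.

    NaN components are masked; returns NaN when no site has a positive
    summed denominator.
    """
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    ok = np.isfinite(num) & np.isfinite(den)
    d = den[ok].sum()
    if d <= 0:
        return float("nan")
    return float(num[ok].sum() / d)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) components, r = 2 populations
# ---------------------------------------------------------------------------

def wc_components_site(n1: float, p1: float, h1: float,
                       n2: float, p2: float, h2: float,
                       ) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) at one site.

    ``n_i`` are called *diploid* counts, ``p_i`` ALT frequencies and
    ``h_i`` observed heterozygote fractions (from the diploid genotypes,
    which is what VCFtools' weighted F_ST consumes).  The weighted window
    estimate is ``sum(a) / sum(a+b+c)``.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    if nbar <= 1:
        raise ValueError("mean sample size must exceed 1 diploid")
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_components_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorized :func:`wc_components_site`; NaN where nbar <= 1 or any
    input is NaN."""
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    r = 2.0
    nbar = (n1 + n2) / r
    ok = nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
            / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
    bad = ~ok | ~np.isfinite(p1) | ~np.isfinite(p2)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def site_stat_table(g: GenotypeMatrix, sel_samples: list[str],
                    ref_samples: list[str]) -> pd.DataFrame:
    """Per-site differentiation statistics for a selected/reference pair.

    Columns: chrom, pos (1-based), p_sel, p_ref, n_sel, n_ref (allele
    counts), hudson_num, hudson_den, fst_site (per-site Hudson ratio, NaN
    when the denominator is 0), wc_a, wc_b, wc_c.
    """
    def pop_arrays(names: list[str]):
        pos = {s: i for i, s in enumerate(g.samples)}
        idx = np.array([pos[s] for s in names], dtype=np.int64)
        d = g.dosage[idx, :]
        called = d != MISSING
        n_dip = called.sum(axis=0).astype(np.float64)
        alt = np.where(called, d, 0).sum(axis=0).astype(np.float64)
        het = np.where(called, d == 1, False).sum(axis=0).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_dip > 0, alt / (2 * np.maximum(n_dip, 1)), np.nan)
            h = np.where(n_dip > 0, het / np.maximum(n_dip, 1), np.nan)
        return n_dip, alt, p, h

    nd1, alt1, p1, h1 = pop_arrays(sel_samples)
    nd2, alt2, p2, h2 = pop_arrays(ref_samples)
    num, den = hudson_fst_arrays(2 * nd1, alt1, 2 * nd2, alt2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_site = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    a, b, c = wc_components_arrays(nd1, p1, h1, nd2, p2, h2)
    return pd.DataFrame({
        "chrom": g.chroms, "pos": g.positions,
        "p_sel": p1, "p_ref": p2,
        "n_sel": (2 * nd1).astype(np.int64), "n_ref": (2 * nd2).astype(np.int64),
        "hudson_num": num, "hudson_den": den, "fst_site": fst_site,
        "wc_a": a, "wc_b": b, "wc_c": c,
    })


# ---------------------------------------------------------------------------
# Diversity: pi, Watterson's theta, Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    """Window diversity summary for one population sample."""

    pi: float  # sum over sites of unbiased per-site heterozygosity
    theta_w: float  # S / a1
    tajima_d: float  # NaN when S == 0
    S: int  # segregating sites
    n: int  # haplotype sample size


def pi_from_counts(derived: np.ndarray, n: int) -> float:
    """Sum over sites of 2 p (1-p) n/(n-1), the mean pairwise difference.

    ``derived`` is the per-site derived/ALT allele count among ``n``
    haplotypes.  Exactly equals the average Hamming distance over all
    C(n, 2) haplotype pairs.
    """
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    k = np.asarray(derived, dtype=np.float64)
    p = k / n
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1.0))


def pi_window(h: HaplotypeMatrix, site_idx: np.ndarray | None = None,
              span: int | None = None) -> tuple[float, float]:
    """Window nucleotide diversity: (per-window sum, per-bp value).

    ``span`` (bp) divides the sum for the per-bp value; NaN per-bp when
    no span is given.
    """
    hap = h.haplotypes if site_idx is None else h.haplotypes[:, site_idx]
    n = hap.shape[0]
    pi = pi_from_counts(hap.sum(axis=0), n) if hap.shape[1] else 0.0
    per_bp = pi / span if span else float("nan")
    return pi, per_bp


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a1 with a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if S == 0:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    return S / a1


def tajimas_d(hap: np.ndarray) -> DiversityStats:
    """Tajima's D for a haplotype slice (rows: haplotypes, cols: sites).

    Monomorphic columns are ignored (they contribute neither to S nor to
    pi); D is NaN when S = 0.  Requires n >= 4 haplotypes.
    """
    hap = np.asarray(hap)
    n = hap.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    k = hap.sum(axis=0)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    pi = pi_from_counts(k[seg], n) if S else 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    theta_w = S / a1
    if S == 0:
        return DiversityStats(pi=0.0, theta_w=0.0, tajima_d=float("nan"),
                              S=0, n=n)
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    d = (pi - theta_w) / math.sqrt(var)
    return DiversityStats(pi=pi, theta_w=theta_w, tajima_d=d, S=S, n=n)


# ---------------------------------------------------------------------------
# LD r^2
# ---------------------------------------------------------------------------

def ld_r2_pair(h: HaplotypeMatrix, i: int, j: int,
               rows: np.ndarray | None = None) -> float:
    """Squared allelic correlation between sites ``i`` and ``j``.

    ``rows`` restricts the haplotype set (e.g. to one population).  NaN
    when either site is monomorphic in that set.
    """
    hap = h.haplotypes if rows is None else h.haplotypes[rows]
    return _r2_cols(hap[:, i].astype(np.float64), hap[:, j].astype(np.float64))


def _r2_cols(x: np.ndarray, y: np.ndarray) -> float:
    n = x.shape[0]
    pa, pb = x.mean(), y.mean()
    va, vb = pa * (1.0 - pa), pb * (1.0 - pb)
    if va <= 0 or vb <= 0:
        return float("nan")
    pab = (x * y).mean()
    d = pab - pa * pb
    return float(d * d / (va * vb))


def ld_r2_from_haplotypes(hap: np.ndarray) -> np.ndarray:
    """All-pairs r^2 matrix for a (haplotypes x sites) 0/1 array.

    NaN rows/columns for monomorphic sites.
    """
    X = np.asarray(hap, dtype=np.float64)
    n, m = X.shape
    p = X.mean(axis=0)
    v = p * (1.0 - p)
    C = X.T @ X / n - np.outer(p, p)  # covariance of allele indicators
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = C * C / np.outer(v, v)
    r2[v <= 0, :] = np.nan
    r2[:, v <= 0] = np.nan
    return r2
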