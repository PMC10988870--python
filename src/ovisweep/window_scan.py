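"""50-kb window scan: outlier thresholds, Fisher enrichment, sweep calls.

The genome is tiled with consecutive, non-overlapping windows (default
50,000 bp, grid anchored so the window containing 1-based position p is
``floor((p-1)/W)`` — reported bounds read ``iW+1 .. (i+1)W``, i.e. the
grid the scan tables print: 90,600,001-90,650,000).  Per window the scan
records the Weir-Cockerham weighted F_ST (sum a / sum(a+b+c)), the
maximum |XP-EHH z|, a one-sided hypergeometric (Fisher) enrichment p for
high-F_ST SNPs, nucleotide diversity per population, the pi-ratio
(reference / selected, so diversity loss in the selected population
pushes the ratio above 1) and Tajima's D per population.

Candidate sweeps are windows in the top 5% of BOTH the weighted F_ST and
the window XP-EHH statistic with Fisher p below 0.05 (default,
"intersect" rule) or, alternatively, windows in the 1% right tail of the
XP-EHH window statistic; flagged windows closer than 50 kb (gap <= 50,000
inclusive) are merged into single sweep regions and annotated with every
gene interval they overlap by at least 1 bp.

Windows with fewer SNPs than ``min_snps`` (default 10) are masked: all
their statistics are NA and they do not enter the empirical quantiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotype_io import (GeneAnnotation, GenotypeMatrix, HaplotypeMatrix,
                          PopulationAssignment, as_haplotypes)
from .haplotype_statistics import xpehh_scan
from .site_statistics import site_stat_table, tajimas_d
from .variant_filtering import FilterConfig, FilterReport, filter_sites

__all__ = [
    "Window", "SweepRegion", "ScanThresholds", "ScanResult",
    "assign_windows", "compute_window_stats", "empirical_threshold",
    "fisher_window_enrichment", "flag_windows", "call_sweeps",
    "merge_sweeps", "annotate_sweeps", "fine_map_region", "shared_genes",
    "run_scan",
]


@dataclass(frozen=True)
class Window:
    """One tile of the scan grid, 0-based half-open."""

    chrom: str
    index: int
    start: int
    end: int
    site_idx: tuple[int, ...] = ()

    @property
    def n_snps(self) -> int:
        return len(self.site_idx)

    @property
    def start1(self) -> int:
        """Reported 1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """Reported 1-based inclusive end."""
        return self.end


@dataclass
class SweepRegion:
    """A merged candidate sweep interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    windows: list[int] = field(default_factory=list)  # window grid indices
    peak_fst: float = float("nan")
    peak_xpehh: float = float("nan")
    genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ScanThresholds:
    """Outlier and window-definition parameters of the scan."""

    fst_tail: float = 0.05
    xpehh_tail: float = 0.05
    window_tail_1pct: float = 0.01  # alternative 1%-right-tail window rule
    fisher_alpha: float = 0.05
    snp_fst_tail: float = 0.05  # SNP-level tail defining "significant SNPs"
    min_snps: int = 10
    window_size: int = 50_000
    merge_gap: int = 50_000
    fisher_bh: bool = False  # Benjamini-Hochberg on window Fisher p-values

    def __post_init__(self) -> None:
        for name in ("fst_tail", "xpehh_tail", "window_tail_1pct",
                     "fisher_alpha", "snp_fst_tail"):
            v = getattr(self, name)
            # 1.0 allowed as the degenerate flag-everything limit
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def assign_windows(chroms: np.ndarray, positions: np.ndarray,
                   chrom_lengths: dict[str, int],
                   window_size: int = 50_000) -> list[Window]:
    """Tile each chromosome and attach each site to exactly one window.

    ``positions`` are 1-based; 1-based position p lands in window index
    ``(p-1) // window_size``.  Every window of every declared chromosome
    is emitted (empty ones included — they are masked downstream); the
    last window of a chromosome may be short.  A site beyond its
    chromosome's declared length is an error.
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    windows: list[Window] = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        on = np.flatnonzero(chroms == chrom)
        if on.size and positions[on].max() > L:
            p = positions[on].max()
            raise ValueError(
                f"site {chrom}:{p} beyond declared length {L}")
        n_win = max(1, -(-L // window_size))
        wi = (positions[on] - 1) // window_size
        by_window: dict[int, list[int]] = {}
        for site_j, w in zip(on, wi):
            by_window.setdefault(int(w), []).append(int(site_j))
        for i in range(n_win):
            windows.append(Window(
                chrom=chrom, index=i,
                start=i * window_size,
                end=min((i + 1) * window_size, L),
                site_idx=tuple(by_window.get(i, ()))))
    extra = set(np.unique(chroms)) - set(chrom_lengths)
    if extra:
        raise ValueError(f"sites on undeclared chromosomes: {sorted(extra)}")
    return windows


def empirical_threshold(values: np.ndarray, tail: float) -> float:
    """Empirical upper-tail cutoff: the (1 - tail) quantile, "higher".

    An item is an outlier iff value >= cutoff, so ties at the cutoff are
    all included.  Warns (but still answers) when fewer than ``1/tail``
    defined values are available.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined values to take a quantile of")
    if v.size < 1.0 / tail:
        warnings.warn(
            f"only {v.size} defined values for a {tail:.0%} tail; "
            "threshold is unstable", stacklevel=2)
    return float(np.quantile(v, 1.0 - tail, method="higher"))


def fisher_window_enrichment(k: int, m: int, K: int, M: int) -> float:
    """One-sided (greater) hypergeometric tail for window enrichment.

    ``k`` significant SNPs among the window's ``m`` SNPs, given ``K``
    significant among ``M`` genome-wide:
    p = sum_{i >= k} C(K, i) C(M-K, m-i) / C(M, m).
    """
    if not (0 <= k <= m <= M and k <= K <= M):
        raise ValueError(
            f"inconsistent counts k={k}, m={m}, K={K}, M={M}")
    return float(hypergeom.sf(k - 1, M, K, m))


def compute_window_stats(windows: list[Window],
                         site_stats: pd.DataFrame,
                         xpehh: pd.DataFrame | None,
                         h_sel: HaplotypeMatrix | None,
                         h_ref: HaplotypeMatrix | None,
                         thresholds: ScanThresholds | None = None,
                         ) -> pd.DataFrame:
    """Aggregate per-site statistics into the window table.

    ``site_stats`` is the per-site frame from
    :func:`~ovisweep.site_statistics.site_stat_table` on the filtered
    sites; ``windows`` index into its rows.  ``xpehh`` (same site order)
    supplies z-scores; the haplotype matrices supply pi and Tajima's D.
    Windows with fewer than ``min_snps`` sites are fully masked.
    """
    th = thresholds or ScanThresholds()
    fst_site = site_stats["fst_site"].to_numpy()
    snp_cut = empirical_threshold(fst_site, th.snp_fst_tail)
    sig_site = np.isfinite(fst_site) & (fst_site >= snp_cut)
    M = int(np.isfinite(fst_site).sum())
    K = int(sig_site.sum())
    wc_a = site_stats["wc_a"].to_numpy()
    wc_sum = wc_a + site_stats["wc_b"].to_numpy() \
        + site_stats["wc_c"].to_numpy()
    z = xpehh["z"].to_numpy() if xpehh is not None else None

    rows = []
    for w in windows:
        idx = np.array(w.site_idx, dtype=np.int64)
        rec = {
            "chrom": w.chrom, "window": w.index,
            "start1": w.start1, "end1": w.end1, "n_snps": w.n_snps,
            "weighted_fst": np.nan, "max_abs_xpehh": np.nan,
            "n_sig_snps": np.nan, "fisher_p": np.nan,
            "pi_sel": np.nan, "pi_ref": np.nan, "pi_ratio": np.nan,
            "log2_pi_ratio": np.nan,
            "tajd_sel": np.nan, "tajd_ref": np.nan,
        }
        if w.n_snps >= th.min_snps:
            a = wc_a[idx]
            s = wc_sum[idx]
            ok = np.isfinite(a) & np.isfinite(s)
            if ok.any() and s[ok].sum() > 0:
                rec["weighted_fst"] = a[ok].sum() / s[ok].sum()
            if z is not None:
                zw = z[idx]
                zw = zw[np.isfinite(zw)]
                if zw.size:
                    rec["max_abs_xpehh"] = float(np.abs(zw).max())
            k = int(sig_site[idx].sum())
            m = int(np.isfinite(fst_site[idx]).sum())
            rec["n_sig_snps"] = k
            if m > 0 and M > 0:
                rec["fisher_p"] = fisher_window_enrichment(k, m, K, M)
            if h_sel is not None and h_sel.n_haplotypes >= 4:
                d = tajimas_d(h_sel.haplotypes[:, idx])
                rec["pi_sel"], rec["tajd_sel"] = d.pi, d.tajima_d
            if h_ref is not None and h_ref.n_haplotypes >= 4:
                d = tajimas_d(h_ref.haplotypes[:, idx])
                rec["pi_ref"], rec["tajd_ref"] = d.pi, d.tajima_d
            if np.isfinite(rec["pi_sel"]) and np.isfinite(rec["pi_ref"]) \
                    and rec["pi_sel"] > 0:
                rec["pi_ratio"] = rec["pi_ref"] / rec["pi_sel"]
                if rec["pi_ratio"] > 0:
                    rec["log2_pi_ratio"] = np.log2(rec["pi_ratio"])
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["snp_fst_cutoff"] = snp_cut
    out.attrs["n_sig_genomewide"] = K
    out.attrs["n_snps_genomewide"] = M
    return out


def flag_windows(table: pd.DataFrame, thresholds: ScanThresholds | None = None,
                 rule: str = "intersect") -> pd.DataFrame:
    """Add outlier flag columns; returns a copy with table.attrs cutoffs.

    rule="intersect": top-``fst_tail`` weighted F_ST AND top-``xpehh_tail``
    window XP-EHH AND Fisher p below alpha.  rule="xpehh_1pct": the 1%
    right tail of the window XP-EHH statistic alone.
    """
    th = thresholds or ScanThresholds()
    t = table.copy()
    fst = t["weighted_fst"].to_numpy(dtype=float)
    xp = t["max_abs_xpehh"].to_numpy(dtype=float)
    fst_cut = empirical_threshold(fst, th.fst_tail)
    xp_cut = empirical_threshold(xp, th.xpehh_tail)
    t["fst_outlier"] = np.isfinite(fst) & (fst >= fst_cut)
    t["xpehh_outlier"] = np.isfinite(xp) & (xp >= xp_cut)
    p = t["fisher_p"].to_numpy(dtype=float)
    if th.fisher_bh:
        from scipy.stats import false_discovery_control
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = false_discovery_control(p[ok], method="bh")
        t["fisher_sig"] = np.isfinite(q) & (q < th.fisher_alpha)
    else:
        t["fisher_sig"] = np.isfinite(p) & (p < th.fisher_alpha)
    if rule == "intersect":
        t["sweep_flag"] = (t["fst_outlier"] & t["xpehh_outlier"]
                           & t["fisher_sig"])
    elif rule == "xpehh_1pct":
        xp1_cut = empirical_threshold(xp, th.window_tail_1pct)
        t["sweep_flag"] = np.isfinite(xp) & (xp >= xp1_cut)
        t.attrs["xpehh_1pct_cutoff"] = xp1_cut
    else:
        raise ValueError(f"unknown sweep rule {rule!r}")
    t.attrs.update(table.attrs)
    t.attrs["fst_cutoff"] = fst_cut
    t.attrs["xpehh_cutoff"] = xp_cut
    return t


def call_sweeps(table: pd.DataFrame,
                thresholds: ScanThresholds | None = None,
                rule: str = "intersect") -> list[SweepRegion]:
    """Flag outlier windows, convert them to regions and merge.

    Returns merged :class:`SweepRegion` list (possibly empty), sorted by
    (chrom, start).
    """
    th = thresholds or ScanThresholds()
    t = flag_windows(table, th, rule)
    regions = [
        SweepRegion(chrom=row.chrom, start=int(row.start1) - 1,
                    end=int(row.end1), windows=[int(row.window)],
                    peak_fst=float(row.weighted_fst),
                    peak_xpehh=float(row.max_abs_xpehh))
        for row in t[t["sweep_flag"]].itertuples()
    ]
    return merge_sweeps(regions, th.merge_gap)


def merge_sweeps(regions: list[SweepRegion],
                 merge_gap: int = 50_000) -> list[SweepRegion]:
    """Merge same-chromosome regions separated by at most ``merge_gap``.

    The gap is ``next.start - prev.end``; merging applies when it is
    <= merge_gap ("within a distance of 50,000 bp" is inclusive) and is
    transitive.  Peak statistics are member maxima.  Idempotent and
    independent of input order.
    """
    if not regions:
        return []
    regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[SweepRegion] = []
    cur = replace(regs[0], windows=list(regs[0].windows),
                  genes=list(regs[0].genes))
    for r in regs[1:]:
        if r.chrom == cur.chrom and r.start - cur.end <= merge_gap:
            cur.end = max(cur.end, r.end)
            cur.windows = sorted(set(cur.windows) | set(r.windows))
            for attr in ("peak_fst", "peak_xpehh"):
                vals = [v for v in (getattr(cur, attr), getattr(r, attr))
                        if v is not None and not math.isnan(v)]
                setattr(cur, attr, max(vals) if vals else float("nan"))
            cur.genes = sorted(set(cur.genes) | set(r.genes))
        else:
            out.append(cur)
            cur = replace(r, windows=list(r.windows), genes=list(r.genes))
    out.append(cur)
    return out


def annotate_sweeps(sweeps: list[SweepRegion],
                    genes: list[GeneAnnotation]) -> list[SweepRegion]:
    """Attach every gene overlapping each sweep by >= 1 bp (half-open).

    A gene abutting the sweep boundary (gene.end == sweep.start) is not
    attached.  Returns new regions; gene names sorted.
    """
    out = []
    for sw in sweeps:
        hit = sorted({g.name for g in genes
                      if g.chrom == sw.chrom
                      and g.start < sw.end and sw.start < g.end})
        out.append(replace(sw, windows=list(sw.windows), genes=hit))
    return out


def fine_map_region(h_sel: HaplotypeMatrix, h_ref: HaplotypeMatrix,
                    chrom: str, start: int, end: int,
                    sub_window: int = 50_000, step: int | None = None,
                    xpehh: pd.DataFrame | None = None,
                    min_snps: int = 1) -> pd.DataFrame:
    """Sliding sub-window statistics across a candidate region.

    ``start``/``end`` are 0-based half-open; sub-windows of ``sub_window``
    bp slide by ``step`` (default: non-overlapping).  The XP-EHH z-scores
    come from the genome-wide scan (pass its frame via ``xpehh`` to keep
    the genome-wide standardization; otherwise it is computed here over
    the full matrices).  Returns a plot-ready frame with start1/end1,
    max |XP-EHH z|, Tajima's D per population and the pi-ratio.
    """
    if step is None:
        step = sub_window
    if xpehh is None:
        xpehh = xpehh_scan(h_sel, h_ref)
    pos = h_sel.positions  # 1-based
    chroms = h_sel.chroms
    z = xpehh["z"].to_numpy()
    rows = []
    s = start
    while s < end:
        e = min(s + sub_window, end)
        idx = np.flatnonzero((chroms == chrom) & (pos >= s + 1) & (pos <= e))
        rec = {"chrom": chrom, "start1": s + 1, "end1": e,
               "n_snps": idx.size, "max_abs_xpehh": np.nan,
               "tajd_sel": np.nan, "tajd_ref": np.nan,
               "pi_sel": np.nan, "pi_ref": np.nan, "pi_ratio": np.nan}
        if idx.size >= min_snps and idx.size > 0:
            zw = z[idx]
            zw = zw[np.isfinite(zw)]
            if zw.size:
                rec["max_abs_xpehh"] = float(np.abs(zw).max())
            if h_sel.n_haplotypes >= 4:
                d = tajimas_d(h_sel.haplotypes[:, idx])
                rec["pi_sel"], rec["tajd_sel"] = d.pi, d.tajima_d
            if h_ref.n_haplotypes >= 4:
                d = tajimas_d(h_ref.haplotypes[:, idx])
                rec["pi_ref"], rec["tajd_ref"] = d.pi, d.tajima_d
            if np.isfinite(rec["pi_sel"]) and rec["pi_sel"] > 0 \
                    and np.isfinite(rec["pi_ref"]):
                rec["pi_ratio"] = rec["pi_ref"] / rec["pi_sel"]
        rows.append(rec)
        if e >= end:
            break
        s += step
    return pd.DataFrame(rows)


def shared_genes(scans: dict[str, set[str] | list[str]]) -> dict:
    """Genes common to all scans plus per-pair intersections.

    Returns {"all": sorted list, ("a", "b"): sorted list, ...} with scan
    names in lexicographic order.  Requires >= 2 scans.
    """
    if len(scans) < 2:
        raise ValueError("need >= 2 scans to intersect")
    sets = {k: set(v) for k, v in scans.items()}
    names = sorted(sets)
    out: dict = {"all": sorted(set.intersection(*sets.values()))}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = sorted(sets[a] & sets[b])
    return out


# ---------------------------------------------------------------------------
# End-to-end scan orchestration (library level)
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """All artifacts of one selected-vs-reference scan."""

    table: pd.DataFrame  # window statistics + flags
    sweeps: list[SweepRegion]
    site_stats: pd.DataFrame
    xpehh: pd.DataFrame
    filter_report: FilterReport
    thresholds: ScanThresholds


def run_scan(g: GenotypeMatrix, assignment: PopulationAssignment,
             chrom_lengths: dict[str, int],
             thresholds: ScanThresholds | None = None,
             filter_config: FilterConfig | None = None,
             genes: list[GeneAnnotation] | None = None,
             rule: str = "intersect") -> ScanResult:
    """Filter -> site stats -> XP-EHH -> windows -> sweep calls.

    ``assignment`` must carry the scan pair (selected / reference).  The
    matrix is subset to the pair's samples, re-filtered on that subset,
    and must be phased (XP-EHH needs haplotypes).
    """
    th = thresholds or ScanThresholds()
    if assignment.selected is None or assignment.reference is None:
        raise ValueError("assignment must designate selected and reference")
    sel = assignment.samples_of(assignment.selected)
    ref = assignment.samples_of(assignment.reference)
    gg, report = filter_sites(g, filter_config, samples=sel + ref)
    hap = as_haplotypes(gg)
    h_sel = hap.subset(sel)
    h_ref = hap.subset(ref)
    stats = site_stat_table(gg, sel, ref)
    xp = xpehh_scan(h_sel, h_ref, maf_min=0.05)
    windows = assign_windows(gg.chroms, gg.positions, chrom_lengths,
                             th.window_size)
    table = compute_window_stats(windows, stats, xp, h_sel, h_ref, th)
    table = flag_windows(table, th, rule)
    sweeps = call_sweeps(table, th, rule)
    if genes:
        sweeps = annotate_sweeps(sweeps, genes)
    return ScanResult(table=table, sweeps=sweeps, site_stats=stats,
                      xpehh=xp, filter_report=report, thresholds=th)
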