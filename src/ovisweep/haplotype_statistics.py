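"""EHH decay, integrated haplotype homozygosity, and XP-EHH.

Extended haplotype homozygosity (EHH) at extension distance x from a
core site is the probability that two haplotypes drawn at random from
the scope are identical over every site between the core and x.  For the
cross-population statistic the scope is *all* haplotypes of a population
(no partition by core allele); the curve starts at 1 at the core and the
core site's own alleles do not split the groups, matching selscan's
XP-EHH computation.

iHH is the trapezoidal integral of the EHH curve over physical distance
(bp), summed over the upstream and downstream directions and truncated
at the first extension site whose EHH falls below the cutoff (default
0.05, the selscan default).  XP-EHH at a core site is
ln(iHH_sel / iHH_ref), standardized genome-wide to mean 0, sd 1 in a
single bin.

Scores are undefined (NaN) when either curve is edge-truncated (reaches
the end of the chromosome before decaying below the cutoff; retention is
switchable), crosses an inter-site gap larger than ``max_gap`` (200 kb,
the selscan guard), or integrates to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix

__all__ = ["EhhCurve", "ehh", "ihh", "xpehh_site", "xpehh_scan",
           "standardize_xpehh"]

EHH_CUTOFF_DEFAULT = 0.05
MAX_GAP_DEFAULT = 200_000


@dataclass
class EhhCurve:
    """EHH values at physical offsets from a core site, one direction."""

    core: int  # site index of the core
    direction: str  # "upstream" (decreasing pos) or "downstream"
    offsets: np.ndarray  # bp distances from the core, offsets[0] == 0
    values: np.ndarray  # EHH at each offset, values[0] == 1
    n_core: int  # haplotypes in scope
    edge_truncated: bool  # hit the chromosome end before the cutoff
    gap_exceeded: bool  # crossed a gap > max_gap


def _ehh_walk(hap: np.ndarray, pos: np.ndarray, core: int, step: int,
              cutoff: float, max_gap: int | None,
              ) -> tuple[list[int], list[float], bool, bool]:
    """Walk from the core in one direction, tracking haplotype groups."""
    n = hap.shape[0]
    pairs_tot = n * (n - 1) / 2.0
    offsets = [0]
    values = [1.0]
    # group ids in [0, k); splitting by the next site maps them to
    # [0, 2k) and a bincount-based compression keeps them dense
    groups = np.zeros(n, dtype=np.int64)
    k = 1
    j = core
    gap_exceeded = False
    edge = False
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= hap.shape[1]:
            edge = True
            break
        if max_gap is not None and abs(int(pos[nxt]) - int(pos[j])) > max_gap:
            gap_exceeded = True
            break
        groups = groups * 2 + hap[:, nxt]
        counts = np.bincount(groups, minlength=2 * k)
        present = counts > 0
        cc = counts[present]
        e = float((cc * (cc - 1)).sum() / 2.0 / pairs_tot)
        remap = np.cumsum(present) - 1
        groups = remap[groups]
        k = int(present.sum())
        offsets.append(abs(int(pos[nxt]) - int(pos[core])))
        values.append(e)
        if e < cutoff:
            break
        j = nxt
    return offsets, values, edge, gap_exceeded


def ehh(h: HaplotypeMatrix | np.ndarray, core: int, direction: str,
        cutoff: float = EHH_CUTOFF_DEFAULT,
        max_gap: int | None = MAX_GAP_DEFAULT,
        positions: np.ndarray | None = None) -> EhhCurve:
    """EHH decay curve from ``core`` in one direction.

    Accepts a :class:`HaplotypeMatrix` or a raw (haplotypes x sites)
    array plus ``positions``.  The curve extends site by site until EHH
    drops below ``cutoff``, a gap larger than ``max_gap`` is met, or the
    chromosome ends; the first sub-cutoff value is included as the final
    point.  Values are non-increasing and in [0, 1]; the zero-length
    extension has EHH = 1.
    """
    if isinstance(h, HaplotypeMatrix):
        hap, pos = h.haplotypes, h.positions
    else:
        hap = np.asarray(h)
        if positions is None:
            raise ValueError("positions required with a raw array")
        pos = np.asarray(positions)
    if hap.shape[0] < 2:
        raise ValueError("EHH needs >= 2 haplotypes")
    if not 0 <= core < hap.shape[1]:
        raise IndexError(f"core index {core} out of bounds")
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    step = -1 if direction == "upstream" else 1
    offsets, values, edge, gap = _ehh_walk(hap, pos, core, step, cutoff,
                                           max_gap)
    return EhhCurve(core=core, direction=direction,
                    offsets=np.array(offsets, dtype=np.int64),
                    values=np.array(values, dtype=np.float64),
                    n_core=hap.shape[0], edge_truncated=edge,
                    gap_exceeded=gap)


def _integrate(offsets: np.ndarray, values: np.ndarray,
               cutoff: float) -> float:
    """Trapezoid area over segments whose far endpoint stays >= cutoff."""
    area = 0.0
    for k in range(1, len(offsets)):
        if values[k] < cutoff:
            break
        area += (values[k - 1] + values[k]) / 2.0 * (offsets[k]
                                                     - offsets[k - 1])
    return area


def ihh(h: HaplotypeMatrix | np.ndarray, core: int,
        cutoff: float = EHH_CUTOFF_DEFAULT,
        max_gap: int | None = MAX_GAP_DEFAULT,
        positions: np.ndarray | None = None) -> tuple[float, bool]:
    """Integrated EHH over both directions; returns (value, truncated).

    ``truncated`` is True when either directional curve hit a chromosome
    edge or an oversized gap before decaying below the cutoff — such
    integrals are incomplete and the enclosing XP-EHH score is dropped
    by default.
    """
    up = ehh(h, core, "upstream", cutoff, max_gap, positions)
    down = ehh(h, core, "downstream", cutoff, max_gap, positions)
    area = (_integrate(up.offsets, up.values, cutoff)
            + _integrate(down.offsets, down.values, cutoff))
    truncated = (up.edge_truncated or down.edge_truncated
                 or up.gap_exceeded or down.gap_exceeded)
    return area, truncated


def xpehh_site(h_sel: HaplotypeMatrix | np.ndarray,
               h_ref: HaplotypeMatrix | np.ndarray,
               core: int,
               cutoff: float = EHH_CUTOFF_DEFAULT,
               max_gap: int | None = MAX_GAP_DEFAULT,
               positions: np.ndarray | None = None,
               keep_truncated: bool = False,
               ) -> tuple[float, float, float]:
    """Raw XP-EHH at one core: (ihh_sel, ihh_ref, ln ratio).

    The raw score is NaN when either iHH is 0 or (unless
    ``keep_truncated``) edge/gap-truncated.  Both matrices must share
    the same site list.
    """
    i_sel, t_sel = ihh(h_sel, core, cutoff, max_gap, positions)
    i_ref, t_ref = ihh(h_ref, core, cutoff, max_gap, positions)
    raw = float("nan")
    if i_sel > 0 and i_ref > 0 and (keep_truncated or not (t_sel or t_ref)):
        # difference of logs, so swapping populations negates exactly
        raw = float(np.log(i_sel) - np.log(i_ref))
    return i_sel, i_ref, raw


def xpehh_scan(h_sel: HaplotypeMatrix, h_ref: HaplotypeMatrix,
               maf_min: float = 0.05,
               cutoff: float = EHH_CUTOFF_DEFAULT,
               max_gap: int | None = MAX_GAP_DEFAULT,
               keep_truncated: bool = False,
               standardize: bool = True) -> pd.DataFrame:
    """XP-EHH at every core site with pooled MAF strictly above ``maf_min``.

    Returns a frame with chrom, pos, p_sel, p_ref, ihh_sel, ihh_ref, raw
    and (if ``standardize``) z.  Sites failing the MAF gate or with an
    undefined score carry NaN in raw/z.
    """
    if [s.pos for s in h_sel.sites] != [s.pos for s in h_ref.sites]:
        raise ValueError("selected and reference matrices must share sites")
    hap1, hap2 = h_sel.haplotypes, h_ref.haplotypes
    pos = h_sel.positions
    chroms = h_sel.chroms
    p1 = hap1.mean(axis=0)
    p2 = hap2.mean(axis=0)
    n1, n2 = hap1.shape[0], hap2.shape[0]
    p_pool = (hap1.sum(axis=0) + hap2.sum(axis=0)) / (n1 + n2)
    maf = np.minimum(p_pool, 1.0 - p_pool)
    m = hap1.shape[1]
    ihh_sel = np.full(m, np.nan)
    ihh_ref = np.full(m, np.nan)
    raw = np.full(m, np.nan)
    # Per-chromosome: curves must not cross a chromosome boundary.
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub1, sub2, subpos = hap1[:, idx], hap2[:, idx], pos[idx]
        for k, j in enumerate(idx):
            if not maf[j] > maf_min:
                continue
            i1, i2, r = xpehh_site(sub1, sub2, k, cutoff, max_gap,
                                   positions=subpos,
                                   keep_truncated=keep_truncated)
            ihh_sel[j], ihh_ref[j], raw[j] = i1, i2, r
    out = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "p_sel": p1, "p_ref": p2,
        "ihh_sel": ihh_sel, "ihh_ref": ihh_ref, "raw": raw,
    })
    if standardize:
        out["z"] = standardize_xpehh(out["raw"].to_numpy())
    return out


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-scores: (raw - mean)/sd over all defined scores.

    Single-bin standardization with the population (ddof=0) standard
    deviation; NaN entries stay NaN.  Requires >= 2 defined scores with
    nonzero spread.
    """
    raw = np.asarray(raw, dtype=np.float64)
    ok = np.isfinite(raw)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined raw scores to standardize")
    mu = raw[ok].mean()
    sd = raw[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("raw scores have zero spread; cannot standardize")
    z = np.full_like(raw, np.nan)
    z[ok] = (raw[ok] - mu) / sd
    return z
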