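"""SNP inclusion rules applied before structure and sweep analyses.

Sites are kept when they are biallelic, have a missing rate of at most
the threshold (strictly: removed when the rate is *higher than* 10%),
and a minor allele frequency strictly *higher than* 5%.  The inequalities
are strict at both boundaries: a site with exactly 10% missing genotypes
survives the missingness rule and a site with MAF exactly 0.05 is removed
by the frequency rule.

The missing rate and MAF are computed on the samples entering the current
analysis (each scan subsets breeds, so per-scan re-filtering is the
default); MAF is pooled over the scan pair unless ``per_population`` is
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["FilterConfig", "FilterReport", "allele_frequency",
           "allele_frequencies", "filter_sites"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the SNP inclusion rules.

    max_missing_rate
        Sites with a missing-genotype fraction strictly greater than this
        are removed (default 0.10).
    maf_min
        Sites with minor allele frequency not strictly greater than this
        are removed (default 0.05).
    biallelic_only
        Remove sites with more than one ALT allele (default True).
    per_population_maf
        Apply the MAF rule within each listed sample group separately (a
        site must pass in every group) instead of on the pooled samples.
    """

    max_missing_rate: float = 0.10
    maf_min: float = 0.05
    biallelic_only: bool = True
    per_population_maf: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    n_in: int = 0
    removed_biallelic: int = 0
    removed_missing: int = 0
    removed_maf: int = 0

    @property
    def n_out(self) -> int:
        return (self.n_in - self.removed_biallelic - self.removed_missing
                - self.removed_maf)

    def to_tsv(self) -> str:
        lines = ["rule\tremoved",
                 f"biallelic\t{self.removed_biallelic}",
                 f"missing_rate\t{self.removed_missing}",
                 f"maf\t{self.removed_maf}",
                 f"sites_in\t{self.n_in}",
                 f"sites_out\t{self.n_out}"]
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:  # log-friendly one-liner
        return (f"{self.n_in} sites in: removed {self.removed_biallelic} "
                f"multi-allelic, {self.removed_missing} by missing rate, "
                f"{self.removed_maf} by MAF; {self.n_out} retained")


def _sample_indices(g: GenotypeMatrix,
                    samples: list[str] | None) -> np.ndarray:
    if samples is None:
        return np.arange(g.n_samples)
    pos = {s: i for i, s in enumerate(g.samples)}
    unknown = [s for s in samples if s not in pos]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    return np.array([pos[s] for s in samples], dtype=np.int64)


def allele_frequency(g: GenotypeMatrix, site: int,
                     samples: list[str] | None = None,
                     ) -> tuple[float, int]:
    """ALT-allele frequency and called allele count at one site.

    Missing genotypes are excluded from numerator and denominator.
    Returns ``(nan, 0)`` when every genotype in the subset is missing.
    """
    idx = _sample_indices(g, samples)
    if idx.size == 0:
        raise ValueError("sample subset is empty")
    d = g.dosage[idx, site]
    called = d != MISSING
    n = 2 * int(called.sum())
    if n == 0:
        return float("nan"), 0
    return float(d[called].sum()) / n, n


def allele_frequencies(g: GenotypeMatrix,
                       samples: list[str] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`allele_frequency` over all sites.

    Returns ``(freq, n_alleles)`` arrays; frequency is NaN where no
    genotype is called.
    """
    idx = _sample_indices(g, samples)
    if idx.size == 0:
        raise ValueError("sample subset is empty")
    d = g.dosage[idx, :]
    called = d != MISSING
    n = 2 * called.sum(axis=0).astype(np.int64)
    alt = np.where(called, d, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return freq, n


def filter_sites(g: GenotypeMatrix, cfg: FilterConfig | None = None,
                 samples: list[str] | None = None,
                 groups: list[list[str]] | None = None,
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the inclusion rules; returns the surviving matrix + report.

    Rules are applied per site in the order biallelic -> missingness ->
    MAF, and each removed site is counted under the first rule it trips
    (the rules are independent, so the surviving set does not depend on
    the order).  ``samples`` restricts the matrix (and all rates) to the
    analysis subset; ``groups`` lists the sample groups for
    ``per_population_maf``.
    """
    cfg = cfg or FilterConfig()
    if samples is not None:
        g = g.take_samples(samples)
    report = FilterReport(n_in=g.n_sites)
    if g.n_sites == 0:
        return g, report

    biallelic = np.array([s.is_biallelic for s in g.sites])
    called = g.dosage != MISSING
    missing_rate = 1.0 - called.sum(axis=0) / g.n_samples

    def maf_of(subset: list[str] | None) -> np.ndarray:
        freq, _ = allele_frequencies(g, subset)
        return np.minimum(freq, 1.0 - freq)

    if cfg.per_population_maf and groups:
        maf_pass = np.ones(g.n_sites, dtype=bool)
        for grp in groups:
            m = maf_of(grp)
            maf_pass &= np.nan_to_num(m, nan=-1.0) > cfg.maf_min
    else:
        m = maf_of(None)
        maf_pass = np.nan_to_num(m, nan=-1.0) > cfg.maf_min

    ok_bi = biallelic | (not cfg.biallelic_only)
    ok_miss = missing_rate <= cfg.max_missing_rate  # removed when strictly >
    keep = ok_bi & ok_miss & maf_pass

    report.removed_biallelic = int((~ok_bi).sum())
    report.removed_missing = int((ok_bi & ~ok_miss).sum())
    report.removed_maf = int((ok_bi & ok_miss & ~maf_pass).sum())
    return g.take_sites(np.flatnonzero(keep)), report
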