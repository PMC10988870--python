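"""Genotype/haplotype data model and readers/writers for the standard formats.

The scan pipeline touches five external formats: VCF v4.x (genotypes, GT
field only), a two-column whitespace-delimited sample->population file,
BED4+/GFF3 gene annotation, TSV window tables and BED sweep output.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  VCF positions (1-based)
are converted at the boundary; report writers re-convert to 1-based
inclusive, which is the convention genome-scan tables are usually printed
in (a 50-kb window grid reads ``90,600,001-90,650,000``).  BED is native
0-based half-open; GFF3 (1-based inclusive) is converted on read.

Chromosome names are matched by exact string comparison; an optional
rename map can be supplied to the readers to reconcile naming schemes
(e.g. ``{"chr7": "7"}``) — there is no silent "chr" normalization.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "PopulationAssignment",
    "GeneAnnotation",
    "read_vcf",
    "write_vcf",
    "as_haplotypes",
    "from_haplotypes",
    "read_population_file",
    "read_gene_annotation",
    "write_window_table",
    "read_window_table",
    "write_sweep_bed",
]

#: Sentinel for a missing diploid genotype in ``GenotypeMatrix.dosage``.
#: Distinct from 0 (homozygous reference) everywhere.
MISSING: int = -1


@dataclass(frozen=True)
class VariantSite:
    """A single variant record: 1-based position, REF and ALT allele(s)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    id: str | None
    ref: str
    alt: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if any(a == self.ref for a in self.alt):
            raise ValueError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes at a set of ordered sites.

    ``dosage[i, j]`` is the ALT-allele count (0/1/2) of sample ``i`` at
    site ``j``, or :data:`MISSING`.  ``alleles[i, j]`` holds the two
    allele indices as called (order preserved from the VCF GT field,
    ``-1`` for ``.``), and ``phased[i, j]`` whether the ``|`` separator
    was used — together these round-trip the GT string exactly.
    """

    sites: list[VariantSite]
    samples: list[str]
    dosage: np.ndarray  # (n_samples, n_sites) int16, MISSING sentinel
    alleles: np.ndarray  # (n_samples, n_sites, 2) int8, -1 missing
    phased: np.ndarray  # (n_samples, n_sites) bool

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.sites)
        if self.dosage.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != ({n}, {m})")
        if self.alleles.shape != (n, m, 2):
            raise ValueError("alleles shape mismatch")
        if self.phased.shape != (n, m):
            raise ValueError("phased shape mismatch")
        prev: tuple[str, int] | None = None
        seen: set[str] = set()
        for s in self.sites:
            if prev is not None and s.chrom == prev[0] and s.pos <= prev[1]:
                raise ValueError(
                    f"sites not strictly increasing at {s.chrom}:{s.pos}")
            if prev is not None and s.chrom != prev[0]:
                if s.chrom in seen:
                    raise ValueError(f"chromosome {s.chrom} not contiguous")
                seen.add(prev[0])
            prev = (s.chrom, s.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions as an int64 array."""
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sites=[self.sites[int(j)] for j in idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx].copy(),
            alleles=self.alleles[:, idx].copy(),
            phased=self.phased[:, idx].copy(),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        idx = np.array([pos[n] for n in names], dtype=np.int64)
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=list(names),
            dosage=self.dosage[idx].copy(),
            alleles=self.alleles[idx].copy(),
            phased=self.phased[idx].copy(),
        )


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: rows ``2i``/``2i+1`` are sample ``i``.

    No missing entries (phased-input contract); allele codes 0/1 only.
    """

    sites: list[VariantSite]
    samples: list[str]
    haplotypes: np.ndarray  # (2*n_samples, n_sites) uint8

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError("haplotype shape mismatch")
        if self.haplotypes.size and not np.isin(
                self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype allele codes must be 0/1")
        for s in self.sites:
            if not s.is_biallelic:
                raise ValueError(
                    f"site {s.chrom}:{s.pos} is not biallelic")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def sample_haplotype_rows(self, names: list[str]) -> np.ndarray:
        """Haplotype row indices (2 per sample) for the named samples."""
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        rows = []
        for n in names:
            rows.extend((2 * pos[n], 2 * pos[n] + 1))
        return np.array(rows, dtype=np.int64)

    def subset(self, names: list[str]) -> "HaplotypeMatrix":
        rows = self.sample_haplotype_rows(names)
        return HaplotypeMatrix(
            sites=list(self.sites),
            samples=list(names),
            haplotypes=self.haplotypes[rows].copy(),
        )

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        return HaplotypeMatrix(
            sites=[self.sites[int(j)] for j in idx],
            samples=list(self.samples),
            haplotypes=self.haplotypes[:, idx].copy(),
        )


@dataclass
class PopulationAssignment:
    """Sample -> population label map plus the scan pair designation."""

    assignment: dict[str, str]
    selected: str | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        for pop in (self.selected, self.reference):
            if pop is not None and pop not in self.assignment.values():
                raise ValueError(f"population {pop!r} has no samples")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == pop]

    def with_pair(self, selected: str, reference: str) -> "PopulationAssignment":
        return PopulationAssignment(dict(self.assignment), selected, reference)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval, stored 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.name}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi)


def read_vcf(path: str | os.PathLike,
             region: str | None = None,
             rename: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read GT genotypes from a VCF (optionally bgzipped) into a matrix.

    Only the GT FORMAT field is consumed.  Dosage is the ALT-allele count
    of the genotype (any ALT for multi-allelic records, which are retained
    with their full ALT list and filtered later); ``./.`` and ``.|.`` map
    to :data:`MISSING`.  ``region`` is ``chrom`` or ``chrom:start-end``
    (1-based inclusive); a region with no records yields an empty matrix.
    Ploidy other than 2 is rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=False)
    samples = list(vcf.samples)
    want: tuple[str, int, int] | None = (
        _parse_region(region) if region else None)

    sites: list[VariantSite] = []
    dos_cols: list[np.ndarray] = []
    allele_cols: list[np.ndarray] = []
    phase_cols: list[np.ndarray] = []
    for rec_i, rec in enumerate(vcf):
        chrom = rec.CHROM
        if rename:
            chrom = rename.get(chrom, chrom)
        if want is not None:
            wchrom, lo, hi = want
            if chrom != wchrom or not (lo <= rec.POS <= hi):
                continue
        gts = rec.genotypes  # list of [a0, a1, phased] per sample
        a = np.full((len(samples), 2), -1, dtype=np.int8)
        ph = np.zeros(len(samples), dtype=bool)
        d = np.full(len(samples), MISSING, dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) != 3:  # [allele, phased] => haploid; longer => polyploid
                raise ValueError(
                    f"non-diploid GT for sample {samples[i]} at record "
                    f"{rec_i + 1} ({chrom}:{rec.POS})")
            a0, a1 = g[0], g[1]
            ph[i] = bool(g[2])
            if a0 < 0 or a1 < 0:
                if not (a0 < 0 and a1 < 0):
                    raise ValueError(
                        f"half-missing GT for sample {samples[i]} at record "
                        f"{rec_i + 1} ({chrom}:{rec.POS})")
                continue
            a[i] = (a0, a1)
            d[i] = int(a0 > 0) + int(a1 > 0)
        sites.append(VariantSite(
            chrom=chrom, pos=rec.POS,
            id=None if rec.ID in (None, ".") else rec.ID,
            ref=rec.REF, alt=tuple(rec.ALT)))
        dos_cols.append(d)
        allele_cols.append(a)
        phase_cols.append(ph)
    vcf.close()

    n = len(samples)
    m = len(sites)
    if m == 0:
        return GenotypeMatrix(
            sites=[], samples=samples,
            dosage=np.empty((n, 0), dtype=np.int16),
            alleles=np.empty((n, 0, 2), dtype=np.int8),
            phased=np.empty((n, 0), dtype=bool))
    order = sorted(range(m), key=lambda j: (sites[j].chrom, sites[j].pos))
    return GenotypeMatrix(
        sites=[sites[j] for j in order],
        samples=samples,
        dosage=np.stack([dos_cols[j] for j in order], axis=1),
        alleles=np.stack([allele_cols[j] for j in order], axis=1),
        phased=np.stack([phase_cols[j] for j in order], axis=1),
    )


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike,
              contigs: dict[str, int] | None = None) -> None:
    """Write the matrix back out as a minimal GT-only VCF v4.2 file."""
    with io.open(os.fspath(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ovisweep\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, site in enumerate(g.sites):
            cols = [site.chrom, str(site.pos), site.id or ".", site.ref,
                    ",".join(site.alt), ".", ".", ".", "GT"]
            for i in range(g.n_samples):
                a0, a1 = g.alleles[i, j]
                sep = "|" if g.phased[i, j] else "/"
                if a0 < 0:
                    cols.append(f".{sep}.")
                else:
                    cols.append(f"{a0}{sep}{a1}")
            fh.write("\t".join(cols) + "\n")


def as_haplotypes(g: GenotypeMatrix) -> HaplotypeMatrix:
    """Split phased diploid genotypes into a 2n x m haplotype matrix.

    Requires every genotype phased (``|``) and non-missing, and every
    site biallelic; haplotype rows ``2i``/``2i+1`` are sample ``i``'s
    left/right alleles in VCF order.
    """
    bad_sites = [s for s in g.sites if not s.is_biallelic]
    if bad_sites:
        s = bad_sites[0]
        raise ValueError(
            f"{len(bad_sites)} multi-allelic site(s), first at "
            f"{s.chrom}:{s.pos}; filter to biallelic sites first")
    miss = np.argwhere(g.dosage == MISSING)
    if miss.size:
        i, j = miss[0]
        s = g.sites[int(j)]
        raise ValueError(
            f"missing genotype(s), first for sample {g.samples[int(i)]} at "
            f"{s.chrom}:{s.pos}; haplotypes require complete phased calls")
    unph = np.argwhere(~g.phased)
    if unph.size:
        i, j = unph[0]
        s = g.sites[int(j)]
        raise ValueError(
            f"unphased genotype(s), first for sample {g.samples[int(i)]} at "
            f"{s.chrom}:{s.pos}; phase upstream before haplotype analysis")
    hap = np.empty((2 * g.n_samples, g.n_sites), dtype=np.uint8)
    hap[0::2] = g.alleles[:, :, 0]
    hap[1::2] = g.alleles[:, :, 1]
    return HaplotypeMatrix(
        sites=list(g.sites), samples=list(g.samples), haplotypes=hap)


# ---------------------------------------------------------------------------
# Population file / gene annotation
# ---------------------------------------------------------------------------

def from_haplotypes(h: HaplotypeMatrix) -> GenotypeMatrix:
    """Pair haplotype rows back into phased diploid genotypes.

    Inverse of :func:`as_haplotypes`: rows ``2i``/``2i+1`` become sample
    ``i``'s left/right alleles, all genotypes phased.
    """
    n = len(h.samples)
    alleles = np.empty((n, h.n_sites, 2), dtype=np.int8)
    alleles[:, :, 0] = h.haplotypes[0::2]
    alleles[:, :, 1] = h.haplotypes[1::2]
    dosage = (h.haplotypes[0::2].astype(np.int16)
              + h.haplotypes[1::2].astype(np.int16))
    return GenotypeMatrix(
        sites=list(h.sites), samples=list(h.samples),
        dosage=dosage, alleles=alleles,
        phased=np.ones((n, h.n_sites), dtype=bool))


def read_population_file(path: str | os.PathLike,
                         known_samples: list[str] | None = None,
                         ) -> PopulationAssignment:
    """Read a two-column whitespace-delimited ``sample population`` file.

    If ``known_samples`` is given, any sample in the file that is not in
    that list raises an error (catching sample-name mismatches early).
    """
    mapping: dict[str, str] = {}
    with open(os.fspath(path)) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{ln}: expected 'sample population', got {line!r}")
            sample, pop = parts
            if sample in mapping:
                raise ValueError(f"{path}:{ln}: duplicate sample {sample!r}")
            mapping[sample] = pop
    if known_samples is not None:
        unknown = sorted(set(mapping) - set(known_samples))
        if unknown:
            raise ValueError(f"population file names unknown samples: {unknown}")
    return PopulationAssignment(mapping)


def read_gene_annotation(path: str | os.PathLike,
                         format: str | None = None,
                         rename: dict[str, str] | None = None,
                         ) -> list[GeneAnnotation]:
    """Read gene intervals from BED4+ or GFF3 into 0-based half-open form.

    ``format`` is ``"bed"`` or ``"gff3"``; inferred from the extension if
    omitted.  For GFF3 only ``gene`` features are kept and the name is
    taken from the ``Name=``/``ID=``/``gene_id=`` attribute.  Overlapping
    records are allowed.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".bed": "bed", ".gff": "gff3", ".gff3": "gff3"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format == "bed":
                if len(f) < 4:
                    raise ValueError(f"{path}:{ln}: BED4+ requires >=4 columns")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if len(f) > 5 else "."
            elif format == "gff3":
                if len(f) < 9:
                    raise ValueError(f"{path}:{ln}: GFF3 requires 9 columns")
                if f[2] != "gene":
                    continue
                chrom = f[0]
                start, end = int(f[3]) - 1, int(f[4])  # 1-based incl -> half-open
                strand = f[6]
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name") or attrs.get("ID") \
                    or attrs.get("gene_id") or f"gene_{ln}"
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            if rename:
                chrom = rename.get(chrom, chrom)
            genes.append(GeneAnnotation(name, chrom, start, end, strand))
    return genes


# ---------------------------------------------------------------------------
# Window table / sweep BED
# ---------------------------------------------------------------------------

def write_window_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a window-statistic table as TSV (``NA`` for masked values)."""
    table.to_csv(os.fspath(path), sep="\t", index=False, na_rep="NA",
                 float_format="%.6g")


def read_window_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path), sep="\t", na_values=["NA"])


def write_sweep_bed(sweeps, path: str | os.PathLike) -> None:
    """Write merged sweep regions as BED (0-based half-open) with stats.

    Columns: chrom, start, end, name, peak weighted FST, peak max |XP-EHH|,
    number of member windows, comma-joined gene names.
    """
    with open(os.fspath(path), "w") as fh:
        for k, sw in enumerate(sweeps):
            genes = ",".join(sw.genes) if sw.genes else "."
            fst = "NA" if sw.peak_fst is None or np.isnan(sw.peak_fst) \
                else f"{sw.peak_fst:.6g}"
            xp = "NA" if sw.peak_xpehh is None or np.isnan(sw.peak_xpehh) \
                else f"{sw.peak_xpehh:.6g}"
            fh.write(f"{sw.chrom}\t{sw.start}\t{sw.end}\tsweep_{k + 1}\t"
                     f"{fst}\t{xp}\t{len(sw.windows)}\t{genes}\n")
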