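"""Population structure: F_ST distances, NJ tree, PCA, LD decay.

Breed-level differentiation uses the Hudson ratio-of-averages F_ST on
pooled breed samples; negative pairwise estimates are clamped to zero
(with a logged count) so the matrix is a valid distance input for
neighbor joining.  PCA operates on individuals with the standard
population-genetics normalization (subtract 2p, divide by
sqrt(2p(1-p))); LD decay is the binned mean r^2 against physical
distance, computed within each population.

The tree algorithm is classical neighbor joining (Saitou-Nei
agglomeration with the Studier-Keppler Q-criterion) with deterministic
lexicographic tie-breaking; negative branch lengths are clamped to zero
and the deficit moved to the sibling edge, so path lengths through the
join are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (MISSING, GenotypeMatrix, HaplotypeMatrix,
                          PopulationAssignment)
from .site_statistics import hudson_fst_arrays, ld_r2_from_haplotypes

__all__ = ["DistanceMatrix", "PcaResult", "LdDecayCurve",
           "pairwise_fst_matrix", "nj_tree", "pca", "ld_decay"]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return df.to_csv(sep="\t", float_format="%.6g")


@dataclass
class PcaResult:
    """Sample coordinates on the top components of the genotype PCA."""

    samples: list[str]
    coords: np.ndarray  # (n_samples, k): eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray  # non-increasing
    variance_fraction: np.ndarray


@dataclass
class LdDecayCurve:
    """Binned mean r^2 against pairwise physical distance."""

    population: str
    bin_mid: np.ndarray  # bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    @property
    def half_decay_distance(self) -> float:
        """Smallest bin midpoint where mean r^2 <= half the binned max."""
        ok = self.n_pairs > 0
        if not ok.any():
            return float("nan")
        half = np.nanmax(self.mean_r2[ok]) / 2.0
        for mid, r2, n in zip(self.bin_mid, self.mean_r2, self.n_pairs):
            if n > 0 and r2 <= half:
                return float(mid)
        return float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"population": self.population,
                             "bin_mid": self.bin_mid,
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.n_pairs})


# ---------------------------------------------------------------------------
# F_ST distance matrix
# ---------------------------------------------------------------------------

def pairwise_fst_matrix(g: GenotypeMatrix,
                        assignment: PopulationAssignment) -> DistanceMatrix:
    """Hudson ratio-of-averages F_ST between every population pair.

    Sites with fewer than 2 called alleles in either population are
    skipped for that pair.  Negative estimates are clamped to 0 (count
    logged).  Each population needs >= 2 samples.
    """
    pops = assignment.populations
    idx_of = {s: i for i, s in enumerate(g.samples)}
    pop_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop in pops:
        names = assignment.samples_of(pop)
        if len(names) < 2:
            raise ValueError(f"population {pop!r} has < 2 samples")
        rows = np.array([idx_of[s] for s in names], dtype=np.int64)
        d = g.dosage[rows, :]
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0).astype(np.float64)
        alt = np.where(called, d, 0).sum(axis=0).astype(np.float64)
        pop_counts[pop] = (n_alleles, alt)

    k = len(pops)
    mat = np.zeros((k, k))
    n_clamped = 0
    for i in range(k):
        for j in range(i + 1, k):
            n1, x1 = pop_counts[pops[i]]
            n2, x2 = pop_counts[pops[j]]
            num, den = hudson_fst_arrays(n1, x1, n2, x2)
            ok = np.isfinite(num) & np.isfinite(den)
            dsum = den[ok].sum()
            fst = num[ok].sum() / dsum if dsum > 0 else 0.0
            if fst < 0:
                n_clamped += 1
                fst = 0.0
            mat[i, j] = mat[j, i] = fst
    if n_clamped:
        logger.info("clamped %d negative pairwise FST value(s) to 0",
                    n_clamped)
    return DistanceMatrix(labels=list(pops), values=mat)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of the NJ tree; leaves carry labels, edges carry lengths."""

    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label: str | None = None,
                 children: list[tuple["TreeNode", float]] | None = None):
        self.label = label
        self.children = children or []
        self.min_leaf = label if label is not None else min(
            c.min_leaf for c, _ in self.children)

    def newick(self, digits: int = 6) -> str:
        return self._nwk(digits) + ";"

    def _nwk(self, digits: int) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk(digits)}:{ln:.{digits}g}"
                         for c, ln in self.children)
        return f"({inner})"

    def leaf_path_lengths(self) -> pd.DataFrame:
        """Pairwise leaf-to-leaf path lengths through the tree."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if not node.children:
                return [(node.label, 0.0)]
            below: list[list[tuple[str, float]]] = []
            for child, ln in node.children:
                below.append([(lab, d + ln) for lab, d in walk(child)])
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i]:
                        for lb, db in below[j]:
                            dists.setdefault(la, {})[lb] = da + db
                            dists.setdefault(lb, {})[la] = da + db
            return [x for grp in below for x in grp]

        leaves = sorted(lab for lab, _ in walk(self))
        out = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for a in leaves:
            for b in leaves:
                if a != b:
                    out.loc[a, b] = dists[a][b]
        return out


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou & Nei) on a distance matrix.

    Agglomerates by the Q-criterion Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties broken by the lexicographically smallest (min leaf, max leaf)
    label pair of the candidate join, so the output is deterministic.
    Terminates on three nodes with the three-point formulas, yielding an
    unrooted tree (trifurcating root).  Negative branch lengths are
    clamped to 0 with the deficit moved to the sibling branch.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]
    D = d.values.astype(np.float64).copy()

    def clamp_pair(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((nodes[i].min_leaf,
                                         nodes[j].min_leaf)))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newD[a, b] = D[ka, kb]
        for a, ka in enumerate(keep):
            dv = (D[i, ka] + D[j, ka] - D[i, j]) / 2.0
            newD[a, m - 2] = newD[m - 2, a] = dv
        nodes = [nodes[k] for k in keep] + [parent]
        D = newD

    # three-point formulas for the final trifurcation
    (a, b, c) = nodes
    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    children = sorted([(a, la), (b, lb), (c, lc)],
                      key=lambda t: t[0].min_leaf)
    return TreeNode(children=children)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(g: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Genotype PCA with per-site 2p-centering and sqrt(2p(1-p)) scaling.

    Missing dosages are mean-imputed (0 after centering); monomorphic
    sites are dropped.  The sample x sample covariance matrix is
    eigendecomposed; coordinates are eigenvectors scaled by the square
    root of their eigenvalues, with signs fixed so each component's
    largest-magnitude entry is positive.
    """
    if k > g.n_samples:
        raise ValueError(f"k={k} exceeds n_samples={g.n_samples}")
    d = g.dosage.astype(np.float64)
    miss = g.dosage == MISSING
    d[miss] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    d = d[:, poly]
    p = p[poly]
    X = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    X[np.isnan(X)] = 0.0  # mean imputation after centering
    m = X.shape[1]
    if m == 0:
        raise ValueError("no polymorphic sites for PCA")
    cov = X @ X.T / m
    w, U = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    U = U[:, order]
    for j in range(U.shape[1]):
        top = np.argmax(np.abs(U[:, j]))
        if U[top, j] < 0:
            U[:, j] = -U[:, j]
    coords = U[:, :k] * np.sqrt(w[:k])
    total = w.sum()
    frac = w[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(samples=list(g.samples), coords=coords,
                     eigenvalues=w[:k], variance_fraction=frac)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(h: HaplotypeMatrix, assignment: PopulationAssignment,
             max_dist: int = 500_000, bin_width: int = 1_000,
             ) -> dict[str, LdDecayCurve]:
    """Binned LD decay curve per population.

    All intra-chromosomal site pairs separated by at most ``max_dist``
    bp are scored with r^2 within each population's haplotypes and
    averaged in ``bin_width`` distance bins.  Pairs where either site is
    monomorphic in the population are skipped.  Each population needs
    >= 4 haplotypes (2 samples).
    """
    n_bins = -(-max_dist // bin_width)
    mids = (np.arange(n_bins) + 0.5) * bin_width
    pos = h.positions
    chroms = h.chroms
    out: dict[str, LdDecayCurve] = {}
    for pop in assignment.populations:
        names = assignment.samples_of(pop)
        rows = h.sample_haplotype_rows(names)
        if rows.size < 4:
            raise ValueError(f"population {pop!r} has < 4 haplotypes")
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=np.int64)
        for chrom in pd.unique(chroms):
            on = np.flatnonzero(chroms == chrom)
            hap = h.haplotypes[np.ix_(rows, on)]
            cpos = pos[on]
            r2 = ld_r2_from_haplotypes(hap)
            iu, ju = np.triu_indices(len(on), k=1)
            dist = cpos[ju] - cpos[iu]
            vals = r2[iu, ju]
            ok = (dist <= max_dist) & np.isfinite(vals)
            b = np.minimum((dist[ok] - 1) // bin_width, n_bins - 1)
            np.add.at(sums, b, vals[ok])
            np.add.at(counts, b, 1)
        with np.errstate(invalid="ignore"):
            mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1),
                               np.nan)
        out[pop] = LdDecayCurve(population=pop, bin_mid=mids,
                                mean_r2=mean_r2, n_pairs=counts)
    return out
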