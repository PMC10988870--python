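"""Synthetic two-population data with the structure the scan assumes.

Two generator modes:

``balding_nichols``
    The Balding-Nichols beta-binomial divergence model — per site an
    ancestral frequency p ~ Uniform(0.05, 0.95) and population-specific
    frequencies p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F), genotypes
    Binomial(2, p_i).  Sites are unlinked, so this mode is the
    calibration oracle for F_ST estimators (E[F_ST] ~ F), not for
    haplotype statistics.

``forward_wf``
    A discrete-generation Wright-Fisher forward simulation of a single
    ancestral population that splits into two.  Mutation adds Poisson
    new biallelic sites at uniform positions, each transmitted haplotype
    recombines with Poisson(r * L) crossovers, and diploid parents are
    resampled multinomially (fitness-weighted in the selection mode).
    Haplotype structure and LD are therefore real, which is what the
    EHH/XP-EHH statistics need.  An optional hard sweep introduces a
    single copy of a focal allele in one population at a stated time
    with fitnesses 1 : 1+hs : 1+s, and the run is conditioned on that
    allele surviving to sampling (restart from the introduction state on
    loss; restart count logged in the truth record).

    Burn-in shortcut: instead of running >= 8N neutral generations from
    a monomorphic start, the ancestral population is seeded from the
    neutral stationary frequency spectrum (site count Poisson(theta *
    a_{2N-1}), derived counts P(k) proportional to 1/k, carriers
    assigned independently per site) and then evolved for ``burnin``
    further generations (default 4N) so haplotype structure — absent
    from the unlinked seed — equilibrates on the coalescent time scale.

Everything is driven by a single integer seed; identical configurations
produce identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from .genotype_io import (GenotypeMatrix, HaplotypeMatrix,
                          PopulationAssignment, VariantSite, from_haplotypes)

__all__ = ["SelectionConfig", "SimulationConfig", "SimulationTruth",
           "simulate_balding_nichols", "simulate_forward_two_pop",
           "make_fixture", "export_dataset", "sweep_scenario",
           "neutral_scan_scenario", "exchangeable_scenario"]


@dataclass(frozen=True)
class SelectionConfig:
    """Hard-sweep parameters for the forward mode.

    ``s`` is the selection coefficient (fitnesses 1, 1+hs, 1+s), ``h``
    the dominance coefficient, ``locus`` the focal position in bp (None:
    mid-chromosome), ``introduction`` the number of generations before
    sampling at which the single focal copy appears (None: at the
    split), and ``target`` the population under selection.
    """

    s: float
    h: float = 0.5
    locus: int | None = None
    introduction: int | None = None
    target: str = "pop1"

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator configuration; the seed is mandatory.

    Defaults are desk-scale study conditions: N = 200 diploids per
    population, a 2-Mb chromosome with mu*L = 1.0 new mutations per
    haplotype per generation, a split N/4 generations before sampling
    (drift F_ST ~ 1 - exp(-t/2N) ~ 0.1, inside the 0.05-0.2 band two
    diverged domestic populations show), and 50 diploids sampled per
    population.  The recombination rate follows the usual forward-
    simulation rescaling: a desk-scale N of a few hundred stands in for
    an effective size in the thousands, so the per-bp rate is scaled up
    (default 1e-6, i.e. 1 cM/Mb at lambda = 100 rescaling of an
    effective size ~10,000) to
    keep the population-scaled recombination 4*N*r realistic.  Without
    rescaling EHH would never decay below the selscan cutoff within a
    desk-scale chromosome (every XP-EHH score edge-truncated), and a
    sweep's haplotype footprint would cover a large fraction of the
    simulated genome, invalidating genome-wide standardization.
    """

    mode: str  # "balding_nichols" | "forward_wf"
    seed: int
    n_diploids: int = 200  # per population (and ancestral size)
    # balding_nichols
    n_sites: int = 2_000
    F: float = 0.1
    site_spacing: int = 1_000  # bp between unlinked sites
    # forward_wf
    chrom_length: int = 2_000_000
    mu_per_hap: float = 1.0  # mu * L, new mutations per haplotype per gen
    recomb_rate: float = 1e-6  # per bp per generation (rescaled, see doc)
    burnin: int | None = None  # default 4N generations after SFS seeding
    split_time: int | None = None  # generations before sampling; default N/4
    sample_size: int | None = None  # diploids per population; default 50
    selection: SelectionConfig | None = None
    max_restarts: int = 500
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.mode not in ("balding_nichols", "forward_wf"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.mode == "balding_nichols" and not 0.0 < self.F < 1.0:
            raise ValueError("F must be in (0, 1)")
        if self.mu_per_hap < 0 or self.recomb_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth emitted with every dataset."""

    mode: str
    seed: int
    params: dict
    populations: dict[str, list[str]]  # pop label -> sample ids
    ancestral_freqs: list[float] | None = None  # balding_nichols
    sweep_locus: int | None = None  # 1-based bp
    sweep_s: float | None = None
    sweep_final_freq: float | None = None  # in the target sample
    sweep_fixed: bool | None = None
    restarts: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        if d["ancestral_freqs"] is not None:
            d["ancestral_freqs"] = [round(x, 6)
                                    for x in d["ancestral_freqs"]]
        return json.dumps(d, indent=1)


def _sample_names(n: int, pop: str) -> list[str]:
    return [f"{pop}_{i:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Balding-Nichols mode
# ---------------------------------------------------------------------------

def simulate_balding_nichols(cfg: SimulationConfig,
                             ) -> tuple[GenotypeMatrix, PopulationAssignment,
                                        SimulationTruth]:
    """Unlinked two-population genotypes with E[F_ST] ~ F."""
    if cfg.mode != "balding_nichols":
        raise ValueError("config mode must be 'balding_nichols'")
    rng = np.random.default_rng(cfg.seed)
    n, m, F = cfg.n_diploids, cfg.n_sites, cfg.F
    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p1 = rng.beta(a, b)
    p2 = rng.beta(a, b)
    g1 = rng.binomial(2, p1, size=(n, m))
    g2 = rng.binomial(2, p2, size=(n, m))
    dosage = np.vstack([g1, g2]).astype(np.int16)
    # arbitrary phase (heterozygotes as 0|1): fine for dosage statistics
    alleles = np.empty((2 * n, m, 2), dtype=np.int8)
    alleles[:, :, 0] = (dosage == 2)
    alleles[:, :, 1] = (dosage >= 1)
    samples = _sample_names(n, "pop1") + _sample_names(n, "pop2")
    sites = [VariantSite(cfg.chrom, (j + 1) * cfg.site_spacing, None,
                         "A", ("T",)) for j in range(m)]
    g = GenotypeMatrix(sites=sites, samples=samples, dosage=dosage,
                       alleles=alleles,
                       phased=np.ones((2 * n, m), dtype=bool))
    pops = {"pop1": samples[:n], "pop2": samples[n:]}
    assign = PopulationAssignment(
        {s: p for p, ss in pops.items() for s in ss})
    truth = SimulationTruth(
        mode=cfg.mode, seed=cfg.seed,
        params={"n_diploids": n, "n_sites": m, "F": F},
        populations=pops, ancestral_freqs=list(p_anc))
    return g, assign, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher mode
# ---------------------------------------------------------------------------

def _seed_from_sfs(rng: np.random.Generator, n_hap: int, theta: float,
                   L: float) -> tuple[np.ndarray, np.ndarray]:
    """Seed haplotypes from the neutral stationary frequency spectrum."""
    classes = np.arange(1, n_hap)
    weights = 1.0 / classes
    n_sites = rng.poisson(theta * weights.sum())
    ks = rng.choice(classes, size=n_sites, p=weights / weights.sum())
    pos = rng.uniform(0, L, size=n_sites)
    H = np.zeros((n_hap, n_sites), dtype=np.uint8)
    for j, k in enumerate(ks):
        carriers = rng.choice(n_hap, size=k, replace=False)
        H[carriers, j] = 1
    return H, pos


def _reproduce(H: np.ndarray, pos: np.ndarray, rng: np.random.Generator,
               rL: float, L: float,
               weights: np.ndarray | None = None) -> np.ndarray:
    """One generation of reproduction for one population block."""
    n_hap = H.shape[0]
    N = n_hap // 2
    parents = rng.choice(N, size=2 * N, p=weights)  # one parent per gamete
    start = rng.integers(0, 2, size=2 * N)
    ncross = rng.poisson(rL, size=2 * N)
    new = H[2 * parents + start].copy()
    for g in np.flatnonzero(ncross):
        xs = np.sort(rng.uniform(0, L, size=ncross[g]))
        parity = np.searchsorted(xs, pos) % 2
        src0 = H[2 * parents[g] + start[g]]
        src1 = H[2 * parents[g] + 1 - start[g]]
        new[g] = np.where(parity == 0, src0, src1)
    return new


def _fitness(H: np.ndarray, col: int, s: float, h: float) -> np.ndarray:
    gt = H[0::2, col].astype(np.int64) + H[1::2, col]
    w = 1.0 + h * s * (gt == 1) + s * (gt == 2)
    return w / w.sum()


def simulate_forward_two_pop(cfg: SimulationConfig,
                             ) -> tuple[HaplotypeMatrix,
                                        PopulationAssignment,
                                        SimulationTruth]:
    """Forward Wright-Fisher two-population simulation with real LD."""
    if cfg.mode != "forward_wf":
        raise ValueError("config mode must be 'forward_wf'")
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_diploids
    L = float(cfg.chrom_length)
    rL = cfg.recomb_rate * L
    burnin = cfg.burnin if cfg.burnin is not None else 4 * N
    split_time = cfg.split_time if cfg.split_time is not None else N // 4
    n_sample = cfg.sample_size if cfg.sample_size is not None else min(50, N)
    sel = cfg.selection
    t_intro = None
    locus_pos = None
    if sel is not None and sel.s > 0:
        t_intro = sel.introduction if sel.introduction is not None \
            else split_time
        if t_intro > split_time:
            raise ValueError("selection must start at or after the split")
        locus_pos = float(sel.locus if sel.locus is not None else L // 2)

    theta = 4.0 * N * cfg.mu_per_hap

    def mutate(H: np.ndarray, pos: np.ndarray):
        n_hap = H.shape[0]
        n_new = rng.poisson(cfg.mu_per_hap * n_hap)
        if n_new == 0:
            return H, pos
        newpos = rng.uniform(0, L, size=n_new)
        carriers = rng.integers(0, n_hap, size=n_new)
        block = np.zeros((n_hap, n_new), dtype=np.uint8)
        block[carriers, np.arange(n_new)] = 1
        return np.concatenate([H, block], axis=1), \
            np.concatenate([pos, newpos])

    def prune(H: np.ndarray, pos: np.ndarray, protect: float | None):
        counts = H.sum(axis=0)
        keep = (counts > 0) & (counts < H.shape[0])
        if protect is not None:
            keep |= pos == protect
        return H[:, keep], pos[keep]

    # --- ancestral phase -------------------------------------------------
    H, pos = _seed_from_sfs(rng, 2 * N, theta, L)
    for _ in range(burnin):
        H = _reproduce(H, pos, rng, rL, L)
        H, pos = mutate(H, pos)
        H, pos = prune(H, pos, None)

    # --- split: both daughter populations reproduce from the ancestor ---
    H1 = _reproduce(H, pos, rng, rL, L)
    H2 = _reproduce(H, pos, rng, rL, L)

    restarts = 0
    snapshot = None
    focal_active = False

    def introduce_focal(H1: np.ndarray, H2: np.ndarray) -> None:
        target = H1 if sel.target == "pop1" else H2
        target[rng.integers(0, 2 * N), pos == locus_pos] = 1

    t = split_time
    while t > 0:
        if t_intro is not None and t == t_intro and not focal_active:
            # append an (empty) focal column, snapshot, then add one copy
            if not (pos == locus_pos).any():
                H1 = np.concatenate(
                    [H1, np.zeros((2 * N, 1), np.uint8)], axis=1)
                H2 = np.concatenate(
                    [H2, np.zeros((2 * N, 1), np.uint8)], axis=1)
                pos = np.concatenate([pos, [locus_pos]])
            snapshot = (H1.copy(), H2.copy(), pos.copy(), t)
            introduce_focal(H1, H2)
            focal_active = True
        w1 = w2 = None
        if focal_active:
            col = int(np.flatnonzero(pos == locus_pos)[0])
            if sel.target == "pop1":
                w1 = _fitness(H1, col, sel.s, sel.h)
            else:
                w2 = _fitness(H2, col, sel.s, sel.h)
        H1 = _reproduce(H1, pos, rng, rL, L, w1)
        H2 = _reproduce(H2, pos, rng, rL, L, w2)
        both = np.concatenate([H1, H2], axis=0)
        both, pos = mutate(both, pos)
        both, pos = prune(both, pos, locus_pos if focal_active else None)
        H1, H2 = both[:2 * N], both[2 * N:]
        if focal_active:
            col = int(np.flatnonzero(pos == locus_pos)[0])
            target = H1 if sel.target == "pop1" else H2
            if target[:, col].sum() == 0:  # focal allele lost: restart
                restarts += 1
                if restarts > cfg.max_restarts:
                    raise RuntimeError(
                        f"focal allele lost in {restarts} consecutive runs; "
                        "increase s or max_restarts, or change the seed")
                H1, H2, pos, t = (snapshot[0].copy(), snapshot[1].copy(),
                                  snapshot[2].copy(), snapshot[3])
                introduce_focal(H1, H2)
                continue
        t -= 1

    # --- sampling --------------------------------------------------------
    rows1 = np.arange(2 * n_sample)
    rows2 = np.arange(2 * n_sample)
    sample = np.concatenate([H1[rows1], H2[rows2]], axis=0)
    order = np.argsort(pos, kind="stable")
    sample = sample[:, order]
    pos_sorted = pos[order]
    counts = sample.sum(axis=0)
    poly = (counts > 0) & (counts < sample.shape[0])
    sample = sample[:, poly]
    pos_sorted = pos_sorted[poly]
    # integer 1-based positions, strictly increasing
    ipos = np.floor(pos_sorted).astype(np.int64) + 1
    for j in range(1, ipos.size):
        if ipos[j] <= ipos[j - 1]:
            ipos[j] = ipos[j - 1] + 1

    samples = _sample_names(n_sample, "pop1") + _sample_names(n_sample, "pop2")
    sites = [VariantSite(cfg.chrom, int(p), None, "A", ("T",))
             for p in ipos]
    h = HaplotypeMatrix(sites=sites, samples=samples,
                        haplotypes=sample.astype(np.uint8))
    pops = {"pop1": samples[:n_sample], "pop2": samples[n_sample:]}
    assign = PopulationAssignment(
        {s: p for p, ss in pops.items() for s in ss})

    sweep_freq = sweep_fixed = sweep_locus_out = None
    if sel is not None and sel.s > 0:
        rows = slice(0, 2 * n_sample) if sel.target == "pop1" \
            else slice(2 * n_sample, 4 * n_sample)
        at = np.flatnonzero(pos_sorted == locus_pos)
        if at.size:
            f = float(sample[rows, at[0]].mean())
        else:  # focal monomorphic in the combined sample => fixed in target
            f = 1.0
        sweep_freq = f
        sweep_fixed = f == 1.0
        sweep_locus_out = int(locus_pos) + 1
    truth = SimulationTruth(
        mode=cfg.mode, seed=cfg.seed,
        params={"n_diploids": N, "chrom_length": cfg.chrom_length,
                "mu_per_hap": cfg.mu_per_hap,
                "recomb_rate": cfg.recomb_rate, "burnin": burnin,
                "split_time": split_time, "sample_size": n_sample,
                "s": sel.s if sel else 0.0,
                "h": sel.h if sel else None},
        populations=pops, sweep_locus=sweep_locus_out,
        sweep_s=sel.s if sel else None,
        sweep_final_freq=sweep_freq, sweep_fixed=sweep_fixed,
        restarts=restarts)
    return h, assign, truth


# ---------------------------------------------------------------------------
# Named validation scenarios (the study conditions used by the test
# battery and the acceptance script; all members of one lambda = 100
# rescaling family, see the class docstring above)
# ---------------------------------------------------------------------------

def sweep_scenario(seed: int) -> SimulationConfig:
    """Strong recent hard sweep: the scan's power scenario.

    4-Mb chromosome, N = 100 diploids per population, per-bp rates
    mu = 5e-7 / r = 1e-6, split 25 generations before sampling
    (F_ST ~ 0.12-0.2), 40 diploids sampled per population.  The sweep
    (s = 1.5, h = 0.9 — s_real ~ 0.015 at lambda = 100) starts from one
    copy 20 generations before sampling at position 2,025,000, the
    middle of a 50-kb window, and is conditioned on survival.  The
    near-dominant fitness makes the escape from low copy number fast
    (small variance in final frequency) while the late phase stalls
    just below fixation, so the sampled sweep is strong but the core
    window keeps the polymorphism that the F_ST/Fisher rules score.
    """
    return SimulationConfig(
        mode="forward_wf", seed=seed, n_diploids=100,
        chrom_length=4_000_000, mu_per_hap=2.0, recomb_rate=1e-6,
        burnin=400, split_time=25, sample_size=40,
        selection=SelectionConfig(s=1.5, h=0.9, introduction=20,
                                  locus=2_025_000))


def neutral_scan_scenario(seed: int) -> SimulationConfig:
    """The sweep scenario without selection: the scan's null."""
    return SimulationConfig(
        mode="forward_wf", seed=seed, n_diploids=100,
        chrom_length=4_000_000, mu_per_hap=2.0, recomb_rate=1e-6,
        burnin=400, split_time=25, sample_size=40)


def exchangeable_scenario(seed: int) -> SimulationConfig:
    """Two samples split at random from one panmictic population.

    split_time = 0: the two "populations" are exchangeable draws from
    the ancestral pool, the strict null for XP-EHH symmetry checks.
    """
    return SimulationConfig(
        mode="forward_wf", seed=seed, n_diploids=100,
        chrom_length=2_000_000, mu_per_hap=1.0, recomb_rate=1e-6,
        burnin=400, split_time=0, sample_size=40)


# ---------------------------------------------------------------------------
# Deterministic unit-test fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str):
    """Tiny hand-coded datasets used in worked examples and unit tests.

    Registry: ``ehh4`` (4 haplotypes x 5 sites, 2/2 split at the first
    downstream extension from the middle core), ``ld6`` (6 haplotypes x
    2 sites with D = 1/12, r^2 = 1/9), ``filter6`` (10 samples x 6 sites
    tripping each filter rule exactly once).
    """
    if name == "ehh4":
        hap = np.array([
            [0, 0, 0, 0, 0],
            [0, 1, 0, 0, 1],
            [1, 0, 1, 1, 0],
            [1, 1, 1, 1, 1],
        ], dtype=np.uint8)
        sites = [VariantSite("1", 1000 * (j + 1), None, "A", ("T",))
                 for j in range(5)]
        return HaplotypeMatrix(sites=sites,
                               samples=["s0", "s1"], haplotypes=hap)
    if name == "ld6":
        # haplotypes AB, AB, Ab, aB, ab, ab with A=1, B=1
        hap = np.array([[1, 1], [1, 1], [1, 0], [0, 1], [0, 0], [0, 0]],
                       dtype=np.uint8)
        sites = [VariantSite("1", 100, None, "A", ("T",)),
                 VariantSite("1", 200, None, "C", ("G",))]
        return HaplotypeMatrix(sites=sites, samples=["s0", "s1", "s2"],
                               haplotypes=hap)
    if name == "filter6":
        n = 10
        dosage = np.zeros((n, 6), dtype=np.int16)
        alt: list[tuple[str, ...]] = [("T",)] * 6
        # site 0: multi-allelic -> removed by the biallelic rule
        alt[0] = ("T", "G")
        dosage[:, 0] = 1
        # site 1: 2/10 genotypes missing (rate 0.2 > 0.1) -> removed
        dosage[:, 1] = 1
        dosage[0, 1] = dosage[1, 1] = -1
        # site 2: MAF exactly 0.05 (1 ALT allele of 20) -> removed
        dosage[0, 2] = 1
        # sites 3-5: fully called, common -> retained
        dosage[: n // 2, 3] = 1
        dosage[: n // 2, 4] = 2
        dosage[:, 5] = 1
        sites = [VariantSite("1", 100 * (j + 1), None, "A", alt[j])
                 for j in range(6)]
        alleles = np.empty((n, 6, 2), dtype=np.int8)
        alleles[:, :, 0] = np.where(dosage == 2, 1, 0)
        alleles[:, :, 1] = np.where(dosage >= 1, 1, 0)
        alleles[dosage == -1] = -1
        return GenotypeMatrix(
            sites=sites, samples=_sample_names(n, "s"),
            dosage=dosage, alleles=alleles,
            phased=np.ones((n, 6), dtype=bool))
    raise KeyError(f"unknown fixture {name!r}")


def export_dataset(outdir: str | os.PathLike, cfg: SimulationConfig) -> dict:
    """Simulate and write VCF + population file + truth JSON to a dir.

    Returns the paths written.  The forward mode writes phased GT; the
    Balding-Nichols mode writes genotypes with heterozygotes as 0|1.
    """
    from .genotype_io import write_vcf

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    if cfg.mode == "balding_nichols":
        g, assign, truth = simulate_balding_nichols(cfg)
        contigs = {cfg.chrom: (cfg.n_sites + 1) * cfg.site_spacing}
    else:
        h, assign, truth = simulate_forward_two_pop(cfg)
        g = from_haplotypes(h)
        contigs = {cfg.chrom: cfg.chrom_length}
    paths = {
        "vcf": os.path.join(outdir, "dataset.vcf"),
        "populations": os.path.join(outdir, "populations.txt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(g, paths["vcf"], contigs=contigs)
    with open(paths["populations"], "w") as fh:
        for s, p in assign.assignment.items():
            fh.write(f"{s}\t{p}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
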