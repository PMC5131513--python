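"""Synthetic multi-marker datasets with known truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* **SSRs** — forward Wright–Fisher simulation of microsatellite allele
  sizes (repeat counts, ancestral size 20) along a population tree, with
  symmetric single-step mutations at rate ``mu`` per gene copy per
  generation.  The ancestral population is burned in to mutation–drift
  balance first (default 8 N_e generations), so the divergence of mean
  allele sizes obeys Goldstein's expectation E[(delta mu)^2] = 2 mu T.
* **SNPs** — biallelic loci whose ancestral frequencies drift along the
  same tree (binomial resampling, no recurrent mutation); a locus enters
  the panel only if it is polymorphic in genotypes drawn from a small
  ascertainment sample, which reproduces the characteristic diversity
  deficit of unscreened lineages (ascertainment bias).
* **Haplotypes** — reproductively isolated species pools, each with a
  private set of phased haplotypes; individuals pair two haplotypes from
  their own pool (optionally crossing pools at a migration rate), so the
  haploweb of the sample decomposes into one field for recombination per
  pool when migration is zero.
* **Niche** — per-cluster bivariate Gaussian climate envelopes embedded in
  a higher-dimensional covariate space by a fixed linear mixing, plus a
  pooled background sample.

``milicia_like_scenario`` wires all four into one end-to-end fixture shaped
like the motivating study system: 435 individuals in 6 clusters, 7 SSRs,
67 SNPs ascertained in two clusters of one species, and three species
pools.  All generators are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geno_io import (
    SNP,
    SSR,
    GenotypeDataset,
    Locus,
    MembershipMatrix,
    PhasedHaplotypeSet,
    ValidationError,
    write_genotype_table,
    write_membership_matrix,
    write_phased_fasta,
)
from .niche_overlap import EnvOccurrenceSet

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ScenarioBundle",
    "simulate_ssr_genotypes",
    "simulate_snp_ascertained",
    "simulate_phased_haplotypes",
    "simulate_env_occurrences",
    "synthesize_membership",
    "milicia_like_config",
    "milicia_like_scenario",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    ``splits`` maps population -> (parent population, split time in
    generations before present); exactly one population has parent ``None``
    and carries the ancestral lineage.  ``mu_ssr`` is the stepwise mutation
    rate per gene copy per locus per generation.  ``panel_pops`` are the
    populations screened for SNP discovery; ``pools`` maps species-pool
    names to the populations they contain.
    """

    seed: int
    populations: list[str]
    sample_sizes: dict[str, int]
    splits: dict[str, tuple[Optional[str], float]]
    n_e: int = 500
    burn_in: Optional[int] = None  # defaults to 8 * n_e

    # SSR block
    ssr_loci: int = 7
    mu_ssr: float = 1e-3
    ancestral_repeats: int = 20

    # SNP block
    snp_loci: int = 67
    snp_n_e: Optional[int] = None  # SNP drift N_e; defaults to n_e
    panel_pops: list[str] = field(default_factory=list)
    panel_inds_per_pop: int = 1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    max_ascertainment_batches: int = 50

    # haplotype block
    pools: dict[str, list[str]] = field(default_factory=dict)
    haplotypes_per_pool: int = 4
    seq_length: int = 600
    pool_divergence_subs: int = 12
    migration: float = 0.0

    # niche block
    niche_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    niche_sd: float = 1.0
    n_background: int = 800
    n_env_vars: int = 4
    env_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        roots = [p for p, (parent, _) in self.splits.items() if parent is None]
        if len(roots) != 1:
            raise ValidationError("splits must define exactly one root population")
        for pop in self.populations:
            if pop not in self.splits:
                raise ValidationError(f"population {pop!r} missing from splits")
        for pop, n in self.sample_sizes.items():
            if n > self.n_e:
                raise ValidationError(
                    f"sample size {n} for {pop!r} exceeds N_e={self.n_e} diploids"
                )
        if self.burn_in is None:
            self.burn_in = 8 * self.n_e

    @property
    def root(self) -> str:
        return next(p for p, (parent, _) in self.splits.items() if parent is None)

    def individual_ids(self) -> dict[str, list[str]]:
        """Deterministic individual IDs per population (shared across marker
        simulations so datasets can be merged)."""
        out: dict[str, list[str]] = {}
        counter = 1
        for pop in self.populations:
            out[pop] = [f"M{counter + i:03d}" for i in range(self.sample_sizes[pop])]
            counter += self.sample_sizes[pop]
        return out


@dataclass
class SyntheticTruth:
    """Ground truth accompanying every generated dataset."""

    seed: int
    cluster_labels: dict[str, str] = field(default_factory=dict)
    species_labels: dict[str, str] = field(default_factory=dict)
    split_times: dict[str, float] = field(default_factory=dict)
    niche_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Wright–Fisher machinery
# ---------------------------------------------------------------------------


def _evolve_ssr(state: np.ndarray, gens: int, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an (L, 2N) array of allele sizes for ``gens`` generations."""
    L, two_n = state.shape
    state = state.copy()
    total = L * two_n
    for _ in range(int(gens)):
        idx = rng.integers(0, two_n, size=(L, two_n))
        state = np.take_along_axis(state, idx, axis=1)
        n_mut = rng.binomial(total, mu)
        if n_mut:
            pos = rng.integers(0, total, size=n_mut)
            steps = rng.integers(0, 2, size=n_mut) * 2 - 1
            np.add.at(state.reshape(-1), pos, steps)
    return state


def _evolve_freq(state: np.ndarray, gens: int, two_n: int, rng: np.random.Generator) -> np.ndarray:
    """Drift a vector of allele frequencies for ``gens`` generations."""
    state = state.copy()
    for _ in range(int(gens)):
        state = rng.binomial(two_n, state) / two_n
    return state


def _states_along_tree(cfg: SimulationConfig, init_state, evolve, rng):
    """Run one evolution operator down the population tree.

    ``init_state`` is the (already burned-in) ancestral state at the root;
    the returned dict maps each population to its state at the present.
    """
    times = {p: t for p, (parent, t) in cfg.splits.items()}
    t_root = max(times.values()) if len(cfg.populations) > 1 else 0.0
    current: dict[str, tuple] = {cfg.root: (init_state, t_root)}
    events = sorted(
        ((t, child, parent) for child, (parent, t) in cfg.splits.items() if parent),
        key=lambda e: (-e[0], e[1]),
    )
    for t, child, parent in events:
        state, ct = current[parent]
        state = evolve(state, ct - t, rng)
        current[parent] = (state, t)
        current[child] = (state.copy(), t)
    return {pop: evolve(state, ct, rng) for pop, (state, ct) in current.items()}


def _rng(cfg: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


# ---------------------------------------------------------------------------
# SSR genotypes
# ---------------------------------------------------------------------------


def simulate_ssr_genotypes(cfg: SimulationConfig) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Stepwise-mutation microsatellites along the population tree."""
    rng = _rng(cfg, 1)
    two_n = 2 * cfg.n_e
    ancestral = np.full((cfg.ssr_loci, two_n), cfg.ancestral_repeats, dtype=np.int32)
    ancestral = _evolve_ssr(ancestral, cfg.burn_in, cfg.mu_ssr, rng)

    def evolve(state, gens, r):
        return _evolve_ssr(state, gens, cfg.mu_ssr, r)

    finals = _states_along_tree(cfg, ancestral, evolve, rng)
    ids = cfg.individual_ids()
    individuals: list[str] = []
    calls: list[list] = []
    groups: dict[str, str] = {}
    for pop in cfg.populations:
        n = cfg.sample_sizes[pop]
        state = np.maximum(finals[pop], 1)
        copy_idx = rng.choice(two_n, size=2 * n, replace=False)
        sampled = state[:, copy_idx]  # (L, 2n)
        for i, ind in enumerate(ids[pop]):
            a = sampled[:, 2 * i]
            b = sampled[:, 2 * i + 1]
            calls.append(
                [(int(min(x, y)), int(max(x, y))) for x, y in zip(a, b)]
            )
            individuals.append(ind)
            groups[ind] = pop
    loci = [Locus(f"ssr{l + 1}", SSR, 1) for l in range(cfg.ssr_loci)]
    truth = SyntheticTruth(
        cfg.seed,
        cluster_labels=dict(groups),
        split_times={p: t for p, (par, t) in cfg.splits.items() if par},
    )
    return GenotypeDataset(individuals, loci, calls, groups), truth


# ---------------------------------------------------------------------------
# ascertained SNPs
# ---------------------------------------------------------------------------


def simulate_snp_ascertained(cfg: SimulationConfig) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Biallelic loci retained only if polymorphic in the discovery panel."""
    if not cfg.panel_pops:
        raise ValidationError("simulate_snp_ascertained: panel_pops is empty")
    unknown = set(cfg.panel_pops) - set(cfg.populations)
    if unknown:
        raise ValidationError(f"panel populations not simulated: {sorted(unknown)}")
    rng = _rng(cfg, 2)
    two_n = 2 * (cfg.snp_n_e or cfg.n_e)
    lo, hi = cfg.ancestral_freq_range
    batch = max(4 * cfg.snp_loci, 64)
    retained: list[np.ndarray] = []  # per-pop frequency columns of kept loci
    n_kept = 0
    for _ in range(cfg.max_ascertainment_batches):
        p0 = rng.uniform(lo, hi, size=batch)

        def evolve(state, gens, r):
            return _evolve_freq(state, gens, two_n, r)

        finals = _states_along_tree(cfg, p0, evolve, rng)
        # draw the discovery panel and keep loci segregating within it
        alt_copies = np.zeros(batch, dtype=int)
        total_copies = 0
        for pop in cfg.panel_pops:
            geno = rng.binomial(2, finals[pop][None, :].repeat(cfg.panel_inds_per_pop, 0))
            alt_copies += geno.sum(axis=0)
            total_copies += 2 * cfg.panel_inds_per_pop
        keep = (alt_copies > 0) & (alt_copies < total_copies)
        if keep.any():
            freq_matrix = np.stack([finals[pop][keep] for pop in cfg.populations])
            retained.append(freq_matrix)
            n_kept += int(keep.sum())
        if n_kept >= cfg.snp_loci:
            break
    if n_kept < cfg.snp_loci:
        raise ValidationError(
            f"ascertainment yielded only {n_kept}/{cfg.snp_loci} polymorphic loci "
            f"after {cfg.max_ascertainment_batches} batches"
        )
    freqs = np.concatenate(retained, axis=1)[:, : cfg.snp_loci]  # (n_pops, L)
    ids = cfg.individual_ids()
    individuals: list[str] = []
    calls: list[list] = []
    groups: dict[str, str] = {}
    for pi, pop in enumerate(cfg.populations):
        n = cfg.sample_sizes[pop]
        alt = rng.binomial(2, freqs[pi][None, :].repeat(n, 0))  # (n, L)
        for i, ind in enumerate(ids[pop]):
            calls.append([((1, 1), (1, 2), (2, 2))[c] for c in alt[i]])
            individuals.append(ind)
            groups[ind] = pop
    loci = [Locus(f"snp{l + 1}", SNP, 1) for l in range(cfg.snp_loci)]
    truth = SyntheticTruth(
        cfg.seed,
        cluster_labels=dict(groups),
        split_times={p: t for p, (par, t) in cfg.splits.items() if par},
    )
    return GenotypeDataset(individuals, loci, calls, groups), truth


# ---------------------------------------------------------------------------
# phased haplotypes in species pools
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_phased_haplotypes(
    cfg: SimulationConfig,
    individuals_by_pool: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[PhasedHaplotypeSet, SyntheticTruth]:
    """Private haplotype pools per species; random mating within pools.

    Each pool's haplotypes derive from a pool ancestor that carries
    substitutions in a pool-specific block of the alignment, so haplotypes
    of different pools are always distinct.  Within a pool one haplotype is
    common (frequency 0.55) and the rest share the remainder equally, which
    keeps the pool's haploweb connected through heterozygotes in samples of
    realistic size.  With ``migration > 0`` an individual's second
    haplotype is drawn from another pool at that rate.
    """
    if not cfg.pools:
        raise ValidationError("simulate_phased_haplotypes: no pools configured")
    if individuals_by_pool is None:
        ids = cfg.individual_ids()
        individuals_by_pool = {
            pool: [i for pop in pops for i in ids[pop]]
            for pool, pops in cfg.pools.items()
        }
    for pool, inds in individuals_by_pool.items():
        if len(inds) < 1:
            raise ValidationError(f"pool {pool!r} has no individuals")
    rng = _rng(cfg, 3)
    n_hap = cfg.haplotypes_per_pool
    if n_hap < 1:
        raise ValidationError("haplotypes_per_pool must be >= 1")
    root = rng.choice(len(_BASES), size=cfg.seq_length)
    pool_names = sorted(individuals_by_pool)
    block = cfg.pool_divergence_subs
    if block * len(pool_names) > cfg.seq_length:
        raise ValidationError("sequence too short for the requested pool divergence")
    pool_haps: dict[str, list[str]] = {}
    for k, pool in enumerate(pool_names):
        anc = root.copy()
        lo = k * block
        for pos in range(lo, lo + block):  # pool-private substitutions
            anc[pos] = (anc[pos] + 1 + rng.integers(0, 3)) % 4
        haps = ["".join(_BASES[anc])]
        while len(haps) < n_hap:
            var = anc.copy()
            for pos in rng.choice(np.arange(lo, lo + block), size=2, replace=False):
                var[pos] = (var[pos] + 1 + rng.integers(0, 3)) % 4
            s = "".join(_BASES[var])
            if s not in haps:
                haps.append(s)
        pool_haps[pool] = haps
    freqs = np.full(n_hap, 0.45 / max(n_hap - 1, 1))
    freqs[0] = 0.55 if n_hap > 1 else 1.0
    sequences: dict[str, tuple[str, str]] = {}
    individuals: list[str] = []
    species: dict[str, str] = {}
    for pool in pool_names:
        for ind in individuals_by_pool[pool]:
            h1 = pool_haps[pool][rng.choice(n_hap, p=freqs)]
            if cfg.migration > 0 and len(pool_names) > 1 and rng.random() < cfg.migration:
                other = pool_names[
                    (pool_names.index(pool) + 1 + rng.integers(0, len(pool_names) - 1))
                    % len(pool_names)
                ]
                h2 = pool_haps[other][rng.choice(n_hap, p=freqs)]
            else:
                h2 = pool_haps[pool][rng.choice(n_hap, p=freqs)]
            sequences[ind] = (h1, h2)
            individuals.append(ind)
            species[ind] = pool
    truth = SyntheticTruth(cfg.seed, species_labels=species)
    return PhasedHaplotypeSet(individuals, sequences), truth


# ---------------------------------------------------------------------------
# environmental occurrences
# ---------------------------------------------------------------------------


def simulate_env_occurrences(
    cfg: SimulationConfig,
    ids_by_cluster: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[EnvOccurrenceSet, SyntheticTruth]:
    """Gaussian climate envelopes per cluster plus a background sample.

    The two latent niche axes are embedded into ``n_env_vars`` observed
    covariates by a fixed linear mixing with additive noise; the background
    pools all cluster envelopes and adds a uniform pad over the bounding
    box, emulating the available (not just occupied) environment.
    """
    if not cfg.niche_means:
        raise ValidationError("simulate_env_occurrences: no niche means configured")
    rng = _rng(cfg, 4)
    clusters = sorted(cfg.niche_means)
    if ids_by_cluster is None:
        ids_by_cluster = {
            c: [f"{c}.occ{i + 1}" for i in range(cfg.sample_sizes.get(c, 20))]
            for c in clusters
        }
    cov = np.eye(2) * cfg.niche_sd**2
    for c in clusters:
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValidationError("niche covariance must be positive definite")
    latent: dict[str, np.ndarray] = {}
    for c in clusters:
        n = len(ids_by_cluster[c])
        latent[c] = rng.multivariate_normal(cfg.niche_means[c], cov, size=n)
    pooled = np.vstack(list(latent.values()))
    mins, maxs = pooled.min(axis=0), pooled.max(axis=0)
    pad = 0.2 * (maxs - mins)
    n_unif = cfg.n_background // 4
    n_mix = cfg.n_background - n_unif
    mix_idx = rng.integers(0, len(pooled), size=n_mix)
    uniform = rng.uniform(mins - pad, maxs + pad, size=(n_unif, 2))
    background_latent = np.vstack([pooled[mix_idx], uniform])
    # fixed mixing of the 2 latent axes into k observed covariates
    mix_rng = np.random.default_rng([cfg.seed, 40])
    W = mix_rng.normal(size=(cfg.n_env_vars, 2))
    W /= np.linalg.norm(W, axis=1, keepdims=True)

    def observe(points: np.ndarray, r: np.random.Generator) -> np.ndarray:
        return points @ W.T + r.normal(scale=cfg.env_noise_sd, size=(len(points), cfg.n_env_vars))

    rows = []
    for c in clusters:
        env = observe(latent[c], rng)
        for i, ind in enumerate(ids_by_cluster[c]):
            rows.append(
                {
                    "id": ind,
                    "lon": float(latent[c][i, 0]),
                    "lat": float(latent[c][i, 1]),
                    "cluster": c,
                    **{f"env_{j + 1}": float(env[i, j]) for j in range(cfg.n_env_vars)},
                }
            )
    occurrences = pd.DataFrame(rows)
    background = observe(background_latent, rng)
    truth = SyntheticTruth(cfg.seed, niche_means=dict(cfg.niche_means))
    return EnvOccurrenceSet(occurrences, background), truth


# ---------------------------------------------------------------------------
# membership-matrix synthesis
# ---------------------------------------------------------------------------


def synthesize_membership(
    individuals: Sequence[str],
    true_labels: Mapping[str, str],
    cluster_names: Sequence[str],
    label_noise: float = 0.0,
    softness: float = 0.4,
    undefined: Sequence[str] = (),
    rng: Optional[np.random.Generator] = None,
    run_id: str = "synthetic",
) -> MembershipMatrix:
    """Build a q matrix from true labels with controllable assignment noise.

    With probability ``label_noise`` an individual's apparent cluster is
    switched to a uniformly chosen other cluster before its q row is drawn.
    Rows mix a one-hot vector with a Dirichlet(0.5) draw at weight
    ``softness`` <= 0.5, so the apparent cluster always stays above q = 0.5
    (assignments are governed purely by the label noise).  Individuals in
    ``undefined`` get an exact 0.5/0.5 tie and are therefore never assigned
    under a strict q > 0.5 rule.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= softness <= 0.5:
        raise ValidationError("softness must lie in [0, 0.5]")
    K = len(cluster_names)
    index = {c: k for k, c in enumerate(cluster_names)}
    undefined = set(undefined)
    q = np.zeros((len(individuals), K))
    for i, ind in enumerate(individuals):
        k = index[true_labels[ind]]
        if ind in undefined:
            other = (k + 1 + rng.integers(0, K - 1)) % K
            q[i, k] = q[i, other] = 0.5
            continue
        if label_noise > 0 and rng.random() < label_noise:
            k = (k + 1 + rng.integers(0, K - 1)) % K
        onehot = np.zeros(K)
        onehot[k] = 1.0
        q[i] = (1 - softness) * onehot + softness * rng.dirichlet(np.full(K, 0.5))
    return MembershipMatrix(run_id, list(individuals), q)


# ---------------------------------------------------------------------------
# the end-to-end scenario
# ---------------------------------------------------------------------------


def milicia_like_config(seed: int) -> SimulationConfig:
    """Study-shaped defaults: 435 individuals in 6 clusters, 7 SSRs, 67 SNPs
    ascertained in two clusters of the widespread species, 3 species pools.

    The split times range from a very shallow intraspecific pair (K3/K4 at
    175 generations, the depth implied by the smallest published
    (delta mu)^2 at mu = 1e-3) to deep species splits (K1 and K6); the two
    isolated species sit far from the panel lineage in SNP-drift units, so
    SNP diversity collapses in the unscreened species while the SSRs keep
    diversity everywhere — the published pattern.
    """
    return SimulationConfig(
        seed=seed,
        populations=["K1", "K2", "K3", "K4", "K5", "K6"],
        sample_sizes={"K1": 50, "K2": 34, "K3": 226, "K4": 77, "K5": 34, "K6": 14},
        splits={
            "K3": (None, 0.0),
            "K6": ("K3", 6000.0),
            "K1": ("K3", 4000.0),
            "K5": ("K3", 3000.0),
            "K2": ("K3", 2000.0),
            "K4": ("K3", 175.0),
        },
        n_e=500,
        snp_n_e=1250,
        panel_pops=["K2", "K5"],
        pools={
            "regia_west": ["K1"],
            "regia_central": ["K6"],
            "excelsa": ["K2", "K3", "K4", "K5"],
        },
        niche_means={
            "K1": (4.5, 1.0),
            "K2": (2.5, 0.5),
            "K3": (0.0, 0.0),
            "K4": (0.8, 0.0),
            "K5": (3.0, -2.0),
            "K6": (6.0, 2.0),
        },
    )


@dataclass
class ScenarioBundle:
    """Everything the full pipeline consumes, plus the generating truth."""

    config: SimulationConfig
    genotypes: GenotypeDataset
    q_snp: MembershipMatrix
    q_ssr: MembershipMatrix
    haplotypes: PhasedHaplotypeSet
    occurrences: EnvOccurrenceSet
    truth: SyntheticTruth


def milicia_like_scenario(
    seed: int,
    out_dir: Optional[str | Path] = None,
    label_noise: float = 0.05,
    n_haplotyped_per_cluster: int = 22,
) -> ScenarioBundle:
    """Generate the full synthetic study and optionally write it to disk.

    ``label_noise`` is the per-marker-set probability that an individual's
    apparent cluster in the q matrix differs from its true cluster; with
    independent noise on both marker sets the expected cross-marker
    concordance is (1-e)^2 + e^2/(K-1).
    """
    cfg = milicia_like_config(seed)
    ssr_ds, truth = simulate_ssr_genotypes(cfg)
    snp_ds, _ = simulate_snp_ascertained(cfg)
    genotypes = ssr_ds.merge_loci(snp_ds)

    clusters = cfg.populations
    rng_q = np.random.default_rng([seed, 5])
    q_snp = synthesize_membership(
        genotypes.individuals, truth.cluster_labels, clusters,
        label_noise, rng=rng_q, run_id="snp_clustering",
    )
    q_ssr = synthesize_membership(
        genotypes.individuals, truth.cluster_labels, clusters,
        label_noise, rng=rng_q, run_id="ssr_clustering",
    )

    ids = cfg.individual_ids()
    pool_members = {
        "regia_west": ids["K1"][: 2 * n_haplotyped_per_cluster],
        "regia_central": ids["K6"][:12],
        "excelsa": [
            i
            for pop in ("K2", "K3", "K4", "K5")
            for i in ids[pop][:n_haplotyped_per_cluster]
        ],
    }
    haplotypes, hap_truth = simulate_phased_haplotypes(cfg, pool_members)
    truth.species_labels = hap_truth.species_labels
    occurrences, niche_truth = simulate_env_occurrences(
        cfg, {pop: ids[pop] for pop in clusters}
    )
    truth.niche_means = niche_truth.niche_means

    bundle = ScenarioBundle(cfg, genotypes, q_snp, q_ssr, haplotypes, occurrences, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotype_table(genotypes, out / "genotypes.csv")
        write_membership_matrix(q_snp, out / "q_snp.csv")
        write_membership_matrix(q_ssr, out / "q_ssr.csv")
        write_phased_fasta(haplotypes, out / "haplotypes.fasta")
        occurrences.occurrences.to_csv(out / "occurrences.csv", index=False)
        pd.DataFrame(
            occurrences.background,
            columns=[f"env_{j + 1}" for j in range(occurrences.background.shape[1])],
        ).to_csv(out / "background.csv", index=False)
        truth.to_json(out / "truth.json")
    return bundle
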