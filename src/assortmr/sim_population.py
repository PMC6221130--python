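"""Forward-in-time simulation of mother-father-offspring trios under assortative mating.

The model simulates a closed population of couples carrying unlinked biallelic
SNPs in Hardy-Weinberg equilibrium.  Two disjoint SNP sets drive the exposure
phenotype X and the outcome phenotype Y additively; a shared standard-normal
confounder U and independent Gaussian noise fill the remaining variance so that
founder phenotypes have unit variance.  Spouses are paired either at random or
by rank-sorting on noisy phenotype proxies, which induces single-trait or
cross-trait assortment of tunable strength P (the proxy-phenotype correlation).
Each couple leaves two offspring (one female, one male), keeping the population
size constant, and the per-SNP transmitted / nontransmitted parental alleles
are recorded so that nontransmitted allele scores can be built downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpPanel",
    "Population",
    "AssortmentSpec",
    "ScenarioConfig",
    "TransmissionRecord",
    "SimulationResult",
    "TrioDataset",
    "draw_panel",
    "simulate_founders",
    "structural_effects",
    "compute_phenotypes",
    "make_proxy",
    "assort_pairs",
    "mate",
    "advance_generations",
    "build_trio_dataset",
]

GX = "GX"
GY = "GY"

#: phenotype-definition terms that refer to the scaled genetic scores rather
#: than to an already-computed phenotype
_GENETIC_TERMS = ("genetic_x", "genetic_y")
_NOISE_TERM = "noise"


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpPanel:
    """Unlinked biallelic SNPs with effect-allele frequencies and set labels.

    ``set_label`` partitions the panel into the exposure set (``"GX"``), the
    outcome set (``"GY"``) and possibly auxiliary sets; all SNPs are simulated
    in linkage equilibrium.
    """

    freq: np.ndarray  # (n_snps,) effect-allele frequency, strictly in (0,1)
    set_label: np.ndarray  # (n_snps,) str tags

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        labels = np.asarray(self.set_label)
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "set_label", labels)
        if freq.ndim != 1 or freq.size < 1:
            raise ValueError("panel must contain at least one SNP")
        if labels.shape != freq.shape:
            raise ValueError("set_label must align with freq")
        if np.any(freq <= 0.0) or np.any(freq >= 1.0):
            raise ValueError("allele frequencies must be strictly inside (0, 1)")

    @property
    def n_snps(self) -> int:
        return self.freq.size

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.set_label == label)

    @property
    def gx(self) -> np.ndarray:
        return self.indices(GX)

    @property
    def gy(self) -> np.ndarray:
        return self.indices(GY)


@dataclass
class Population:
    """One generation of individuals with phased genotypes and phenotypes.

    ``hap1``/``hap2`` hold per-SNP 0/1 allele counts for the two haplotypes;
    the genotype is their sum.  ``sex`` is 0 for female, 1 for male.
    ``mother``/``father`` index into the previous generation (-1 for founders).
    """

    hap1: np.ndarray  # (n, n_snps) int8
    hap2: np.ndarray  # (n, n_snps) int8
    sex: np.ndarray  # (n,) int8, 0=female 1=male
    phenotypes: dict[str, np.ndarray] = field(default_factory=dict)
    mother: Optional[np.ndarray] = None
    father: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.hap1.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        return self.hap1 + self.hap2

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == 0)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == 1)


@dataclass(frozen=True)
class AssortmentSpec:
    """How spouses are paired.

    ``pattern``:

    * ``"none"`` — uniform random pairing.
    * ``"single_trait"`` — both partners rank-sorted on the ``trait_a`` proxy.
    * ``"cross_trait"`` — bidirectional two-set sorting: couples are paired at
      random, split into two halves; in one half men are sorted on the
      ``trait_b`` proxy and women on the ``trait_a`` proxy, in the other half
      the traits are swapped, and the two sorted halves are concatenated.
    """

    pattern: str = "none"
    trait_a: str = "X"
    trait_b: str = "Y"

    def __post_init__(self):
        if self.pattern not in ("none", "single_trait", "cross_trait"):
            raise ValueError(f"unknown assortment pattern: {self.pattern!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one data-generating process.

    Heritabilities are founder narrow-sense values: the structural genetic
    effects delta_X, delta_Y are calibrated against the theoretical founder
    score variance (sum of 2p(1-p)) so that var(delta_X * Z_X) = h2_X in the
    founder generation; under assortment the realized heritability drifts
    upward slightly, as expected for phenotypic assortment models.
    """

    n_trios: int = 40_000
    n_snps_x: int = 50
    n_snps_y: int = 50
    maf_low: float = 0.1
    maf_high: float = 0.5
    h2_x: float = 0.5
    h2_y: float = 0.5
    beta_xy: float = 0.0
    confounder_share: float = 0.2
    p_assort: float = 1.0  # proxy-phenotype correlation P, in (0, 1]
    assortment: AssortmentSpec = field(default_factory=AssortmentSpec)
    n_generations: int = 1
    n_instrument_snps: int = 50
    phenotype_defs: tuple = ()  # ((name, ((term, coef), ...)), ...)
    forbid_sibs: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if self.n_snps_x < 1 or self.n_snps_y < 1:
            raise ValueError("SNP counts must be >= 1")
        if not (0 < self.maf_low <= self.maf_high < 1):
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        for h2 in (self.h2_x, self.h2_y):
            if not (0 <= h2 < 1):
                raise ValueError("heritabilities must lie in [0, 1)")
        if not (0 <= self.confounder_share < 1):
            raise ValueError("confounder_share must lie in [0, 1)")
        if self.h2_x + self.confounder_share >= 1 or self.h2_y + self.confounder_share >= 1:
            raise ValueError("variance budget h2 + confounder_share must stay below 1")
        if self.assortment.pattern != "none" and not (0 < self.p_assort <= 1):
            raise ValueError("assortment strength P must lie in (0, 1]; "
                             "use pattern 'none' for no assortment")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (1 <= self.n_instrument_snps <= self.n_snps_x):
            raise ValueError("n_instrument_snps must lie in [1, n_snps_x]")

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class TransmissionRecord:
    """Per-offspring transmitted / nontransmitted parental haplotypes (0/1)."""

    transmitted_m: np.ndarray  # (n_off, n_snps) int8, from mother
    transmitted_f: np.ndarray  # from father
    nontransmitted_m: np.ndarray
    nontransmitted_f: np.ndarray


@dataclass
class SimulationResult:
    """Final mating round: parents, couples, offspring and transmissions."""

    panel: SnpPanel
    parents: Population
    couples: np.ndarray  # (n_couples, 2) indices into parents: [female, male]
    offspring: Population  # 2 per couple, rows 2i (female) and 2i+1 (male)
    transmission: TransmissionRecord
    delta_x: float
    delta_y: float
    instrument_snps: np.ndarray  # indices into the panel, subset of GX


@dataclass
class TrioDataset:
    """One analyzed offspring per couple with parental genotypes and phases.

    ``nt_m``/``nt_f`` are the per-SNP nontransmitted parental haplotypes (0/1).
    ``split_a`` marks the random half used for instrument-weight training; the
    complementary half is the analysis half.
    """

    g_o: np.ndarray  # (n_trios, n_snps) offspring genotype 0/1/2
    g_m: np.ndarray  # mother genotype
    g_f: np.ndarray  # father genotype
    nt_m: np.ndarray  # mother nontransmitted haplotype 0/1
    nt_f: np.ndarray  # father nontransmitted haplotype 0/1
    x: np.ndarray  # offspring exposure
    y: np.ndarray  # offspring outcome
    x_m: np.ndarray  # mother exposure phenotype
    x_f: np.ndarray  # father exposure phenotype
    split_a: np.ndarray  # bool, True = weight-training half
    panel: Optional[SnpPanel] = None
    instrument_snps: Optional[np.ndarray] = None

    def __post_init__(self):
        n = self.g_o.shape[0]
        for name in ("g_m", "g_f", "nt_m", "nt_f"):
            if getattr(self, name).shape != self.g_o.shape:
                raise ValueError(f"{name} must match g_o shape")
        for name in ("x", "y", "x_m", "x_f", "split_a"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per trio")

    @property
    def n_trios(self) -> int:
        return self.g_o.shape[0]

    @property
    def n_snps(self) -> int:
        return self.g_o.shape[1]

    def validate(self) -> None:
        """Check the Mendelian bookkeeping invariants; raise on violation."""
        t_m = self.g_m - self.nt_m
        t_f = self.g_f - self.nt_f
        if np.any((t_m < 0) | (t_m > 1)) or np.any((t_f < 0) | (t_f > 1)):
            raise AssertionError("transmitted haplotype outside {0,1}")
        if np.any(self.g_o != t_m + t_f):
            raise AssertionError("offspring genotype != sum of transmitted haplotypes")
        if np.any((self.g_o < 0) | (self.g_o > 2)):
            raise AssertionError("genotype outside {0,1,2}")
        n_a = int(self.split_a.sum())
        if abs(n_a - (self.n_trios - n_a)) > 1:
            raise AssertionError("half-split sizes differ by more than 1")

    def half(self, which: str) -> np.ndarray:
        if which == "A":
            return np.flatnonzero(self.split_a)
        if which == "B":
            return np.flatnonzero(~self.split_a)
        raise ValueError("half must be 'A' or 'B'")

    def to_frame(self) -> pd.DataFrame:
        """Export in the canonical tab-delimited trio dialect (per-SNP columns)."""
        cols: dict[str, np.ndarray] = {"trio_id": np.arange(self.n_trios)}
        for k in range(self.n_snps):
            cols[f"g{k}_o"] = self.g_o[:, k]
            cols[f"g{k}_m"] = self.g_m[:, k]
            cols[f"g{k}_f"] = self.g_f[:, k]
        for k in range(self.n_snps):
            cols[f"nt{k}_m"] = self.nt_m[:, k]
            cols[f"nt{k}_f"] = self.nt_f[:, k]
        cols["x"] = self.x
        cols["y"] = self.y
        cols["x_m"] = self.x_m
        cols["x_f"] = self.x_f
        cols["split"] = np.where(self.split_a, "A", "B")
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrioDataset":
        n_snps = sum(1 for c in df.columns if c.startswith("g") and c.endswith("_o"))
        if n_snps == 0:
            raise ValueError("no genotype columns (g<k>_o) found")

        def block(fmt: str) -> np.ndarray:
            names = [fmt.format(k) for k in range(n_snps)]
            missing = [c for c in names if c not in df.columns]
            if missing:
                raise ValueError(f"missing columns: {missing[:3]}...")
            return df[names].to_numpy(dtype=np.int8)

        have_nt = "nt0_m" in df.columns
        zeros = np.zeros((len(df), n_snps), dtype=np.int8)
        split = (df["split"].to_numpy() == "A") if "split" in df.columns else None
        if split is None:
            # user data without a pre-assigned split: alternate deterministically
            split = np.arange(len(df)) % 2 == 0
        get = lambda c: df[c].to_numpy(dtype=float) if c in df.columns else np.full(len(df), np.nan)
        return cls(
            g_o=block("g{}_o"),
            g_m=block("g{}_m"),
            g_f=block("g{}_f"),
            nt_m=block("nt{}_m") if have_nt else zeros,
            nt_f=block("nt{}_f") if have_nt else zeros.copy(),
            x=get("x"),
            y=get("y"),
            x_m=get("x_m"),
            x_f=get("x_f"),
            split_a=split,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def draw_panel(n_snps: int, maf_low: float, maf_high: float, seed=None,
               label: str = GX) -> SnpPanel:
    """Draw a SNP panel with frequencies ~ Uniform[maf_low, maf_high]."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (0 < maf_low <= maf_high < 1):
        raise ValueError("need 0 < maf_low <= maf_high < 1")
    rng = _as_rng(seed)
    freq = rng.uniform(maf_low, maf_high, size=n_snps)
    return SnpPanel(freq=freq, set_label=np.full(n_snps, label))


def scenario_panel(cfg: ScenarioConfig, seed=None) -> SnpPanel:
    """The GX + GY panel for a scenario (disjoint sets, no pleiotropy)."""
    rng = _as_rng(seed)
    n = cfg.n_snps_x + cfg.n_snps_y
    freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=n)
    labels = np.array([GX] * cfg.n_snps_x + [GY] * cfg.n_snps_y)
    return SnpPanel(freq=freq, set_label=labels)


def simulate_founders(panel: SnpPanel, n_couples: int, seed=None) -> Population:
    """Founders in Hardy-Weinberg and linkage equilibrium: haplotype alleles
    i.i.d. Bernoulli(freq).  Returns n_couples females then n_couples males."""
    if n_couples < 1:
        raise ValueError("n_couples must be >= 1")
    rng = _as_rng(seed)
    n = 2 * n_couples
    freq = panel.freq
    hap1 = (rng.random((n, panel.n_snps)) < freq).astype(np.int8)
    hap2 = (rng.random((n, panel.n_snps)) < freq).astype(np.int8)
    sex = np.repeat(np.array([0, 1], dtype=np.int8), n_couples)
    return Population(hap1=hap1, hap2=hap2, sex=sex)


def structural_effects(panel: SnpPanel, cfg: ScenarioConfig) -> tuple[float, float]:
    """Per-score structural effects delta_X, delta_Y.

    Calibrated so that in founders var(delta * Z) = h2 where Z is the
    unweighted allele-count sum and the theoretical founder variance of Z is
    sum_k 2 p_k (1 - p_k).
    """
    var_zx = float(np.sum(2 * panel.freq[panel.gx] * (1 - panel.freq[panel.gx])))
    var_zy = float(np.sum(2 * panel.freq[panel.gy] * (1 - panel.freq[panel.gy])))
    delta_x = math.sqrt(cfg.h2_x / var_zx) if cfg.h2_x > 0 else 0.0
    delta_y = math.sqrt(cfg.h2_y / var_zy) if cfg.h2_y > 0 else 0.0
    return delta_x, delta_y


def compute_phenotypes(pop: Population, cfg: ScenarioConfig, panel: SnpPanel,
                       delta_x: float, delta_y: float, seed=None) -> Population:
    """Attach X, Y, U and any auxiliary phenotypes to a population.

    X = delta_X*Z_X + sqrt(c)*U + e_X,          e_X ~ N(0, 1 - h2_X - c)
    Y = beta_XY*X + delta_Y*Z_Y + sqrt(c)*U + e_Y,  e_Y ~ N(0, 1 - h2_Y - c)

    with U ~ N(0,1) shared between X and Y within an individual.  Auxiliary
    phenotypes are evaluated in declared order as linear combinations of
    previously defined phenotypes, the scaled genetic scores (terms
    ``genetic_x`` = delta_X*Z_X and ``genetic_y`` = delta_Y*Z_Y, i.e.
    horizontal pleiotropy shared across all variants of the set), U, and
    fresh unit-variance noise (term ``noise``).
    """
    rng = _as_rng(seed)
    geno = pop.genotypes
    zx = geno[:, panel.gx].sum(axis=1).astype(float)
    zy = geno[:, panel.gy].sum(axis=1).astype(float)
    c = cfg.confounder_share
    u = rng.standard_normal(pop.n)
    gx_term = delta_x * zx
    gy_term = delta_y * zy
    e_x = rng.standard_normal(pop.n) * math.sqrt(max(1 - cfg.h2_x - c, 0.0))
    x = gx_term + math.sqrt(c) * u + e_x
    e_y = rng.standard_normal(pop.n) * math.sqrt(max(1 - cfg.h2_y - c, 0.0))
    y = cfg.beta_xy * x + gy_term + math.sqrt(c) * u + e_y
    phen = {"X": x, "Y": y, "U": u}
    terms = {"genetic_x": gx_term, "genetic_y": gy_term, "U": u}
    for name, combo in cfg.phenotype_defs:
        val = np.zeros(pop.n)
        for term, coef in combo:
            if term == _NOISE_TERM:
                val = val + coef * rng.standard_normal(pop.n)
            elif term in terms:
                val = val + coef * terms[term]
            elif term in phen:
                val = val + coef * phen[term]
            else:
                raise ValueError(f"phenotype_def {name!r} references unknown term {term!r}")
        phen[name] = val
    pop.phenotypes = phen
    return pop


def make_proxy(values: np.ndarray, p: float, seed=None) -> np.ndarray:
    """Noisy proxy with cor(values, proxy) = P in expectation.

    proxy = values + e with e ~ N(0, var(values) * (1 - P^2) / P^2).
    """
    if not (0 < p <= 1):
        raise ValueError("assortment strength P must lie in (0, 1]")
    if p == 1.0:
        return np.asarray(values, dtype=float).copy()
    rng = _as_rng(seed)
    v = float(np.var(values))
    sd = math.sqrt(v * (1 - p * p) / (p * p))
    return values + rng.standard_normal(len(values)) * sd


def assort_pairs(pop: Population, spec: AssortmentSpec, p: float, seed=None,
                 forbid_sibs: bool = False) -> np.ndarray:
    """Pair females with males; returns (n_couples, 2) [female_idx, male_idx].

    Random pattern pairs uniformly.  Sorting patterns first pair at random,
    split the couples into two equal sets, rank-sort each sex within each set
    on its assigned phenotype proxy, and concatenate the sets preserving the
    sorted order (the bidirectional two-set scheme; within a set the rank
    correlation of the sorted proxies is exactly 1).
    """
    rng = _as_rng(seed)
    females = pop.females
    males = pop.males
    if len(females) != len(males):
        raise ValueError("unequal numbers of females and males")
    n = len(females)

    f_perm = rng.permutation(females)
    m_perm = rng.permutation(males)
    if forbid_sibs and pop.mother is not None:
        f_perm, m_perm = _avoid_sib_pairs(pop, f_perm, m_perm, rng)
    if spec.pattern == "none":
        return np.column_stack([f_perm, m_perm])

    def proxy_for(idx: np.ndarray, trait: str, sub) -> np.ndarray:
        if trait not in pop.phenotypes:
            raise ValueError(f"assortment trait {trait!r} not among phenotypes")
        return make_proxy(pop.phenotypes[trait][idx], p, sub)

    half = n // 2
    sets = [(slice(0, half)), (slice(half, n))]
    if spec.pattern == "cross_trait":
        female_traits = (spec.trait_a, spec.trait_b)
        male_traits = (spec.trait_b, spec.trait_a)
    else:  # single_trait: both sexes, both sets on trait_a
        female_traits = (spec.trait_a, spec.trait_a)
        male_traits = (spec.trait_a, spec.trait_a)

    f_out, m_out = [], []
    for sl, ft, mt in zip(sets, female_traits, male_traits):
        f_idx = f_perm[sl]
        m_idx = m_perm[sl]
        fp = proxy_for(f_idx, ft, rng)
        mp = proxy_for(m_idx, mt, rng)
        f_out.append(f_idx[np.argsort(fp, kind="stable")])
        m_out.append(m_idx[np.argsort(mp, kind="stable")])
    return np.column_stack([np.concatenate(f_out), np.concatenate(m_out)])


def _avoid_sib_pairs(pop: Population, f_perm: np.ndarray, m_perm: np.ndarray,
                     rng: np.random.Generator, max_rounds: int = 100):
    """Reshuffle male side among sib-paired couples until no full sibs remain."""
    for _ in range(max_rounds):
        sibs = (pop.mother[f_perm] == pop.mother[m_perm]) & (
            pop.father[f_perm] == pop.father[m_perm])
        k = int(sibs.sum())
        if k == 0:
            return f_perm, m_perm
        if k == 1:
            # swap with one random other couple
            j = rng.integers(len(m_perm))
            i = int(np.flatnonzero(sibs)[0])
            m_perm[[i, j]] = m_perm[[j, i]]
        else:
            idx = np.flatnonzero(sibs)
            m_perm[idx] = m_perm[rng.permutation(idx)]
    raise RuntimeError("could not eliminate sibling pairings")


def mate(couples: np.ndarray, pop: Population, seed=None,
         n_offspring: int = 2) -> tuple[Population, TransmissionRecord]:
    """Mendelian transmission: each parent passes one haplotype allele per SNP
    with probability 1/2; the other allele is recorded as nontransmitted.

    Each couple has ``n_offspring`` children (default 2: one female, one
    male), keeping the population size constant.  Offspring row order is
    couple-major: rows [i*n_offspring, (i+1)*n_offspring) belong to couple i.
    """
    rng = _as_rng(seed)
    fem = couples[:, 0]
    mal = couples[:, 1]
    n_c = len(fem)
    n_snps = pop.hap1.shape[1]

    def meiosis(parent_idx: np.ndarray):
        h1 = pop.hap1[parent_idx]
        h2 = pop.hap2[parent_idx]
        pick = rng.random((len(parent_idx), n_snps)) < 0.5
        trans = np.where(pick, h1, h2).astype(np.int8)
        nontrans = np.where(pick, h2, h1).astype(np.int8)
        return trans, nontrans

    rep_f = np.repeat(fem, n_offspring)
    rep_m = np.repeat(mal, n_offspring)
    t_m, nt_m = meiosis(rep_f)
    t_f, nt_f = meiosis(rep_m)
    n_off = n_c * n_offspring
    # deterministic sex alternation keeps the sex ratio exact and the
    # population closed (one daughter, one son per couple when n_offspring=2)
    sex = np.tile(np.arange(n_offspring, dtype=np.int8) % 2, n_c)
    offspring = Population(hap1=t_m, hap2=t_f, sex=sex, mother=rep_f, father=rep_m)
    record = TransmissionRecord(transmitted_m=t_m, transmitted_f=t_f,
                                nontransmitted_m=nt_m, nontransmitted_f=nt_f)
    return offspring, record


def advance_generations(cfg: ScenarioConfig, seed=None,
                        panel: Optional[SnpPanel] = None) -> SimulationResult:
    """Run the full generational loop and return the final mating round.

    Founders are simulated once; then for each of ``cfg.n_generations``
    rounds: phenotypes are computed (fresh U and noise per individual, the
    structural deltas staying fixed at their founder calibration), spouses
    are paired per the assortment spec, and offspring are produced.  The
    last round's parents, couples, offspring and transmission records define
    the study sample.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        cfg.seed if seed is None else seed)
    streams = seq.spawn(3 + 2 * cfg.n_generations)
    if panel is None:
        panel = scenario_panel(cfg, np.random.default_rng(streams[0]))
    delta_x, delta_y = structural_effects(panel, cfg)
    pop = simulate_founders(panel, cfg.n_trios, np.random.default_rng(streams[1]))
    inst_rng = np.random.default_rng(streams[2])
    instrument = np.sort(inst_rng.choice(panel.gx, size=cfg.n_instrument_snps,
                                         replace=False))

    couples = offspring = record = None
    for g in range(cfg.n_generations):
        rng_p = np.random.default_rng(streams[3 + 2 * g])
        rng_m = np.random.default_rng(streams[4 + 2 * g])
        pop = compute_phenotypes(pop, cfg, panel, delta_x, delta_y, rng_p)
        couples = assort_pairs(pop, cfg.assortment, cfg.p_assort, rng_p,
                               forbid_sibs=cfg.forbid_sibs)
        offspring, record = mate(couples, pop, rng_m)
        if g < cfg.n_generations - 1:
            parents = pop
            pop = offspring
        else:
            parents = pop
    # phenotypes for the analyzed offspring generation
    rng_last = np.random.default_rng(seq.spawn(1)[0])
    offspring = compute_phenotypes(offspring, cfg, panel, delta_x, delta_y, rng_last)
    return SimulationResult(panel=panel, parents=parents, couples=couples,
                            offspring=offspring, transmission=record,
                            delta_x=delta_x, delta_y=delta_y,
                            instrument_snps=instrument)


def build_trio_dataset(sim: SimulationResult, seed=None) -> TrioDataset:
    """Assemble one analyzed trio per final couple with a random A/B half-split.

    Of the two offspring per couple the analyzed one is chosen at random.
    """
    rng = _as_rng(seed)
    n_c = sim.couples.shape[0]
    n_off_per = sim.offspring.n // n_c
    pick = rng.integers(0, n_off_per, size=n_c)
    rows = np.arange(n_c) * n_off_per + pick

    g_m = sim.parents.genotypes[sim.couples[:, 0]]
    g_f = sim.parents.genotypes[sim.couples[:, 1]]
    tr = sim.transmission
    t_m = tr.transmitted_m[rows]
    t_f = tr.transmitted_f[rows]
    g_o = (t_m + t_f).astype(np.int8)

    # random half-split with sizes differing by at most one
    perm = rng.permutation(n_c)
    split_a = np.zeros(n_c, dtype=bool)
    split_a[perm[: n_c // 2]] = True

    ds = TrioDataset(
        g_o=g_o, g_m=g_m.astype(np.int8), g_f=g_f.astype(np.int8),
        nt_m=tr.nontransmitted_m[rows], nt_f=tr.nontransmitted_f[rows],
        x=sim.offspring.phenotypes["X"][rows],
        y=sim.offspring.phenotypes["Y"][rows],
        x_m=sim.parents.phenotypes["X"][sim.couples[:, 0]],
        x_f=sim.parents.phenotypes["X"][sim.couples[:, 1]],
        split_a=split_a, panel=sim.panel, instrument_snps=sim.instrument_snps,
    )
    ds.validate()
    return ds


def simulate_trios(cfg: ScenarioConfig, seed=None) -> TrioDataset:
    """Convenience pipeline: advance_generations then build_trio_dataset."""
    seq = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_sim, s_build = seq.spawn(2)
    sim = advance_generations(cfg, s_sim)
    return build_trio_dataset(sim, np.random.default_rng(s_build))
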