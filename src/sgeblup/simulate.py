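"""Synthetic pen-structured pig data with the statistical structure the model assumes.

The simulator produces, from one seeded configuration:

* a multi-generation pedigree with discrete generations, litters (full-sib
  sets) and random mating;
* unlinked biallelic marker genotypes by gene dropping through that pedigree;
* direct and social breeding values with covariance C (x) A, either by the
  bivariate Mendelian-sampling recursion on the pedigree ("pedigree"
  architecture) or as sums of centered marker dosages times bivariate normal
  marker effects ("marker" architecture, in which realized genomic
  relationships carry information about the breeding values);
* same-sex, same-batch pens assembled from sorted litters, and average daily
  gain phenotypes  y_i = fixed + a_D,i + sum of pen mates' a_S + litter +
  pen + residual.

Ground truth (per-animal a_D, a_S, TBV and the generating components) is kept
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .components import VarianceComponents
from .pedigree import UNKNOWN, PedigreeTable, make_pedigree

__all__ = [
    "FixedEffectLevels",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_social_phenotypes",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FixedEffectLevels:
    """Magnitudes of the simulated fixed effects, in g/d.

    The intercept and dispersion defaults give ADG on the realistic ~790 g/d
    scale; batch effects are drawn N(0, batch_sd^2), sexes differ by
    sex_diff, and age at target weight (days) enters with slope age_slope.
    """

    intercept: float = 790.0
    batch_sd: float = 15.0
    sex_diff: float = 20.0
    age_slope: float = -1.5
    age_mean: float = 155.0
    age_sd: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    n_founders: int = 60
    n_generations: int = 2
    litter_size_range: tuple = (3, 7)
    group_size_range: tuple = (5, 5)
    n_batches: int = 4  # batches per generation (year-month-week analogue)
    n_markers: int = 500
    founder_allele_freq_range: tuple = (0.05, 0.95)
    true_components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(
            sigma2_aD=2320.0, sigma_aDaS=72.0, sigma2_aS=23.0,
            sigma2_g=479.0, sigma2_l=256.0, sigma2_e=3739.0,
        )
    )
    fixed_effect_levels: FixedEffectLevels = field(default_factory=FixedEffectLevels)
    genotyped_fraction: float = 0.3
    seed: int = 0
    matings_per_generation: int | None = None  # default: n_founders // 2
    architecture: str = "pedigree"  # or "marker"

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least 2 founders")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be >= 0")
        lo, hi = self.litter_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad litter_size_range {self.litter_size_range}")
        lo, hi = self.group_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad group_size_range {self.group_size_range}")
        lo, hi = self.founder_allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"founder allele frequencies must lie strictly in (0,1), got {self.founder_allele_freq_range}"
            )
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ConfigurationError("genotyped_fraction must lie in [0, 1]")
        if self.architecture not in ("pedigree", "marker"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        self.true_components.validate()

    def _streams(self):
        ss = np.random.SeedSequence(self.seed)
        keys = ("pedigree", "genotypes", "effects", "phenotypes")
        return dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))


@dataclass
class SimulatedDataset:
    """One simulated population: pedigree + phenotypes + genotypes + truth."""

    pedigree: PedigreeTable
    phenotypes: pd.DataFrame  # animal, adg, batch, sex, pen, litter, age_days, group_size, period
    genotypes: pd.DataFrame  # index: genotyped animal ids; columns: markers
    truth: pd.DataFrame  # animal, a_D, a_S, TBV
    components: VarianceComponents
    founder_freqs: np.ndarray
    config: SimulationConfig

    def write(self, outdir) -> None:
        """Write pedigree/phenotype/genotype/truth files as plain text."""
        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_frame().drop(columns="F").to_csv(
            outdir / "pedigree.csv", index=False
        )
        self.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        sio.write_genotypes_raw(self.genotypes, outdir / "genotypes.raw")
        sio.write_genotypes_tsv(self.genotypes, outdir / "genotypes.tsv")
        self.truth.to_csv(outdir / "truth_breeding_values.csv", index=False)
        pd.Series(vars(self.components)).to_csv(
            outdir / "truth_components.csv", header=["value"]
        )


def _simulate_structure(config: SimulationConfig, rng) -> pd.DataFrame:
    """Pedigree rows with sex/litter/generation metadata, parents before offspring."""
    n_half = config.n_founders // 2
    rows = []  # animal, sire, dam, generation, sex, litter
    next_id = 1
    founders = []
    for i in range(config.n_founders):
        sex = "M" if i < config.n_founders - n_half else "F"
        rows.append((next_id, 0, 0, 0, sex, 0))
        founders.append((next_id, sex))
        next_id += 1
    litter_id = 0
    prev = founders
    n_matings = config.matings_per_generation or (config.n_founders // 2)
    lo, hi = config.litter_size_range
    for gen in range(1, config.n_generations + 1):
        males = [a for a, s in prev if s == "M"]
        females = [a for a, s in prev if s == "F"]
        if not males or not females:
            raise ConfigurationError("a generation ran out of sires or dams")
        k = min(n_matings, len(females))
        dams = rng.choice(females, size=k, replace=False)
        # limited sire pool: each sire serves ~4 dams, giving half-sib family
        # sizes on the realistic nucleus-herd scale (average ~4 litters/sire)
        n_sires = min(len(males), max(1, int(np.ceil(k / 4))))
        sire_pool = rng.choice(males, size=n_sires, replace=False)
        sires = rng.choice(sire_pool, size=k, replace=True)
        cur = []
        for s, d in zip(sires, dams):
            litter_id += 1
            for _ in range(int(rng.integers(lo, hi + 1))):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((next_id, int(s), int(d), gen, sex, litter_id))
                cur.append((next_id, sex))
                next_id += 1
        prev = cur
    return pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "generation", "sex", "litter"]
    )


def simulate_pedigree(config: SimulationConfig) -> PedigreeTable:
    """Generate a topologically ordered pedigree with discrete generations."""
    meta = _simulate_structure(config, config._streams()["pedigree"])
    return make_pedigree(meta.animal, meta.sire, meta.dam, meta.generation)


def _gene_drop(ped: PedigreeTable, freqs: np.ndarray, rng) -> np.ndarray:
    """Drop founder alleles through the pedigree; returns (n, m, 2) haplotypes."""
    n, m = len(ped), len(freqs)
    hap = np.empty((n, m, 2), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for slot, parent in ((0, s), (1, d)):
            if parent == UNKNOWN:
                hap[i, :, slot] = rng.random(m) < freqs
            else:
                choice = rng.integers(0, 2, size=m)
                hap[i, :, slot] = hap[parent, np.arange(m), choice]
    return hap


def simulate_genotypes(ped: PedigreeTable, config: SimulationConfig):
    """Gene-drop dosages for every pedigree animal; returns (dosages, founder freqs)."""
    streams = config._streams()
    rng = streams["genotypes"]
    lo, hi = config.founder_allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_markers)
    hap = _gene_drop(ped, freqs, rng)
    return hap.sum(axis=2).astype(np.int8), freqs


def _pedigree_bvs(ped: PedigreeTable, C: np.ndarray, rng) -> np.ndarray:
    """Bivariate (a_D, a_S) via the Mendelian-sampling recursion: Cov = C (x) A."""
    n = len(ped)
    w = np.ones(n)
    F = ped.F
    both = (ped.sire != UNKNOWN) & (ped.dam != UNKNOWN)
    one = (ped.sire != UNKNOWN) ^ (ped.dam != UNKNOWN)
    w[both] = 0.5 - 0.25 * (F[ped.sire[both]] + F[ped.dam[both]])
    par = np.where(ped.sire != UNKNOWN, ped.sire, ped.dam)
    w[one] = 0.75 - 0.25 * F[par[one]]
    # eigen-based square root tolerates singular C (e.g. sigma2_aS = 0)
    ev, U = np.linalg.eigh(C)
    L = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    z = rng.standard_normal((n, 2))
    a = np.zeros((n, 2))
    ms = z @ L.T * np.sqrt(w)[:, None]
    for i in range(n):
        mean = np.zeros(2)
        if ped.sire[i] != UNKNOWN:
            mean += 0.5 * a[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            mean += 0.5 * a[ped.dam[i]]
        a[i] = mean + ms[i]
    return a


def _marker_bvs(dosages: np.ndarray, freqs: np.ndarray, C: np.ndarray, rng) -> np.ndarray:
    """(a_D, a_S) as sums of centered dosages times bivariate marker effects.

    Effects are scaled so founder-generation variance equals C; realized
    genomic relationships then carry information about the breeding values.
    """
    sum2pq = np.sum(2.0 * freqs * (1.0 - freqs))
    ev, U = np.linalg.eigh(C / sum2pq)
    L = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    alpha = rng.standard_normal((len(freqs), 2)) @ L.T
    Z = dosages.astype(float) - 2.0 * freqs
    return Z @ alpha


def _assemble_pens(meta: pd.DataFrame, config: SimulationConfig, rng) -> pd.DataFrame:
    """Assign non-founders to same-sex, same-batch pens built from sorted litters."""
    lo, hi = config.group_size_range
    offspring = meta[meta.generation > 0].copy()
    # each litter goes whole into one batch of its generation
    litters = offspring[["litter", "generation"]].drop_duplicates()
    batch_of_litter = {
        row.litter: (row.generation - 1) * config.n_batches
        + int(rng.integers(0, config.n_batches))
        for row in litters.itertuples()
    }
    offspring["batch"] = offspring.litter.map(batch_of_litter)
    pen_rows = []
    pen_id = 0
    for (_batch, _sex), cell in offspring.sort_values(["batch", "sex", "litter"]).groupby(
        ["batch", "sex"], sort=True
    ):
        animals = cell.animal.tolist()
        start = 0
        while start < len(animals):
            size = int(rng.integers(lo, hi + 1))
            members = animals[start : start + size]
            start += size
            pen_id += 1
            for a in members:
                pen_rows.append((a, pen_id))
    pens = pd.DataFrame(pen_rows, columns=["animal", "pen"])
    return offspring.merge(pens, on="animal")


def simulate_social_phenotypes(config: SimulationConfig) -> SimulatedDataset:
    """Full simulation: pedigree, genotypes, breeding values, pens, phenotypes."""
    comp = config.true_components
    comp.validate()
    streams = config._streams()
    meta = _simulate_structure(config, streams["pedigree"])
    ped = make_pedigree(meta.animal, meta.sire, meta.dam, meta.generation)

    dosages, freqs = simulate_genotypes(ped, config)

    C = comp.C()
    if config.architecture == "marker":
        a = _marker_bvs(dosages, freqs, C, streams["effects"])
    else:
        a = _pedigree_bvs(ped, C, streams["effects"])
    a_D = dict(zip(ped.ids, a[:, 0]))
    a_S = dict(zip(ped.ids, a[:, 1]))

    recs = _assemble_pens(meta, config, streams["pedigree"])
    rng = streams["phenotypes"]
    fe = config.fixed_effect_levels
    n_batch_total = recs.batch.nunique()
    batch_eff = dict(
        zip(sorted(recs.batch.unique()), rng.normal(0.0, fe.batch_sd, n_batch_total))
    )
    litter_eff = {
        l: rng.normal(0.0, np.sqrt(comp.sigma2_l)) for l in sorted(recs.litter.unique())
    }
    pen_eff = {p: rng.normal(0.0, np.sqrt(comp.sigma2_g)) for p in sorted(recs.pen.unique())}
    recs = recs.sort_values("animal").reset_index(drop=True)
    recs["age_days"] = rng.normal(fe.age_mean, fe.age_sd, len(recs))
    recs["group_size"] = recs.groupby("pen").animal.transform("size")

    mates_sum = np.zeros(len(recs))
    pen_groups = recs.groupby("pen").animal.apply(list).to_dict()
    for idx, row in enumerate(recs.itertuples()):
        mates_sum[idx] = sum(a_S[m] for m in pen_groups[row.pen] if m != row.animal)

    y = (
        fe.intercept
        + recs.batch.map(batch_eff).to_numpy()
        + np.where(recs.sex == "M", 0.5, -0.5) * fe.sex_diff
        + fe.age_slope * (recs.age_days.to_numpy() - fe.age_mean)
        + recs.animal.map(a_D).to_numpy()
        + mates_sum
        + recs.litter.map(litter_eff).to_numpy()
        + recs.pen.map(pen_eff).to_numpy()
        + rng.normal(0.0, np.sqrt(comp.sigma2_e), len(recs))
    )
    phenotypes = pd.DataFrame(
        {
            "animal": recs.animal,
            "adg": y,
            "batch": recs.batch,
            "sex": recs.sex,
            "pen": recs.pen,
            "litter": recs.litter,
            "age_days": recs.age_days,
            "group_size": recs.group_size,
            "period": recs.batch,
        }
    )

    n_geno = int(round(config.genotyped_fraction * len(recs)))
    geno_ids = np.sort(rng.choice(recs.animal.to_numpy(), size=n_geno, replace=False))
    gidx = ped.indices_of(geno_ids)
    genotypes = pd.DataFrame(
        dosages[gidx],
        index=pd.Index(geno_ids, name="animal"),
        columns=[f"m{j + 1}" for j in range(config.n_markers)],
    )

    n_bar = float(phenotypes.group_size.mean()) if len(phenotypes) else 1.0
    truth = pd.DataFrame(
        {
            "animal": ped.ids,
            "a_D": a[:, 0],
            "a_S": a[:, 1],
            "TBV": a[:, 0] + (n_bar - 1.0) * a[:, 1],
        }
    )
    return SimulatedDataset(
        pedigree=ped,
        phenotypes=phenotypes,
        genotypes=genotypes,
        truth=truth,
        components=comp,
        founder_freqs=freqs,
        config=config,
    )
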