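"""Synthetic structured genotype data with full ground truth.

The generator emulates the statistical structure the downstream analyses
assume: several breeding populations with a tunable differentiation level,
hexaploid allele counts collapsed to three diploidized codes, per-locus
missingness, and replicated per-stage samples with injected genotyping
error and mislabeling events.

Population allele frequencies follow the Balding-Nichols model: for an
ancestral frequency ``p`` and target differentiation ``F_ST = F``, each
population's frequency is drawn from
``Beta(p (1 - F) / F, (1 - p)(1 - F) / F)``, whose variance around ``p``
is ``F p (1 - p)``. Individual hexaploid allele counts are binomial (or
beta-binomial when within-population inbreeding is requested) and then
diploidized. The defaults mirror the study design this toolkit targets:
four breeding platforms with 331/126/144/61 parents, 15 chromosomes with
14 loci each, and a three-stage replicate design over 94 clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    LocusInfo,
    SampleInfo,
    HOM_REF,
    HOM_ALT,
    HET,
    MISSING,
)
from .qc import diploidize

__all__ = ["SimConfig", "SimTruth", "simulate_parents", "simulate_replicates",
           "DEFAULT_POPULATIONS"]

#: (population, n_parents) pairs of the emulated breeding program
DEFAULT_POPULATIONS = (
    ("Peru", 331),
    ("Uganda", 126),
    ("Mozambique", 144),
    ("Ghana", 61),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic genotype generator.

    Defaults are the emulated study's design values; see the methods note
    for the rationale of each.
    """

    populations: tuple = DEFAULT_POPULATIONS
    n_chromosomes: int = 15
    loci_per_chromosome: int = 14
    chromosome_length: int = 30_000_000  # bp; positions drawn uniformly
    target_fst: float = 0.07
    ancestral_maf_range: tuple[float, float] = (0.10, 0.50)
    ploidy: int = 6
    inbreeding_f: float | dict = 0.0  # per-population beta-binomial correlation
    missing_rate: float = 0.05
    # replicate-design parameters
    stages: tuple = ("in_vitro", "screenhouse", "field")
    genotype_error_rate: float = 0.01
    mislabel_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("missing_rate", "genotype_error_rate", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError(f"target_fst must be in (0, 1), got {self.target_fst}")
        if self.ploidy <= 0 or self.ploidy % 2:
            raise ValueError(f"ploidy must be a positive even integer, got {self.ploidy}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    def pop_inbreeding(self, pop: str) -> float:
        if isinstance(self.inbreeding_f, dict):
            return float(self.inbreeding_f.get(pop, 0.0))
        return float(self.inbreeding_f)


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated matrix."""

    ancestral_freqs: np.ndarray = field(repr=False, default=None)
    population_freqs: pd.DataFrame | None = field(repr=False, default=None)
    populations: dict[str, str] = field(default_factory=dict)  # sample -> pop
    replicate_map: pd.DataFrame | None = None
    mislabeled_genotypes: list = field(default_factory=list)
    swaps: list = field(default_factory=list)  # (gid_a, gid_b, stage)
    n_error_sites: int = 0
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "populations": self.populations,
            "mislabeled_genotypes": self.mislabeled_genotypes,
            "swaps": self.swaps,
            "n_error_sites": self.n_error_sites,
            "config": self.config,
        }


def _draw_pop_freqs(
    p: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw of one population's frequencies, resampling
    numerically degenerate Beta parameters."""
    scale = (1.0 - fst) / fst
    alpha = np.maximum(p * scale, 1e-9)
    beta = np.maximum((1.0 - p) * scale, 1e-9)
    q = rng.beta(alpha, beta)
    # clip away exact 0/1 so downstream binomials stay polymorphic in expectation
    return np.clip(q, 1e-6, 1.0 - 1e-6)


def _locus_metadata(cfg: SimConfig, rng: np.random.Generator) -> list[LocusInfo]:
    loci: list[LocusInfo] = []
    counter = 0
    for c in range(1, cfg.n_chromosomes + 1):
        positions = np.sort(
            rng.choice(
                np.arange(1, cfg.chromosome_length, dtype=np.int64),
                size=cfg.loci_per_chromosome,
                replace=False,
            )
        )
        for pos in positions:
            counter += 1
            loci.append(
                LocusInfo(
                    allele_id=f"SNP{counter:05d}",
                    chromosome=f"Chr{c:02d}",
                    position=int(pos),
                )
            )
    return loci


def simulate_parents(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate structured breeding-parent genotypes.

    Ancestral frequencies are uniform over ``ancestral_maf_range``;
    population frequencies follow Balding-Nichols at ``target_fst``;
    individual alt-allele counts are ``Binomial(ploidy, p_pop)`` (or
    beta-binomial with correlation ``inbreeding_f`` when positive), then
    diploidized; calls are masked at ``missing_rate``. Fully reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    loci = _locus_metadata(cfg, rng)
    p_anc = rng.uniform(*cfg.ancestral_maf_range, size=L)

    samples: list[SampleInfo] = []
    cols: list[np.ndarray] = []
    pop_freqs: dict[str, np.ndarray] = {}
    pop_of: dict[str, str] = {}
    for pop, n_pop in cfg.populations:
        q = _draw_pop_freqs(p_anc, cfg.target_fst, rng)
        pop_freqs[pop] = q
        f_within = cfg.pop_inbreeding(pop)
        for k in range(n_pop):
            sid = f"{pop}_{k + 1:04d}"
            if f_within > 0:
                scale = (1.0 - f_within) / f_within
                p_ind = rng.beta(
                    np.maximum(q * scale, 1e-9), np.maximum((1 - q) * scale, 1e-9)
                )
            else:
                p_ind = q
            counts = rng.binomial(cfg.ploidy, p_ind)
            col = np.asarray(diploidize(counts, cfg.ploidy), dtype=np.int8)
            if cfg.missing_rate > 0:
                col = col.copy()
                col[rng.random(L) < cfg.missing_rate] = MISSING
            cols.append(col)
            samples.append(SampleInfo(sample_id=sid, population=pop))
            pop_of[sid] = pop

    calls = np.column_stack(cols)
    gm = GenotypeMatrix(loci=loci, samples=samples, calls=calls)
    truth = SimTruth(
        ancestral_freqs=p_anc,
        population_freqs=pd.DataFrame(pop_freqs, index=[l.allele_id for l in loci]),
        populations=pop_of,
        config=asdict(cfg),
    )
    return gm, truth


def _apply_genotype_errors(
    col: np.ndarray,
    p_alt: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Flip calls at ``rate``: HOM -> HET; HET -> a homozygote drawn from
    the locus allele frequency. Missing calls stay missing."""
    out = col.copy()
    hit = (rng.random(col.shape[0]) < rate) & (col != MISSING)
    n = int(hit.sum())
    if n == 0:
        return out, 0
    was_het = hit & (col == HET)
    was_hom = hit & ~was_het
    out[was_hom] = HET
    if was_het.any():
        to_alt = rng.random(int(was_het.sum())) < p_alt[was_het]
        vals = np.where(to_alt, HOM_ALT, HOM_REF).astype(np.int8)
        out[was_het] = vals
    return out, n


def simulate_replicates(
    gm: GenotypeMatrix, cfg: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Replicate each genotype once per stage, with errors and mislabels.

    ``gm`` must hold one sample per genotype (its sample IDs become the
    genotype IDs). Each stage copy is perturbed independently at
    ``cfg.genotype_error_rate`` (homozygote <-> heterozygote moves only,
    heterozygote resolution drawn from the locus allele frequency). A
    fraction ``cfg.mislabel_fraction`` of genotypes (rounded down to an
    even count, paired off) have one randomly chosen stage's copies
    swapped between the pair; every swap is recorded in the truth.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gids = gm.sample_ids
    G = len(gids)
    stages = list(cfg.stages)
    if len(stages) < 2:
        raise ValueError("need at least two stages")

    n_affected = int(round(cfg.mislabel_fraction * G))
    n_pairs = n_affected // 2
    if n_pairs * 2 > G:
        raise ValueError("mislabel_fraction requires more swap pairs than genotypes")

    # empirical alt-allele frequency per locus, for heterozygote resolution
    calls = gm.calls
    n_ref = (calls == HOM_REF).sum(axis=1).astype(float)
    n_alt = (calls == HOM_ALT).sum(axis=1).astype(float)
    n_het = (calls == HET).sum(axis=1).astype(float)
    tot = np.maximum(2 * (n_ref + n_alt + n_het), 1.0)
    p_alt = (2 * n_alt + n_het) / tot

    copies: dict[tuple[str, str], np.ndarray] = {}
    n_errors = 0
    gidx = gm.sample_index()
    for gid in gids:
        base = calls[:, gidx[gid]]
        for stage in stages:
            col, n = _apply_genotype_errors(base, p_alt, cfg.genotype_error_rate, rng)
            copies[(gid, stage)] = col
            n_errors += n

    swaps: list[tuple[str, str, str]] = []
    mislabeled: set[str] = set()
    if n_pairs:
        chosen = rng.choice(G, size=2 * n_pairs, replace=False)
        for k in range(n_pairs):
            ga, gb = gids[chosen[2 * k]], gids[chosen[2 * k + 1]]
            stage = stages[int(rng.integers(len(stages)))]
            copies[(ga, stage)], copies[(gb, stage)] = (
                copies[(gb, stage)],
                copies[(ga, stage)],
            )
            swaps.append((ga, gb, stage))
            mislabeled.update((ga, gb))

    samples = []
    cols = []
    map_rows = []
    for gid in gids:
        for stage in stages:
            sid = f"{gid}.{stage}"
            samples.append(SampleInfo(sample_id=sid, genotype_id=gid, stage=stage))
            cols.append(copies[(gid, stage)])
            map_rows.append((sid, gid, stage))
    out = GenotypeMatrix(
        loci=list(gm.loci), samples=samples, calls=np.column_stack(cols)
    )
    rep_map = pd.DataFrame(map_rows, columns=["sample_id", "genotype_id", "stage"])
    truth = SimTruth(
        replicate_map=rep_map,
        mislabeled_genotypes=sorted(mislabeled),
        swaps=swaps,
        n_error_sites=n_errors,
        config=asdict(cfg),
    )
    return out, truth
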