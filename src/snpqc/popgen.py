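"""Diversity and differentiation statistics on diploidized genotypes.

All estimators treat the collapsed (diploidized) codes as if they were
diploid genotypes — the same working assumption the upstream genotype
calling makes. For an autohexaploid this biases heterozygosity-based
quantities; the bias is documented rather than corrected, because the raw
dosage information needed to correct it is not present in the data.

Implemented here:

* Nei's per-population inbreeding coefficient F_IS = 1 - H_obs / H_exp,
  with the multi-locus value formed as a ratio of unweighted per-locus
  averages over loci polymorphic within the population.
* Weir & Cockerham's (1984) variance-component estimators of F (F_IT-role),
  theta (F_ST-role) and f (F_IS-role), with per-locus components a, b, c
  summed over loci before forming ratios, plus pairwise theta.
* Linkage-disequilibrium r^2 as the squared Pearson correlation of
  genotype dosages (phase-free), optionally per chromosome.
* Mantel permutation tests of distance-matrix correlation (one-sided
  upper, joint row+column relabeling of the second matrix).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix, GenotypeError, HOM_REF, HOM_ALT, HET

__all__ = [
    "NeiFis",
    "FStats",
    "LDResult",
    "MantelResult",
    "nei_fis",
    "wc_fstats",
    "wc_components",
    "pairwise_theta",
    "ld_r2",
    "mantel",
]


def _population_groups(
    gm: GenotypeMatrix, populations: Mapping[str, str] | None
) -> dict[str, list[int]]:
    """Map population -> column indices; falls back to SampleInfo.population."""
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(gm.samples):
        pop = populations.get(s.sample_id) if populations is not None else s.population
        if pop is None:
            continue
        groups.setdefault(pop, []).append(j)
    if not groups:
        raise GenotypeError("no sample has a population assignment")
    return groups


def _pop_counts(gm: GenotypeMatrix, cols: Sequence[int]):
    """Per-locus (n_called, alt-allele freq, het fraction) for one population."""
    sub = gm.calls[:, cols]
    n_ref = (sub == HOM_REF).sum(axis=1).astype(float)
    n_alt = (sub == HOM_ALT).sum(axis=1).astype(float)
    n_het = (sub == HET).sum(axis=1).astype(float)
    n_called = n_ref + n_alt + n_het
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, (2 * n_alt + n_het) / (2 * n_called), np.nan)
        h = np.where(n_called > 0, n_het / n_called, np.nan)
    return n_called, p, h


# ---------------------------------------------------------------------------
# Nei F_IS
# ---------------------------------------------------------------------------


@dataclass
class NeiFis:
    """Per-population Nei inbreeding coefficients and their mean."""

    per_population: dict[str, float]
    average: float
    n_loci_used: dict[str, int] = field(default_factory=dict)

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.per_population.items() if np.isfinite(v)}


def nei_fis(
    gm: GenotypeMatrix, populations: Mapping[str, str] | None = None
) -> NeiFis:
    """Nei's F_IS = 1 - H_obs / H_exp per population.

    For each population, only loci polymorphic *within* it contribute:
    H_obs is the unweighted mean observed heterozygote fraction over those
    loci and H_exp the mean of ``2 p (1 - p)``. A population whose loci
    are all monomorphic (or with < 2 samples) gets NaN and is excluded
    from the average.
    """
    groups = _population_groups(gm, populations)
    per: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for pop, cols in sorted(groups.items()):
        if len(cols) < 2:
            warnings.warn(f"population {pop!r} has fewer than 2 samples; F_IS undefined")
            per[pop] = np.nan
            n_used[pop] = 0
            continue
        n_called, p, h = _pop_counts(gm, cols)
        poly = (n_called > 0) & (p > 0) & (p < 1)
        n_used[pop] = int(poly.sum())
        if not poly.any():
            per[pop] = np.nan
            continue
        h_obs = float(np.mean(h[poly]))
        h_exp = float(np.mean(2 * p[poly] * (1 - p[poly])))
        per[pop] = 1.0 - h_obs / h_exp
    defined = [v for v in per.values() if np.isfinite(v)]
    avg = float(np.mean(defined)) if defined else np.nan
    return NeiFis(per_population=per, average=avg, n_loci_used=n_used)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984)
# ---------------------------------------------------------------------------


@dataclass
class FStats:
    """Variance-component fixation indices.

    F is the correlation of genes within individuals (overall inbreeding,
    F_IT-role), theta the correlation of genes among individuals within
    populations (F_ST-role) and f the correlation of genes within
    individuals within populations (F_IS-role); they satisfy
    ``(1 - F) = (1 - theta)(1 - f)``.
    """

    F: float
    theta: float
    f: float
    n_loci: int = 0
    components: pd.DataFrame | None = field(default=None, repr=False)


def wc_components(
    gm: GenotypeMatrix, populations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-locus Weir-Cockerham variance components a, b, c.

    ``a`` is the among-population component, ``b`` among individuals
    within populations, ``c`` within individuals. Populations with fewer
    than two samples are excluded with a warning. Loci called in fewer
    than two populations get NaN components.
    """
    groups = _population_groups(gm, populations)
    usable = {}
    for pop, cols in sorted(groups.items()):
        if len(cols) < 2:
            warnings.warn(
                f"population {pop!r} has fewer than 2 samples; excluded from F-statistics"
            )
        else:
            usable[pop] = cols
    if len(usable) < 1:
        raise GenotypeError("need at least one population with >= 2 samples")

    counts = [_pop_counts(gm, cols) for cols in usable.values()]
    n_mat = np.stack([c[0] for c in counts])  # (r, L) called sample sizes
    p_mat = np.stack([c[1] for c in counts])
    h_mat = np.stack([c[2] for c in counts])

    present = n_mat > 0
    r_eff = present.sum(axis=0).astype(float)  # populations with data per locus
    valid = r_eff >= 2

    n_mat = np.where(present, n_mat, 0.0)
    p_fill = np.where(present, p_mat, 0.0)
    h_fill = np.where(present, h_mat, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_tot = n_mat.sum(axis=0)
        nbar = n_tot / r_eff
        nc = (n_tot - (n_mat**2).sum(axis=0) / n_tot) / (r_eff - 1)
        pbar = (n_mat * p_fill).sum(axis=0) / n_tot
        s2 = (n_mat * (p_fill - pbar) ** 2).sum(axis=0) / ((r_eff - 1) * nbar)
        hbar = (n_mat * h_fill).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r_eff - 1) / r_eff) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return pd.DataFrame(
        {"a": a, "b": b, "c": c},
        index=pd.Index(gm.locus_ids, name="AlleleID"),
    )


def wc_fstats(
    gm: GenotypeMatrix,
    populations: Mapping[str, str] | None = None,
    keep_components: bool = False,
) -> FStats:
    """Weir-Cockerham F, theta and f with components summed over loci.

    ``theta = sum(a) / sum(a+b+c)``, ``F = 1 - sum(c) / sum(a+b+c)`` and
    ``f = 1 - sum(c) / sum(b+c)``, so the identity
    ``(1-F) = (1-theta)(1-f)`` holds exactly by construction.
    """
    comp = wc_components(gm, populations)
    ok = comp.dropna()
    if ok.empty:
        raise GenotypeError("no locus is informative for F-statistics")
    A, B, C = ok["a"].sum(), ok["b"].sum(), ok["c"].sum()
    total = A + B + C
    theta = A / total
    F = 1.0 - C / total
    # f is inestimable when every within-population component vanishes
    f = 1.0 - C / (B + C) if (B + C) != 0 else np.nan
    return FStats(
        F=float(F),
        theta=float(theta),
        f=float(f),
        n_loci=len(ok),
        components=comp if keep_components else None,
    )


def pairwise_theta(
    gm: GenotypeMatrix, populations: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta between populations (zero diagonal)."""
    groups = _population_groups(gm, populations)
    pops = sorted(p for p, cols in groups.items() if len(cols) >= 2)
    if len(pops) < 2:
        raise GenotypeError("pairwise_theta needs at least two populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    sample_pop = {
        gm.samples[j].sample_id: pop for pop, cols in groups.items() for j in cols
    }
    for pa, pb in itertools.combinations(pops, 2):
        ids = [
            s.sample_id for s in gm.samples if sample_pop.get(s.sample_id) in (pa, pb)
        ]
        sub = gm.subset(sample_ids=ids)
        st = wc_fstats(sub, {k: v for k, v in sample_pop.items() if v in (pa, pb)})
        out.loc[pa, pb] = out.loc[pb, pa] = st.theta
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    """Pairwise r^2 within one chromosome (or genome-wide)."""

    chromosome: str | None
    pairs: pd.DataFrame  # columns locus_a, locus_b, r2
    mean_r2: float
    frac_r2_ge_threshold: float
    threshold: float
    n_excluded: int  # pairs undefined (monomorphic in the shared samples)


def _pairwise_r2(dos: np.ndarray, ids: list[str], threshold: float,
                 chromosome: str | None) -> LDResult:
    L = dos.shape[0]
    rows = []
    n_excluded = 0
    for i in range(L):
        for j in range(i + 1, L):
            both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            x, y = dos[i, both], dos[j, both]
            if both.sum() < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                n_excluded += 1
                continue
            r = np.corrcoef(x, y)[0, 1]
            rows.append((ids[i], ids[j], r * r))
    pairs = pd.DataFrame(rows, columns=["locus_a", "locus_b", "r2"])
    mean_r2 = float(pairs["r2"].mean()) if len(pairs) else np.nan
    frac = float((pairs["r2"] >= threshold).mean()) if len(pairs) else np.nan
    return LDResult(
        chromosome=chromosome,
        pairs=pairs,
        mean_r2=mean_r2,
        frac_r2_ge_threshold=frac,
        threshold=threshold,
        n_excluded=n_excluded,
    )


def ld_r2(
    gm: GenotypeMatrix, by_chromosome: bool = True, threshold: float = 0.1
) -> list[LDResult]:
    """Dosage-correlation r^2 between locus pairs.

    r^2 is the squared Pearson correlation of diploid dosage vectors
    (HOM_REF -> 0, HET -> 1, HOM_ALT -> 2) over samples called at both
    loci. Pairs where either locus is monomorphic in the shared samples
    are excluded and counted. With ``by_chromosome`` the comparison is
    restricted to within-chromosome pairs (chromosomes with fewer than two
    loci yield an empty result).
    """
    dos = gm.dosage_float()
    if not by_chromosome:
        return [_pairwise_r2(dos, gm.locus_ids, threshold, None)]
    results = []
    chroms: dict[str, list[int]] = {}
    for i, l in enumerate(gm.loci):
        if l.chromosome is not None:
            chroms.setdefault(l.chromosome, []).append(i)
    for chrom in sorted(chroms):
        idx = chroms[chrom]
        results.append(
            _pairwise_r2(dos[idx], [gm.locus_ids[i] for i in idx], threshold, chrom)
        )
    return results


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    """Permutation test of distance-matrix correlation."""

    r: float
    p_value: float
    n_perm: int
    seed: int | None


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (upper) Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the strictly-lower
    triangles after aligning ``d2`` to ``d1``'s label order. The null
    distribution relabels ``d2``'s rows and columns jointly;
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if set(d1.labels) != set(d2.labels):
        diff = sorted(set(d1.labels) ^ set(d2.labels))
        raise GenotypeError(f"distance matrices have different labels: {diff}")
    d2 = d2.reorder(d1.labels)
    n = d1.n
    tri = np.tril_indices(n, k=-1)
    x = d1.values[tri]
    y_mat = d2.values

    x_c = x - x.mean()
    x_norm = np.sqrt((x_c**2).sum())

    def corr(mat: np.ndarray) -> float:
        y = mat[tri]
        y_c = y - y.mean()
        denom = x_norm * np.sqrt((y_c**2).sum())
        if denom == 0:
            return np.nan
        return float((x_c * y_c).sum() / denom)

    r_obs = corr(y_mat)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(y_mat[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_perm, seed=seed)
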