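"""Per-locus quality metrics and locus filtering.

Metrics are computed from the diploidized calls themselves, never copied
from platform columns. Allele frequencies treat a heterozygote as one copy
of each allele on a diploid scale — a deliberate simplification for
collapsed hexaploid data (see the methods note). PIC is the gene-diversity
form ``1 - p^2 - q^2`` with maximum 0.5 for a biallelic locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    GenotypeError,
    HOM_REF,
    HOM_ALT,
    HET,
)

__all__ = ["FilterSpec", "FilterReport", "locus_quality", "filter_loci", "diploidize",
           "PARENT_FILTER", "PROGENY_FILTER"]


QUALITY_COLUMNS = [
    "n_called",
    "call_rate",
    "freq_hom_ref",
    "freq_hom_alt",
    "freq_het",
    "maf",
    "pic",
    "avg_pic",
]


def locus_quality(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus quality metrics.

    Returns a DataFrame indexed by AlleleID with columns ``n_called``,
    ``call_rate``, ``freq_hom_ref``, ``freq_hom_alt``, ``freq_het`` (class
    frequencies among called samples), ``maf``, ``pic`` (gene diversity
    ``2p(1-p)``-equivalent, max 0.5) and ``avg_pic`` (mean of the
    per-allele presence diversities).

    The alternative-allele frequency is
    ``p = (2 n_HOM_ALT + n_HET) / (2 n_called)``; ``maf = min(p, 1-p)``.
    Loci with zero called samples get ``call_rate`` 0 and NaN for every
    frequency-based metric (flagged, never raised).
    """
    if gm.n_samples == 0:
        raise GenotypeError("locus_quality requires at least one sample")
    calls = gm.calls
    n = gm.n_samples
    n_ref = (calls == HOM_REF).sum(axis=1).astype(float)
    n_alt = (calls == HOM_ALT).sum(axis=1).astype(float)
    n_het = (calls == HET).sum(axis=1).astype(float)
    n_called = n_ref + n_alt + n_het
    call_rate = n_called / n

    with np.errstate(divide="ignore", invalid="ignore"):
        freq_ref = np.where(n_called > 0, n_ref / n_called, np.nan)
        freq_alt = np.where(n_called > 0, n_alt / n_called, np.nan)
        freq_het = np.where(n_called > 0, n_het / n_called, np.nan)
        p_alt = np.where(n_called > 0, (2 * n_alt + n_het) / (2 * n_called), np.nan)
        # presence frequency of each allele among called genotypes
        carry_ref = np.where(n_called > 0, (n_ref + n_het) / n_called, np.nan)
        carry_alt = np.where(n_called > 0, (n_alt + n_het) / n_called, np.nan)

    maf = np.minimum(p_alt, 1 - p_alt)
    pic = 1 - p_alt**2 - (1 - p_alt) ** 2
    avg_pic = 0.5 * (
        (1 - carry_ref**2 - (1 - carry_ref) ** 2)
        + (1 - carry_alt**2 - (1 - carry_alt) ** 2)
    )

    return pd.DataFrame(
        {
            "n_called": n_called.astype(int),
            "call_rate": call_rate,
            "freq_hom_ref": freq_ref,
            "freq_hom_alt": freq_alt,
            "freq_het": freq_het,
            "maf": maf,
            "pic": pic,
            "avg_pic": avg_pic,
        },
        index=pd.Index(gm.locus_ids, name="AlleleID"),
    )


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds for locus filtering; ``None`` disables a criterion.

    ``max_missingness`` and ``min_call_rate`` are two spellings of one
    quantity (missingness = 1 - call rate); both may be given.
    ``require_placed`` drops loci without a chromosome or on the unplaced
    pseudo-chromosome Chr00.
    """

    max_missingness: float | None = None
    min_pic: float | None = None
    min_maf: float | None = None
    min_call_rate: float | None = None
    require_placed: bool = False

    def __post_init__(self) -> None:
        for name in ("max_missingness", "min_pic", "min_maf", "min_call_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: recipe used for breeding-parent matrices (<=25% missing, PIC >= 0.25, MAF >= 10%)
PARENT_FILTER = FilterSpec(max_missingness=0.25, min_pic=0.25, min_maf=0.10)

#: stringent recipe used for segregating progeny (PIC >= 0.25, MAF >= 20%,
#: call rate >= 90%, placed loci only)
PROGENY_FILTER = FilterSpec(
    min_pic=0.25, min_maf=0.20, min_call_rate=0.90, require_placed=True
)


@dataclass
class FilterReport:
    """Summary of a filtering pass."""

    n_input: int
    n_kept: int
    thresholds: dict
    per_criterion: dict = field(default_factory=dict)
    first_fail: dict = field(default_factory=dict)
    not_evaluated: list = field(default_factory=lambda: ["allele_depth"])
    warnings: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


# criterion order used for first-fail attribution
_CRITERIA = ("missingness", "pic", "maf", "call_rate", "placement")


def _criterion_failures(
    gm: GenotypeMatrix, quality: pd.DataFrame, spec: FilterSpec
) -> dict[str, np.ndarray]:
    """Boolean fail-mask per active criterion (NaN metrics count as failures)."""
    fails: dict[str, np.ndarray] = {}
    cr = quality["call_rate"].to_numpy()
    if spec.max_missingness is not None:
        fails["missingness"] = (1 - cr) > spec.max_missingness
    if spec.min_pic is not None:
        pic = quality["pic"].to_numpy()
        fails["pic"] = ~(pic >= spec.min_pic)
    if spec.min_maf is not None:
        maf = quality["maf"].to_numpy()
        fails["maf"] = ~(maf >= spec.min_maf)
    if spec.min_call_rate is not None:
        fails["call_rate"] = cr < spec.min_call_rate
    if spec.require_placed:
        fails["placement"] = np.array([not l.is_placed for l in gm.loci])
    return fails


def filter_loci(
    gm: GenotypeMatrix, spec: FilterSpec
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci passing every active criterion of ``spec``.

    A locus survives iff missingness <= max_missingness AND pic >= min_pic
    AND maf >= min_maf AND call_rate >= min_call_rate AND (when required)
    it has a real chromosome assignment. The report tallies removals both
    per criterion (a locus may fail several) and by first failing
    criterion. Sequencing-depth requirements cannot be evaluated from a
    genotype matrix and are recorded as not evaluated.

    An empty result is allowed and flagged with a warning in the report.
    """
    quality = locus_quality(gm)
    fails = _criterion_failures(gm, quality, spec)
    n = gm.n_loci
    any_fail = np.zeros(n, dtype=bool)
    for mask in fails.values():
        any_fail |= mask

    per_criterion = {k: int(m.sum()) for k, m in fails.items()}
    first_fail: dict[str, int] = {}
    attributed = np.zeros(n, dtype=bool)
    for crit in _CRITERIA:
        if crit in fails:
            fresh = fails[crit] & ~attributed
            first_fail[crit] = int(fresh.sum())
            attributed |= fails[crit]

    keep_ids = [l.allele_id for l, bad in zip(gm.loci, any_fail) if not bad]
    report = FilterReport(
        n_input=n,
        n_kept=len(keep_ids),
        thresholds=asdict(spec),
        per_criterion=per_criterion,
        first_fail=first_fail,
    )
    if not keep_ids:
        report.warnings.append("no loci passed the filter")
        filtered = GenotypeMatrix(loci=[], samples=list(gm.samples),
                                  calls=np.empty((0, gm.n_samples), dtype=np.int8))
        return filtered, report
    return gm.subset(locus_ids=keep_ids), report


def diploidize(alt_count: int | np.ndarray, ploidy: int = 6) -> int | np.ndarray:
    """Collapse an alternative-allele dosage into a diploidized code.

    0 copies -> HOM_REF, ``ploidy`` copies -> HOM_ALT, any intermediate
    dosage -> HET (a hexaploid's five heterozygous classes collapse to
    one).
    """
    if ploidy <= 0 or ploidy % 2:
        raise ValueError(f"ploidy must be a positive even integer, got {ploidy}")
    arr = np.asarray(alt_count)
    if np.any(arr > ploidy) or np.any(arr < 0):
        raise ValueError(f"alt_count must lie in [0, {ploidy}]")
    out = np.full(arr.shape, HET, dtype=np.int8)
    out[arr == 0] = HOM_REF
    out[arr == ploidy] = HOM_ALT
    if np.isscalar(alt_count) or arr.ndim == 0:
        return int(out[()])
    return out
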