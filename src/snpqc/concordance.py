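"""Replicate-concordance detection of mislabeled clones.

A clonal genotype propagated through several stages (tissue culture,
screenhouse, field) should yield near-identical genotype calls at every
stage. A genotype whose replicated samples do not cluster together on the
allele-sharing distance is taken as a mislabeling (sample mix-up) event.
Two decision rules are provided:

* ``tree_clade`` (default): the genotype's replicates must form their own
  clade on the neighbor-joining tree of all samples — formally, the
  replicate set must be one side of some edge bipartition of the unrooted
  tree. This mirrors judging clusters on a published tree.
* ``exclusive_cluster``: the largest ASD among the replicates must be
  strictly smaller than the smallest ASD from any replicate to any
  non-replicate sample. Purely distance-based and tree-free.

A genotype whose replicates agree among themselves (within a resolvability
floor) but that fails only because a distinct genotype sits closer than
that floor is a near-duplicate clone: it is flagged unresolvable instead
of being counted as mislabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, asd_matrix
from .genotypes import GenotypeMatrix, GenotypeError
from .popgen import MantelResult, mantel
from .trees import neighbor_joining, tree_bipartitions

__all__ = [
    "ConcordanceReport",
    "StagePairCorrelation",
    "replicate_concordance",
    "stage_matrix_correlation",
    "DEFAULT_STAGES",
]

DEFAULT_STAGES = ("in_vitro", "screenhouse", "field")


@dataclass
class ConcordanceReport:
    """Per-genotype replicate-cluster verdicts and the overall rate.

    ``per_genotype`` maps genotype_id to a record with ``status`` in
    {"concordant", "discordant", "unresolvable", "untestable"},
    ``within_max_asd`` (largest replicate-replicate distance) and
    ``nearest_outsider_asd``. ``mislabeling_pct`` is
    ``100 * n_discordant / n_tested`` where ``n_tested`` counts genotypes
    with a definite verdict (unresolvable and single-replicate genotypes
    are excluded from both numerator and denominator).
    """

    method: str
    per_genotype: dict[str, dict]
    n_tested: int
    n_discordant: int
    n_unresolvable: int
    n_untestable: int
    mislabeling_pct: float
    stage_flows: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_tested": self.n_tested,
            "n_discordant": self.n_discordant,
            "n_unresolvable": self.n_unresolvable,
            "n_untestable": self.n_untestable,
            "mislabeling_pct": self.mislabeling_pct,
            "per_genotype": self.per_genotype,
        }


def _replicate_groups(
    gm: GenotypeMatrix, replicate_map: pd.DataFrame
) -> dict[str, list[str]]:
    known = set(gm.sample_ids)
    missing = sorted(set(replicate_map["sample_id"]) - known)
    if missing:
        raise GenotypeError(f"replicate map references unknown samples: {missing}")
    groups: dict[str, list[str]] = {}
    for gid, sub in replicate_map.groupby("genotype_id", sort=True):
        groups[gid] = list(sub["sample_id"])
    return groups


def _stage_order(replicate_map: pd.DataFrame) -> list[str]:
    seen = list(dict.fromkeys(replicate_map["stage"]))
    known = [s for s in DEFAULT_STAGES if s in seen]
    return known + [s for s in seen if s not in known]


def replicate_concordance(
    gm: GenotypeMatrix,
    replicate_map: pd.DataFrame,
    method: str = "tree_clade",
    distances: DistanceMatrix | None = None,
    min_overlap: int = 20,
    resolvability_floor: float = 0.01,
) -> ConcordanceReport:
    """Classify each replicated genotype as concordant or mislabeled.

    Parameters
    ----------
    gm
        Genotype matrix containing every sample in the map.
    replicate_map
        DataFrame with columns ``sample_id, genotype_id, stage``.
    method
        ``"tree_clade"`` or ``"exclusive_cluster"`` (see module docstring).
    distances
        Optional precomputed ASD matrix over ``gm``'s samples.
    resolvability_floor
        A discordant genotype whose nearest outsider sits closer than this
        ASD is flagged unresolvable rather than mislabeled.
    """
    if method not in ("tree_clade", "exclusive_cluster"):
        raise ValueError(f"unknown method {method!r}")
    groups = _replicate_groups(gm, replicate_map)
    if distances is None:
        distances = asd_matrix(gm, min_overlap=min_overlap)
    idx = distances.index()

    splits = None
    if method == "tree_clade":
        tree = neighbor_joining(distances)
        sides: set[frozenset] = set()
        for bip in tree_bipartitions(tree):
            sides.update(bip)
        # pendant-adjacent cherries of size 2..n-2 are covered; singleton
        # replicate sets never reach here (untestable)
        splits = sides

    per: dict[str, dict] = {}
    n_discordant = n_unresolvable = n_untestable = n_tested = 0
    sample_to_gid = dict(zip(replicate_map["sample_id"], replicate_map["genotype_id"]))

    all_ids = distances.labels
    for gid, members in groups.items():
        rec: dict = {"n_replicates": len(members)}
        if len(members) < 2:
            rec["status"] = "untestable"
            rec["concordant"] = None
            n_untestable += 1
            per[gid] = rec
            continue
        m_idx = [idx[s] for s in members]
        o_idx = [idx[s] for s in all_ids if sample_to_gid.get(s) != gid]
        within = distances.values[np.ix_(m_idx, m_idx)]
        within_max = float(within.max())
        if o_idx:
            between = distances.values[np.ix_(m_idx, o_idx)]
            nearest_out = float(between.min())
        else:
            nearest_out = np.inf
        rec["within_max_asd"] = within_max
        rec["nearest_outsider_asd"] = nearest_out

        if method == "exclusive_cluster":
            ok = within_max < nearest_out
        else:
            member_set = frozenset(members)
            n_total = len(all_ids)
            if len(members) == n_total:
                ok = True
            elif len(members) > n_total - 2:
                # complement smaller than 2 leaves: the set is trivially a side
                ok = True
            else:
                ok = member_set in splits

        if ok:
            rec["status"] = "concordant"
            rec["concordant"] = True
            n_tested += 1
        elif within_max < resolvability_floor and nearest_out < resolvability_floor:
            # replicates agree among themselves but a distinct genotype sits
            # within the floor: a near-duplicate clone, not a mislabel
            rec["status"] = "unresolvable"
            rec["concordant"] = None
            n_unresolvable += 1
        else:
            rec["status"] = "discordant"
            rec["concordant"] = False
            n_tested += 1
            n_discordant += 1
        per[gid] = rec

    pct = 100.0 * n_discordant / n_tested if n_tested else np.nan
    flows = _stage_flows(replicate_map, per)
    return ConcordanceReport(
        method=method,
        per_genotype=per,
        n_tested=n_tested,
        n_discordant=n_discordant,
        n_unresolvable=n_unresolvable,
        n_untestable=n_untestable,
        mislabeling_pct=pct,
        stage_flows=flows,
    )


def _stage_flows(replicate_map: pd.DataFrame, per: dict[str, dict]) -> pd.DataFrame:
    """(genotype, stage_from, stage_to, concordant) rows for alluvial plots."""
    stages = _stage_order(replicate_map)
    rows = []
    for gid, sub in replicate_map.groupby("genotype_id", sort=True):
        have = [s for s in stages if s in set(sub["stage"])]
        verdict = per.get(gid, {}).get("concordant")
        for a, b in zip(have, have[1:]):
            rows.append((gid, a, b, verdict))
    return pd.DataFrame(
        rows, columns=["genotype_id", "stage_from", "stage_to", "concordant"]
    )


@dataclass(frozen=True)
class StagePairCorrelation:
    """Mantel agreement between two stages' distance matrices."""

    stage_a: str
    stage_b: str
    mantel: MantelResult
    discordance_rate_pct: float  # 100 * (1 - r), reading r as agreement


def stage_matrix_correlation(
    gm: GenotypeMatrix,
    replicate_map: pd.DataFrame,
    stages: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    min_overlap: int = 20,
) -> list[StagePairCorrelation]:
    """Mantel correlation between per-stage ASD matrices.

    One genotype-labelled ASD matrix is built per stage from the genotypes
    with exactly one sample in every requested stage (complete cases);
    genotypes missing any stage are dropped from all matrices. Returns one
    result per stage pair, in stage order.
    """
    if stages is None:
        stages = _stage_order(replicate_map)
    stages = list(stages)
    if len(stages) < 2:
        raise GenotypeError("need at least two stages")

    by_gid: dict[str, dict[str, str]] = {}
    for _, row in replicate_map.iterrows():
        by_gid.setdefault(row["genotype_id"], {})[row["stage"]] = row["sample_id"]
    complete = sorted(g for g, m in by_gid.items() if all(s in m for s in stages))
    dropped = sorted(set(by_gid) - set(complete))
    if dropped:
        warnings.warn(f"{len(dropped)} genotype(s) missing a stage dropped: {dropped[:5]}...")
    if len(complete) < 3:
        raise GenotypeError("fewer than 3 genotypes have a sample in every stage")

    mats: dict[str, DistanceMatrix] = {}
    for stage in stages:
        ids = [by_gid[g][stage] for g in complete]
        sub = gm.subset(sample_ids=ids)
        dm = asd_matrix(sub, min_overlap=min_overlap)
        mats[stage] = DistanceMatrix(labels=complete, values=dm.values,
                                     n_overlap=dm.n_overlap)

    out = []
    for i, sa in enumerate(stages):
        for sb in stages[i + 1 :]:
            res = mantel(mats[sa], mats[sb], n_perm=n_perm, seed=seed)
            out.append(
                StagePairCorrelation(
                    stage_a=sa,
                    stage_b=sb,
                    mantel=res,
                    discordance_rate_pct=100.0 * (1.0 - res.r),
                )
            )
    return out
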