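"""Diagnostic SNP panel construction and evaluation.

Workflow: from a quality-filtered parent marker set, keep the markers that
also behave well in a segregating progeny population (the *intermediate*
set), then pick ``k`` markers per chromosome maximizing physical spread
(for ``k = 2``, the most widely separated pair). Chromosomes that come up
short are topped up from a *fallback* candidate list (typically the full
filtered parent set) by maximal distance to what is already selected.
Trait-associated markers ride along unchanged. The reduced panel is
evaluated against the full set by tree dissimilarity, inbreeding-rank
preservation and mislabeling-rate agreement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import replicate_concordance
from .distance import asd_matrix
from .genotypes import GenotypeMatrix, GenotypeError, TraitMarker
from .popgen import nei_fis
from .qc import FilterSpec, filter_loci, locus_quality
from .trees import compare_trees, neighbor_joining

__all__ = [
    "PanelSelection",
    "build_intermediate",
    "select_panel",
    "merge_trait_markers",
    "evaluate_panel",
    "published_panel",
    "DEFAULT_CHROMOSOMES",
]

#: the 15 base chromosomes of the target genome
DEFAULT_CHROMOSOMES = tuple(f"Chr{i:02d}" for i in range(1, 16))

_MARKER_COLUMNS = ["allele_id", "chromosome", "position", "pic"]


@dataclass
class PanelSelection:
    """An ordered marker panel with per-chromosome provenance.

    ``markers`` is a DataFrame with columns ``allele_id, chromosome,
    position, pic`` (plus ``source`` and, after a trait merge, ``trait``),
    ordered by chromosome then position. ``fallbacks`` records markers
    drawn from the fallback set and why; ``deficits`` maps chromosomes to
    their remaining shortfall.
    """

    markers: pd.DataFrame
    k_per_chrom: int
    per_chromosome: dict[str, list[str]] = field(default_factory=dict)
    fallbacks: list[dict] = field(default_factory=list)
    deficits: dict[str, int] = field(default_factory=dict)
    trait_markers: list[TraitMarker] = field(default_factory=list)
    evaluation: dict | None = None

    @property
    def allele_ids(self) -> list[str]:
        return list(self.markers["allele_id"])

    def to_tsv(self, path: str | Path) -> None:
        df = self.markers.copy()
        df.insert(0, "No", range(1, len(df) + 1))
        df.to_csv(path, sep="\t", index=False)


def published_panel() -> tuple[pd.DataFrame, list[TraitMarker]]:
    """The published 36-marker rapid-QC reference panel shipped with the
    package: 30 fingerprinting SNPs (two per chromosome) and 6
    trait-associated markers.

    Returns the 30 fingerprinting markers as a marker table (``allele_id,
    chromosome, position, allele_seq, snp_change``) and the trait markers
    as :class:`TraitMarker` objects.
    """
    path = Path(__file__).parent / "data" / "published_panel.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    core = df[df["trait"].isna()].copy()
    core = core[["allele_id", "chromosome", "position", "allele_seq", "snp_change"]]
    traits = [
        TraitMarker(
            trait=row["trait"],
            chromosome=row["chromosome"],
            position=int(row["position"]),
            snp_change=row["snp_change"],
            genetic_position=float(row["genetic_position"]),
        )
        for _, row in df[df["trait"].notna()].iterrows()
    ]
    return core.reset_index(drop=True), traits


def _marker_table(gm: GenotypeMatrix, pic: Mapping[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "allele_id": [l.allele_id for l in gm.loci],
            "chromosome": [l.chromosome for l in gm.loci],
            "position": [l.position for l in gm.loci],
            "pic": [pic.get(l.allele_id, np.nan) for l in gm.loci],
        }
    )


def build_intermediate(
    parents_gm: GenotypeMatrix,
    progeny_gm: GenotypeMatrix,
    filter_spec: FilterSpec,
) -> pd.DataFrame:
    """Markers passing the filter in parents and usable in progeny.

    A marker is retained iff it passes ``filter_spec`` in the parents and
    is present in the progeny matrix with at least one called sample and
    segregating there (MAF > 0). The result is ranked by parent PIC,
    descending (ties by AlleleID), as a marker table suitable for
    :func:`select_panel`.
    """
    shared = set(parents_gm.locus_ids) & set(progeny_gm.locus_ids)
    if not shared:
        raise GenotypeError("parents and progeny share no AlleleIDs")
    filtered, _ = filter_loci(parents_gm, filter_spec)
    candidates = [l for l in filtered.locus_ids if l in shared]
    if not candidates:
        raise GenotypeError("no filtered parent marker is present in the progeny")
    prog_q = locus_quality(progeny_gm.subset(locus_ids=[
        l for l in progeny_gm.locus_ids if l in set(candidates)
    ]))
    usable = set(prog_q.index[(prog_q["n_called"] > 0) & (prog_q["maf"] > 0)])
    keep = [l for l in candidates if l in usable]
    if not keep:
        raise GenotypeError("no shared marker segregates in the progeny")
    parent_pic = locus_quality(filtered)["pic"]
    table = _marker_table(filtered.subset(locus_ids=keep), parent_pic.to_dict())
    return table.sort_values(
        ["pic", "allele_id"], ascending=[False, True]
    ).reset_index(drop=True)


def _min_pairwise_distance(positions: Sequence[int]) -> float:
    return min(
        abs(a - b) for a, b in itertools.combinations(positions, 2)
    ) if len(positions) > 1 else 0.0


def _choose_k_spread(sub: pd.DataFrame, k: int) -> list[int]:
    """Row indices of the k markers maximizing minimum pairwise bp distance.

    Exhaustive when the candidate count is small (the usual case);
    farthest-point greedy otherwise. Ties break toward higher mean PIC,
    then lexicographically lowest AlleleID tuple.
    """
    n = len(sub)
    pos = sub["position"].to_numpy(dtype=float)
    pic = sub["pic"].to_numpy(dtype=float)
    ids = sub["allele_id"].to_numpy()

    def key(combo: tuple[int, ...]):
        d = _min_pairwise_distance([pos[i] for i in combo])
        mean_pic = float(np.nan_to_num(pic[list(combo)], nan=0.0).mean())
        return (-d, -mean_pic, tuple(sorted(ids[list(combo)])))

    from math import comb

    if comb(n, k) <= 20000:
        best = min(itertools.combinations(range(n), k), key=key)
        return list(best)
    # greedy: start from the extreme pair, add farthest-from-selected
    order = np.argsort(pos, kind="stable")
    chosen = [int(order[0]), int(order[-1])]
    while len(chosen) < k:
        rest = [i for i in range(n) if i not in chosen]
        nxt = max(
            rest,
            key=lambda i: (min(abs(pos[i] - pos[j]) for j in chosen),
                           pic[i] if np.isfinite(pic[i]) else 0.0,
                           ),
        )
        chosen.append(int(nxt))
    return chosen


def select_panel(
    candidates: pd.DataFrame,
    k_per_chrom: int = 2,
    fallback: pd.DataFrame | None = None,
    chromosomes: Iterable[str] | None = None,
) -> PanelSelection:
    """Pick ``k`` markers per chromosome by maximal physical spread.

    ``candidates`` and ``fallback`` are marker tables (columns
    ``allele_id, chromosome, position, pic``). Chromosomes with fewer than
    ``k`` placed candidates keep what they have and are topped up from the
    fallback table by maximal distance to the already-selected markers on
    that chromosome (ties by PIC, then AlleleID). A chromosome absent from
    both sets is reported as a deficit, never an exception. Selection is
    deterministic: the same inputs always yield the same panel.
    """
    if k_per_chrom < 1:
        raise ValueError("k_per_chrom must be >= 1")
    for col in _MARKER_COLUMNS:
        if col not in candidates.columns:
            raise GenotypeError(f"candidate table is missing column {col!r}")
    if chromosomes is None:
        pools = [candidates] + ([fallback] if fallback is not None else [])
        chromosomes = sorted(
            {c for df in pools for c in df["chromosome"].dropna().unique()}
        )
    chromosomes = list(chromosomes)

    placed = candidates.dropna(subset=["chromosome", "position"])
    fb = (
        fallback.dropna(subset=["chromosome", "position"])
        if fallback is not None
        else None
    )

    rows: list[pd.DataFrame] = []
    per_chrom: dict[str, list[str]] = {}
    fallbacks: list[dict] = []
    deficits: dict[str, int] = {}

    for chrom in chromosomes:
        sub = placed[placed["chromosome"] == chrom].reset_index(drop=True)
        if len(sub) >= k_per_chrom:
            chosen_idx = _choose_k_spread(sub, k_per_chrom)
            chosen = sub.iloc[sorted(chosen_idx)].copy()
            chosen["source"] = "candidate"
        else:
            chosen = sub.copy()
            chosen["source"] = "candidate"
            need = k_per_chrom - len(chosen)
            if fb is not None and need > 0:
                pool = fb[
                    (fb["chromosome"] == chrom)
                    & ~fb["allele_id"].isin(chosen["allele_id"])
                ].reset_index(drop=True)
                for _ in range(need):
                    if pool.empty:
                        break
                    sel_pos = chosen["position"].to_numpy(dtype=float)

                    def dist_to_selected(p: float) -> float:
                        return float(np.min(np.abs(sel_pos - p))) if len(sel_pos) else np.inf

                    ranked = sorted(
                        pool.itertuples(index=True),
                        key=lambda t: (
                            -dist_to_selected(t.position),
                            -(t.pic if np.isfinite(t.pic) else 0.0),
                            t.allele_id,
                        ),
                    )
                    pick = ranked[0]
                    row = pool.loc[[pick.Index]].copy()
                    row["source"] = "fallback"
                    chosen = pd.concat([chosen, row], ignore_index=True)
                    fallbacks.append(
                        {
                            "allele_id": pick.allele_id,
                            "chromosome": chrom,
                            "reason": f"chromosome had {len(sub)} candidate(s), needed {k_per_chrom}",
                        }
                    )
                    pool = pool.drop(index=pick.Index).reset_index(drop=True)
            if len(chosen) < k_per_chrom:
                deficits[chrom] = k_per_chrom - len(chosen)
        chosen = chosen.sort_values("position").reset_index(drop=True)
        per_chrom[chrom] = list(chosen["allele_id"])
        if len(chosen):
            rows.append(chosen)

    markers = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=_MARKER_COLUMNS + ["source"])
    )
    if markers["allele_id"].duplicated().any():
        dups = markers.loc[markers["allele_id"].duplicated(), "allele_id"].tolist()
        raise GenotypeError(f"panel selection produced duplicate AlleleIDs: {dups}")
    markers = markers.sort_values(["chromosome", "position"]).reset_index(drop=True)
    return PanelSelection(
        markers=markers,
        k_per_chrom=k_per_chrom,
        per_chromosome=per_chrom,
        fallbacks=fallbacks,
        deficits=deficits,
    )


def merge_trait_markers(
    panel: PanelSelection, traits: Sequence[TraitMarker]
) -> PanelSelection:
    """Append trait-specific markers to a panel (distinct role, no dedup).

    Trait markers are carried as given; a trait marker whose allele_id
    already sits in the panel is kept once with a warning. The merged
    panel size is ``len(panel) + len(traits)`` in the usual disjoint case.
    """
    markers = panel.markers.copy()
    kept_traits: list[TraitMarker] = []
    rows = []
    existing = set(markers["allele_id"])
    for t in traits:
        tid = t.allele_id or f"trait:{t.trait}@{t.chromosome}:{t.position}"
        if tid in existing:
            warnings.warn(f"trait marker {tid!r} already in panel; kept once")
            continue
        rows.append(
            {
                "allele_id": tid,
                "chromosome": t.chromosome,
                "position": t.position,
                "pic": np.nan,
                "source": "trait",
                "trait": t.trait,
            }
        )
        existing.add(tid)
        kept_traits.append(t)
    if rows:
        markers = pd.concat([markers, pd.DataFrame(rows)], ignore_index=True)
    return PanelSelection(
        markers=markers,
        k_per_chrom=panel.k_per_chrom,
        per_chromosome=dict(panel.per_chromosome),
        fallbacks=list(panel.fallbacks),
        deficits=dict(panel.deficits),
        trait_markers=list(panel.trait_markers) + kept_traits,
        evaluation=panel.evaluation,
    )


def evaluate_panel(
    gm_full: GenotypeMatrix,
    panel: PanelSelection | Sequence[str],
    populations: Mapping[str, str] | None = None,
    replicate_map: pd.DataFrame | None = None,
    min_overlap: int = 1,
    concordance_method: str = "tree_clade",
) -> dict:
    """Compare a reduced panel against the full marker set.

    Computes (a) the strict tree dissimilarity between NJ trees built from
    full-set and panel-set ASD; (b) Nei F_IS per population on both sets
    and whether the panel preserves the full set's population ranking;
    (c) when a replicate map is given, the mislabeling rate via panel vs
    via full set. Panel markers absent from ``gm_full`` (e.g. appended
    trait markers genotyped separately) are ignored with a note.
    """
    ids = panel.allele_ids if isinstance(panel, PanelSelection) else list(panel)
    present = [i for i in ids if i in set(gm_full.locus_ids)]
    absent = sorted(set(ids) - set(present))
    if len(present) < 2:
        raise GenotypeError("panel has fewer than 2 markers present in the matrix")
    gm_panel = gm_full.subset(locus_ids=present)

    d_full = asd_matrix(gm_full, min_overlap=min_overlap)
    d_panel = asd_matrix(gm_panel, min_overlap=min_overlap)
    cmp = compare_trees(neighbor_joining(d_full), neighbor_joining(d_panel))

    result: dict = {
        "n_panel_markers_used": len(present),
        "panel_markers_absent": absent,
        "tree_dissimilarity_pct": cmp.dissimilarity_pct,
        "n_shared_bipartitions": cmp.n_shared,
    }

    has_pops = populations is not None or any(
        s.population is not None for s in gm_full.samples
    )
    if has_pops:
        fis_full = nei_fis(gm_full, populations)
        fis_panel = nei_fis(gm_panel, populations)
        rank_full = sorted(fis_full.defined(), key=fis_full.per_population.get, reverse=True)
        rank_panel = sorted(fis_panel.defined(), key=fis_panel.per_population.get, reverse=True)
        result["nei_fis_full"] = fis_full.per_population
        result["nei_fis_panel"] = fis_panel.per_population
        result["fis_rank_preserved"] = rank_full == rank_panel

    if replicate_map is not None:
        rep_full = replicate_concordance(
            gm_full, replicate_map, method=concordance_method, distances=d_full
        )
        rep_panel = replicate_concordance(
            gm_panel, replicate_map, method=concordance_method, distances=d_panel
        )
        result["mislabeling_pct_full"] = rep_full.mislabeling_pct
        result["mislabeling_pct_panel"] = rep_panel.mislabeling_pct
    return result
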