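"""Diploidized genotype matrices and their companion tables.

The central container is :class:`GenotypeMatrix`: a loci x samples matrix of
diploidized genotype calls. Hexaploid dosage classes are collapsed to three
codes plus missing; on disk the calls use the conventional serialization
``0`` = homozygous reference, ``1`` = homozygous alternative, ``2`` =
heterozygous and ``-`` = missing. Internally the four states are small
integer constants (:data:`HOM_REF`, :data:`HOM_ALT`, :data:`HET`,
:data:`MISSING`) so that no arithmetic is ever performed on the
non-dosage file codes.

Companion tables (sample -> population assignments, replicate maps linking
clone identities to per-stage samples, and trait-marker lists) are plain
two-to-five column TSV files handled by the ``read_*``/``write_*`` helpers
below.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HOM_ALT",
    "HET",
    "MISSING",
    "GenotypeError",
    "GenotypeParseError",
    "LocusInfo",
    "SampleInfo",
    "TraitMarker",
    "GenotypeMatrix",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_population_table",
    "write_population_table",
    "read_replicate_table",
    "write_replicate_table",
    "read_trait_markers",
    "write_trait_markers",
]

# Internal genotype codes. HET is deliberately not between the homozygotes:
# dosage conversion is explicit via GenotypeMatrix.dosage().
HOM_REF: int = 0
HOM_ALT: int = 1
HET: int = 2
MISSING: int = -1

_VALID_CODES = frozenset({HOM_REF, HOM_ALT, HET, MISSING})

# File tokens follow the diploidized coding 0 = AA, 1 = BB, 2 = AB, "-" = missing.
TOKEN_TO_CODE: Mapping[str, int] = {"0": HOM_REF, "1": HOM_ALT, "2": HET, "-": MISSING}
CODE_TO_TOKEN: Mapping[int, str] = {HOM_REF: "0", HOM_ALT: "1", HET: "2", MISSING: "-"}

# Diploid-equivalent dosage of the alternative allele; missing maps to -1.
_DOSAGE_LUT = np.full(4, -1, dtype=np.int8)
_DOSAGE_LUT[HOM_REF] = 0
_DOSAGE_LUT[HOM_ALT] = 2
_DOSAGE_LUT[HET] = 1

#: chromosome label used by the genotyping platform for unplaced markers
UNPLACED_CHROM = "Chr00"

# Platform quality columns reported by the genotyping provider (stored, never
# recomputed from them).
PLATFORM_QUALITY_COLUMNS = (
    "CallRate",
    "FreqHomRef",
    "FreqHomSnp",
    "FreqHets",
    "PICSnp",
    "AvgPIC",
)

_DART_META_COLUMNS = (
    "AlleleID",
    "AlleleSequence",
    "SNP",
    "Chrom",
    "ChromPos",
) + PLATFORM_QUALITY_COLUMNS

_SIMPLE_META_COLUMNS = ("AlleleID", "Chrom", "Pos")


class GenotypeError(ValueError):
    """Invalid genotype data (duplicate IDs, unknown codes, bad shapes)."""


class GenotypeParseError(GenotypeError):
    """A genotype file could not be parsed."""


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one biallelic locus."""

    allele_id: str
    chromosome: str | None = None
    position: int | None = None
    allele_seq: str | None = None
    snp_change: str | None = None
    platform_quality: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.position is not None and self.position <= 0:
            raise GenotypeError(
                f"locus {self.allele_id}: position must be positive, got {self.position}"
            )

    @property
    def is_placed(self) -> bool:
        """True if the locus has a genuine chromosome assignment."""
        return self.chromosome is not None and self.chromosome != UNPLACED_CHROM


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one DNA sample."""

    sample_id: str
    population: str | None = None
    genotype_id: str | None = None
    stage: str | None = None


@dataclass(frozen=True)
class TraitMarker:
    """A trait-associated marker carried into a diagnostic panel as-is."""

    trait: str
    chromosome: str
    position: int
    snp_change: str | None = None
    genetic_position: float | None = None
    allele_id: str | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise GenotypeError(
                f"trait marker {self.trait}: position must be positive, got {self.position}"
            )


@dataclass
class GenotypeMatrix:
    """Loci x samples matrix of diploidized genotype calls.

    Parameters
    ----------
    loci
        Ordered locus metadata; AlleleIDs must be unique.
    samples
        Ordered sample metadata; sample IDs must be unique.
    calls
        ``(n_loci, n_samples)`` int8 array over
        {HOM_REF, HOM_ALT, HET, MISSING}.
    """

    loci: list[LocusInfo]
    samples: list[SampleInfo]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (len(self.loci), len(self.samples)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.calls[i, j]} at locus "
                f"{self.loci[i].allele_id}, sample {self.samples[j].sample_id}"
            )
        self._check_unique([l.allele_id for l in self.loci], "AlleleID")
        self._check_unique([s.sample_id for s in self.samples], "sample ID")

    @staticmethod
    def _check_unique(ids: Sequence[str], what: str) -> None:
        seen: set[str] = set()
        dups = {i for i in ids if i in seen or seen.add(i)}
        if dups:
            raise GenotypeError(f"duplicate {what}(s): {sorted(dups)}")

    # -- basic views ------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> list[str]:
        return [l.allele_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def locus_index(self) -> dict[str, int]:
        return {l.allele_id: i for i, l in enumerate(self.loci)}

    def sample_index(self) -> dict[str, int]:
        return {s.sample_id: j for j, s in enumerate(self.samples)}

    def dosage(self) -> np.ndarray:
        """Diploid-equivalent alternative-allele dosage (0/1/2, -1 = missing)."""
        return _DOSAGE_LUT[self.calls]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN for missing calls."""
        d = self.dosage().astype(float)
        d[d < 0] = np.nan
        return d

    # -- subsetting -------------------------------------------------------

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        locus_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to the requested IDs, in the given order.

        Raises :class:`GenotypeError` naming the offenders when an ID is
        unknown, and for an explicitly empty selection.
        """
        if sample_ids is None:
            sample_ids = self.sample_ids
        if locus_ids is None:
            locus_ids = self.locus_ids
        sample_ids = list(sample_ids)
        locus_ids = list(locus_ids)
        if not sample_ids or not locus_ids:
            raise GenotypeError("subset requires at least one sample and one locus")
        sidx = self.sample_index()
        lidx = self.locus_index()
        bad_s = [s for s in sample_ids if s not in sidx]
        bad_l = [l for l in locus_ids if l not in lidx]
        if bad_s or bad_l:
            raise GenotypeError(
                f"unknown IDs in subset request: samples={bad_s} loci={bad_l}"
            )
        rows = [lidx[l] for l in locus_ids]
        cols = [sidx[s] for s in sample_ids]
        return GenotypeMatrix(
            loci=[self.loci[i] for i in rows],
            samples=[self.samples[j] for j in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
        )

    def with_sample_info(self, infos: Mapping[str, SampleInfo]) -> "GenotypeMatrix":
        """Replace sample metadata by sample_id lookup (IDs must match)."""
        samples = [infos.get(s.sample_id, s) for s in self.samples]
        return GenotypeMatrix(loci=list(self.loci), samples=samples, calls=self.calls.copy())

    def annotate_populations(self, populations: Mapping[str, str]) -> "GenotypeMatrix":
        samples = [
            replace(s, population=populations[s.sample_id])
            if s.sample_id in populations
            else s
            for s in self.samples
        ]
        return GenotypeMatrix(loci=list(self.loci), samples=samples, calls=self.calls.copy())


# ---------------------------------------------------------------------------
# Genotype CSV I/O
# ---------------------------------------------------------------------------


def _split_columns(header: Sequence[str], dialect: str) -> tuple[list[str], list[str]]:
    meta_names = _DART_META_COLUMNS if dialect == "dart_onerow" else _SIMPLE_META_COLUMNS
    meta: list[str] = []
    i = 0
    for col in header:
        if col in meta_names:
            meta.append(col)
            i += 1
        else:
            break
    if "AlleleID" not in meta:
        raise GenotypeParseError(
            f"no AlleleID column found before sample columns (header starts {list(header[:3])})"
        )
    return meta, list(header[i:])


def _parse_position(value: str) -> int | None:
    if value in ("", "nan", "NA", "-"):
        return None
    try:
        pos = int(float(value))
    except ValueError as exc:
        raise GenotypeParseError(f"invalid position {value!r}") from exc
    return pos if pos > 0 else None


def read_genotype_csv(
    path: str | Path,
    dialect: str = "simple",
    skip_header_prefix: str | None = "*",
) -> GenotypeMatrix:
    """Read a one-row-per-locus genotype CSV.

    Two dialects are supported. ``simple`` expects columns
    ``AlleleID, Chrom, Pos`` followed by one column per sample.
    ``dart_onerow`` mirrors the genotyping platform's one-row export:
    ``AlleleID, AlleleSequence, SNP, Chrom, ChromPos`` plus the platform
    quality columns (CallRate, FreqHomRef, FreqHomSnp, FreqHets, PICSnp,
    AvgPIC), any of which may be absent, followed by sample columns.

    Platform exports often carry preamble rows whose first cell starts with
    ``*``; these are skipped when ``skip_header_prefix`` is set (the
    tolerant header-skip; pass ``None`` to disable).

    Genotype cells must be one of ``0`` (hom. reference), ``1``
    (hom. alternative), ``2`` (heterozygous) or ``-`` (missing); anything
    else raises :class:`GenotypeParseError`.
    """
    if dialect not in ("simple", "dart_onerow"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    start = 0
    if skip_header_prefix:
        while start < len(lines) and lines[start].split(",", 1)[0].startswith(
            skip_header_prefix
        ):
            start += 1
    if start >= len(lines):
        raise GenotypeParseError(f"{path}: no header row found")
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(lines[start:])),
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc

    meta_cols, sample_cols = _split_columns(list(df.columns), dialect)
    if not sample_cols:
        # allowed: header-only file describes an empty panel of samples
        sample_cols = []

    pos_col = "ChromPos" if dialect == "dart_onerow" else "Pos"
    loci: list[LocusInfo] = []
    for _, row in df.iterrows():
        quality = None
        if dialect == "dart_onerow":
            q = {
                c: float(row[c])
                for c in PLATFORM_QUALITY_COLUMNS
                if c in meta_cols and row[c] not in ("", "NA")
            }
            quality = q or None
        chrom = row["Chrom"] if "Chrom" in meta_cols and row["Chrom"] != "" else None
        loci.append(
            LocusInfo(
                allele_id=row["AlleleID"],
                chromosome=chrom,
                position=_parse_position(row[pos_col]) if pos_col in meta_cols else None,
                allele_seq=row["AlleleSequence"]
                if "AlleleSequence" in meta_cols and row["AlleleSequence"] != ""
                else None,
                snp_change=row["SNP"] if "SNP" in meta_cols and row["SNP"] != "" else None,
                platform_quality=quality,
            )
        )

    calls = np.empty((len(df), len(sample_cols)), dtype=np.int8)
    for j, col in enumerate(sample_cols):
        tokens = df[col].to_numpy()
        for i, tok in enumerate(tokens):
            code = TOKEN_TO_CODE.get(tok.strip())
            if code is None:
                raise GenotypeParseError(
                    f"{path}: unrecognized genotype token {tok!r} at locus "
                    f"{loci[i].allele_id}, sample {col} (line {start + i + 2})"
                )
            calls[i, j] = code

    samples = [SampleInfo(sample_id=c) for c in sample_cols]
    return GenotypeMatrix(loci=loci, samples=samples, calls=calls)


def write_genotype_csv(
    gm: GenotypeMatrix, path: str | Path, dialect: str = "simple"
) -> None:
    """Write a genotype matrix re-readable by :func:`read_genotype_csv`.

    Column order is fixed by the dialect, so the output is byte-stable for
    a given matrix. Missing calls serialize as ``-``.
    """
    if dialect not in ("simple", "dart_onerow"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    data: dict[str, list] = {"AlleleID": [l.allele_id for l in gm.loci]}
    if dialect == "simple":
        data["Chrom"] = [l.chromosome or "" for l in gm.loci]
        data["Pos"] = ["" if l.position is None else str(l.position) for l in gm.loci]
    else:
        data["AlleleSequence"] = [l.allele_seq or "" for l in gm.loci]
        data["SNP"] = [l.snp_change or "" for l in gm.loci]
        data["Chrom"] = [l.chromosome or "" for l in gm.loci]
        data["ChromPos"] = ["" if l.position is None else str(l.position) for l in gm.loci]
        for qc in PLATFORM_QUALITY_COLUMNS:
            col = [
                ""
                if l.platform_quality is None or qc not in l.platform_quality
                else repr(float(l.platform_quality[qc]))
                for l in gm.loci
            ]
            if any(v != "" for v in col):
                data[qc] = col
    for j, s in enumerate(gm.samples):
        data[s.sample_id] = [CODE_TO_TOKEN[int(c)] for c in gm.calls[:, j]]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Companion tables (TSV)
# ---------------------------------------------------------------------------


def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>population`` (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: expected columns sample_id, population")
    col_s, col_p = df.columns[:2]
    if df[col_s].duplicated().any():
        dups = df[col_s][df[col_s].duplicated()].tolist()
        raise GenotypeError(f"duplicate sample IDs in population table: {dups}")
    return dict(zip(df[col_s], df[col_p]))


def write_population_table(populations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(populations), "population": list(populations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate map TSV: columns ``sample_id, genotype_id, stage``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype_id", "stage"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"{path}: replicate table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["genotype_id", "stage"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["genotype_id", "stage"]].drop_duplicates().values.tolist()
        raise GenotypeError(f"replicate table has duplicate (genotype, stage) pairs: {pairs}")
    return df[["sample_id", "genotype_id", "stage"]]


def write_replicate_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["sample_id", "genotype_id", "stage"]].to_csv(path, sep="\t", index=False)


def read_trait_markers(path: str | Path) -> list[TraitMarker]:
    """Read a trait-marker TSV with columns
    ``trait, genetic_position, chromosome, position, snp_change[, allele_id]``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"trait", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"{path}: trait table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        try:
            pos = int(row["position"])
        except (ValueError, TypeError) as exc:
            raise GenotypeParseError(
                f"{path}: malformed trait row for {row['trait']!r}: bad position "
                f"{row['position']!r}"
            ) from exc
        gpos = row["genetic_position"] if "genetic_position" in df.columns else ""
        out.append(
            TraitMarker(
                trait=row["trait"],
                chromosome=row["chromosome"],
                position=pos,
                snp_change=row.get("snp_change") or None,
                genetic_position=float(gpos) if gpos not in ("", "nan") else None,
                allele_id=(row.get("allele_id") or None)
                if "allele_id" in df.columns
                else None,
            )
        )
    return out


def write_trait_markers(markers: Iterable[TraitMarker], path: str | Path) -> None:
    markers = list(markers)
    pd.DataFrame(
        {
            "trait": [m.trait for m in markers],
            "genetic_position": [m.genetic_position for m in markers],
            "chromosome": [m.chromosome for m in markers],
            "position": [m.position for m in markers],
            "snp_change": [m.snp_change for m in markers],
            "allele_id": [m.allele_id for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)
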