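"""Allele-sharing distance (ASD) between diploidized genotypes.

The per-locus distance between two called genotypes is

* 0   if the codes are identical (including heterozygote vs heterozygote),
* 1   if one is homozygous reference and the other homozygous alternative,
* 0.5 if exactly one of the two is heterozygous,

and the pairwise ASD is the mean over loci where both samples are called
(pairwise deletion). The measure needs no Hardy-Weinberg or linkage
assumptions, which is what makes it suitable for diploidized polyploid
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError, HET, MISSING

__all__ = ["DistanceMatrix", "asd_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels.

    ``n_overlap`` (optional) records the number of loci each pairwise
    value was computed from; ``low_overlap`` flags pairs whose overlap
    fell below the requested minimum.
    """

    labels: list[str]
    values: np.ndarray
    n_overlap: np.ndarray | None = None
    low_overlap: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise GenotypeError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise GenotypeError("distance matrix labels must be unique")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise GenotypeError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise GenotypeError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.labels)}

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = self.index()
        missing = [l for l in labels if l not in idx]
        if missing:
            raise GenotypeError(f"unknown labels in reorder: {missing}")
        order = [idx[l] for l in labels]
        sub = np.ix_(order, order)
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[sub].copy(),
            n_overlap=None if self.n_overlap is None else self.n_overlap[sub].copy(),
            low_overlap=None if self.low_overlap is None else self.low_overlap[sub].copy(),
        )

    def relabel(self, mapping: dict[str, str]) -> "DistanceMatrix":
        return DistanceMatrix(
            labels=[mapping.get(l, l) for l in self.labels],
            values=self.values.copy(),
            n_overlap=None if self.n_overlap is None else self.n_overlap.copy(),
        )

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


def asd_matrix(
    gm: GenotypeMatrix,
    min_overlap: int = 20,
    zero_overlap: str = "error",
) -> DistanceMatrix:
    """Pairwise allele-sharing distances under pairwise deletion.

    Parameters
    ----------
    gm
        Genotype matrix with at least two samples.
    min_overlap
        Pairs sharing fewer called loci than this are flagged in
        ``low_overlap`` (the value is still reported).
    zero_overlap
        Policy for pairs with no shared called locus: ``"error"`` raises,
        ``"mean"`` substitutes the mean of the defined off-diagonal
        distances.
    """
    if gm.n_samples < 2:
        raise GenotypeError("asd_matrix requires at least two samples")
    if zero_overlap not in ("error", "mean"):
        raise ValueError(f"zero_overlap must be 'error' or 'mean', got {zero_overlap!r}")

    calls = gm.calls  # (L, n)
    n = gm.n_samples
    called = calls != MISSING
    is_het = calls == HET

    values = np.zeros((n, n), dtype=float)
    overlap = np.zeros((n, n), dtype=np.int64)
    # row-at-a-time evaluation of the per-locus rule, vectorized over loci
    for i in range(n):
        ci = calls[:, i : i + 1]
        both = called[:, i : i + 1] & called[:, i + 1 :]
        same = ci == calls[:, i + 1 :]
        one_het = is_het[:, i : i + 1] ^ is_het[:, i + 1 :]
        # identical -> 0; opposite homozygotes -> 1; exactly one het -> 0.5
        d = np.where(same, 0.0, np.where(one_het, 0.5, 1.0))
        d = np.where(both, d, 0.0)
        cnt = both.sum(axis=0)
        tot = d.sum(axis=0)
        overlap[i, i + 1 :] = cnt
        with np.errstate(invalid="ignore"):
            values[i, i + 1 :] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    values = values + values.T
    overlap = overlap + overlap.T
    np.fill_diagonal(overlap, called.sum(axis=0))

    off_diag = ~np.eye(n, dtype=bool)
    no_overlap = (overlap == 0) & off_diag
    if no_overlap.any():
        if zero_overlap == "error":
            i, j = np.argwhere(no_overlap)[0]
            raise GenotypeError(
                f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no "
                "called loci (pass zero_overlap='mean' to substitute the mean)"
            )
        fill = np.nanmean(values[off_diag])
        values[no_overlap] = fill

    low = (overlap < min_overlap) & off_diag
    return DistanceMatrix(
        labels=gm.sample_ids, values=values, n_overlap=overlap, low_overlap=low
    )
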