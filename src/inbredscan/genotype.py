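"""Genotype-matrix container shared by every stage of the pipeline.

Genotypes are stored as alternate-allele dosages: 0 (hom ref), 1 (het),
2 (hom alt), with ``MISSING`` (-1) for no-calls.  Variants are kept in a
pandas table (chrom, pos, ref, alt) ordered by chromosome then position;
no operation in the package ever reorders variants within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage code for a missing genotype call.  Never imputed.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with coordinates and population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    pop_labels
        Population tag per sample (parallel to ``sample_ids``).
    variants
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; positions strictly increasing within each chromosome.
    calls
        ``(n_samples, n_variants)`` int8 array of dosages in
        {0, 1, 2, MISSING}.
    depth
        Optional per-call read depth, same shape as ``calls``.
    degraded
        Optional boolean flag per sample marking degraded (e.g. archival
        leather) samples that bypass call-rate/MAF/HWE filtering and are
        admitted to F_HOM only.
    """

    sample_ids: list[str]
    pop_labels: np.ndarray
    variants: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    degraded: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.degraded is None:
            self.degraded = np.zeros(len(self.sample_ids), dtype=bool)
        else:
            self.degraded = np.asarray(self.degraded, dtype=bool)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> list:
        """Chromosome identifiers in order of first appearance."""
        return list(dict.fromkeys(self.variants["chrom"]))

    @property
    def populations(self) -> list:
        return list(dict.fromkeys(self.pop_labels))

    def chrom_slice(self, chrom) -> slice:
        """Contiguous variant-index slice for one chromosome."""
        idx = np.flatnonzero(self.variants["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("pop_labels length mismatch")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} calls outside {{0,1,2,{MISSING}}}")
        v = self.variants
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in v.columns:
                raise ValueError(f"variants table lacks column {col!r}")
        if (v["ref"].to_numpy() == v["alt"].to_numpy()).any():
            raise ValueError("ref == alt at some variant")
        pos = v["pos"].to_numpy()
        chrom = v["chrom"].to_numpy()
        for c in dict.fromkeys(chrom):
            p = pos[chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.depth is not None and self.depth.shape != self.calls.shape:
            raise ValueError("depth shape mismatch")

    # ------------------------------------------------------------------
    def take_variants(self, mask_or_index) -> "GenotypeMatrix":
        """Subset variants, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            pop_labels=self.pop_labels.copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
            degraded=self.degraded.copy(),
        )

    def take_samples(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            pop_labels=self.pop_labels[idx].copy(),
            variants=self.variants.copy(),
            calls=self.calls[idx].copy(),
            depth=None if self.depth is None else self.depth[idx].copy(),
            degraded=self.degraded[idx].copy(),
        )

    def by_population(self) -> dict:
        """Split into one GenotypeMatrix per population label."""
        return {
            pop: self.take_samples(self.pop_labels == pop)
            for pop in self.populations
        }

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.pop_labels, other.pop_labels)
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and np.array_equal(self.calls, other.calls)
        )
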