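"""In-memory genotype container shared by every pipeline stage.

Dosages are stored as an ``int8`` array of counts of ``allele1`` per
(sample, variant), with ``-1`` marking a missing call. Variant and sample
metadata travel alongside as pandas DataFrames, mirroring the bim/fam
split of PLINK filesets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_VARIANT_COLUMNS = ["chrom", "bp", "id", "allele1", "allele2"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array of counts of ``allele1``
        in {0, 1, 2}; ``-1`` encodes a missing call.
    variants
        DataFrame with columns ``chrom, bp, id, allele1, allele2``
        (1-based physical positions).
    samples
        DataFrame with at least an ``id`` column; extra columns (e.g.
        ``population`` for reference panels) are carried through subsetting.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample metadata does not match dosage rows")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant metadata does not match dosage columns")
        missing_cols = [c for c in _VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        if "id" not in self.samples.columns:
            raise ValueError("sample table lacks an 'id' column")
        if self.samples["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosages != MISSING

    def variant_missing_rate(self) -> np.ndarray:
        # computed as missing/n directly so a rate of exactly 5% compares
        # equal to a 0.05 threshold
        return (~self.observed_mask()).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (~self.observed_mask()).mean(axis=1)

    def allele1_freq(self) -> np.ndarray:
        """Frequency of allele1 among non-missing calls, per variant.

        Monomorphic-missing variants (no calls at all) return ``nan``.
        """
        obs = self.observed_mask()
        d = np.where(obs, self.dosages, 0).astype(float)
        counts = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, d.sum(axis=0) / counts, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------------
    def subset_variants(self, index) -> "GenotypeMatrix":
        """Return a copy restricted to the given variant positions.

        ``index`` is anything numpy fancy-indexing accepts along axis 1
        (boolean mask or integer positions).
        """
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index].copy(),
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index].copy(),
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def keep_sample_ids(self, ids) -> "GenotypeMatrix":
        keep = self.samples["id"].isin(set(ids)).to_numpy()
        return self.subset_samples(keep)

    def keep_variant_ids(self, ids) -> "GenotypeMatrix":
        keep = self.variants["id"].isin(set(ids)).to_numpy()
        return self.subset_variants(keep)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.variants.copy(), self.samples.copy()
        )

    # ------------------------------------------------------------------
    def mean_imputed(self) -> np.ndarray:
        """Float dosage matrix with missing calls replaced by 2*p̂."""
        x = self.dosages.astype(float)
        p = self.allele1_freq()
        fill = np.where(np.isnan(p), 0.0, 2.0 * p)
        miss = ~self.observed_mask()
        if miss.any():
            x[miss] = np.broadcast_to(fill, x.shape)[miss]
        return x


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices that share an identical variant table."""
    if not a.variants[_VARIANT_COLUMNS].equals(b.variants[_VARIANT_COLUMNS]):
        raise ValueError("variant tables differ; align before concatenating")
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    if samples["id"].duplicated().any():
        raise ValueError("sample ids collide between the two matrices")
    return GenotypeMatrix(
        np.vstack([a.dosages, b.dosages]), a.variants.copy(), samples
    )
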