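"""Core in-memory containers shared across the pipeline.

Genotypes are held as a dense dosage matrix (individuals x variants,
values in [0, 2], NaN for missing calls) alongside a variant metadata
table. Cohort covariates and cytokine panels are plain pandas DataFrames
keyed by ``individual_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic variants dosage matrix.

    Parameters
    ----------
    dosages
        float array of shape (n_individuals, n_variants); entries in
        [0, 2], NaN marks a missing genotype.
    variants
        DataFrame with columns chrom, pos (1-based), id, ref, alt.
    individual_ids
        array of individual identifiers, length n_individuals.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length does not match dosage columns")
        if self.individual_ids is None:
            self.individual_ids = np.array(
                [f"ind_{i}" for i in range(self.dosages.shape[0])]
            )
        self.individual_ids = np.asarray(self.individual_ids)
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise ValueError("individual_ids length does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """ALT allele frequency per variant over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def select_variants(self, index) -> "GenotypeMatrix":
        """Subset by positional variant indices (or boolean mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            individual_ids=self.individual_ids.copy(),
        )

    def select_individuals(self, index) -> "GenotypeMatrix":
        """Subset by positional individual indices (or boolean mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            individual_ids=self.individual_ids[index],
        )

    def variant_index(self) -> dict:
        """Map variant id -> column position."""
        return {vid: j for j, vid in enumerate(self.variants["id"])}
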