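"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -9

_ALLOWED_BASES = set("ACGTN-")


@dataclass
class GenotypeTable:
    """Diploid microsatellite genotypes with site membership and coordinates.

    Parameters
    ----------
    individuals : pd.DataFrame
        Indexed by individual id, with columns ``site``, ``easting``,
        ``northing`` (planar metres, UTM-like).
    alleles : np.ndarray
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        sizes in base pairs; ``missing`` marks absent calls, and both copies
        of a locus are present or both missing.
    loci : list of str
        Locus names, one per column of ``alleles``.
    """

    individuals: pd.DataFrame
    alleles: np.ndarray
    loci: list[str]
    missing: int = MISSING

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.alleles.shape[0] != len(self.individuals):
            raise ValueError("allele rows do not match individual table")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("allele columns do not match locus list")
        m = self.alleles == self.missing
        if np.any(m[:, :, 0] != m[:, :, 1]):
            raise ValueError("half-missing genotype: both alleles of a locus "
                             "must be present or both missing")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def sites(self) -> pd.Series:
        return self.individuals["site"]

    def locus(self, name_or_idx) -> np.ndarray:
        """Return the (n_individuals, 2) allele-size slab for one locus."""
        idx = name_or_idx if isinstance(name_or_idx, int) else self.loci.index(name_or_idx)
        return self.alleles[:, idx, :]

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.loci == other.loci
            and self.individuals.equals(other.individuals)
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide sequences with per-haplotype carrier counts."""

    ids: list[str]
    seqs: list[str]
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        bad = set("".join(self.seqs)) - _ALLOWED_BASES
        if bad:
            raise ValueError(f"illegal characters in alignment: {sorted(bad)}")
        if self.counts is None:
            self.counts = np.ones(len(self.ids), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.ids) or np.any(self.counts < 1):
            raise ValueError("counts must align with ids and be >= 1")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())

    def matrix(self, expand: bool = False) -> np.ndarray:
        """Character matrix; with ``expand`` each haplotype is repeated by count."""
        rows = [np.frombuffer(s.encode(), dtype="S1") for s in self.seqs]
        mat = np.vstack(rows)
        if expand:
            mat = np.repeat(mat, self.counts, axis=0)
        return mat
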