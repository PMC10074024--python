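"""Per-sample template dosages from phased haplotypes.

A :class:`HaplotypePanel` stores the phased alleles of ``n`` samples at
``u`` biallelic SNPs (haploid or diploid).  For a template the *dosage*
of a sample is the fraction of its haplotype copies matching the
template: {0, 1} for haploids and {0, 0.5, 1} for diploids (0, 1 or 2
matching copies).  Dosages for a set of templates form the feature
matrix that all downstream regressions consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .templates import validate_template

__all__ = ["HaplotypePanel", "build_dosage_matrix", "template_frequency"]


@dataclass
class HaplotypePanel:
    """Phased haplotypes for a region.

    Parameters
    ----------
    haplotypes
        uint8 array of shape ``(n, ploidy, u)`` with entries in {0, 1};
        axis 1 indexes the chromosome copies of each sample.
    snp_ids
        ``u`` SNP identifiers in genomic coordinate order (positions are
        0-based, left to right, matching string indexing of templates).
    sample_ids
        Optional ``n`` sample identifiers.
    """

    haplotypes: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 3:
            raise ValueError("haplotypes must have shape (n, ploidy, u)")
        if h.size and h.max() > 1:
            raise ValueError("haplotype alleles must be 0 or 1")
        if h.shape[1] not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        self.haplotypes = h
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(h.shape[2])]
        if len(self.snp_ids) != h.shape[2]:
            raise ValueError("snp_ids length must equal the SNP count")
        if self.sample_ids is not None and len(self.sample_ids) != h.shape[0]:
            raise ValueError("sample_ids length must equal the sample count")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def ploidy(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def u(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def snp_dosage(self) -> np.ndarray:
        """Per-SNP alternative-allele dosage, shape ``(n, u)``, in [0, 1]."""
        return self.haplotypes.mean(axis=1)

    def subset(self, idx: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given sample indices (order preserved)."""
        ids = None
        if self.sample_ids is not None:
            ids = [self.sample_ids[i] for i in np.atleast_1d(idx)]
        return HaplotypePanel(self.haplotypes[idx], list(self.snp_ids), ids)

    @classmethod
    def from_strings(
        cls,
        samples: Sequence[Sequence[str]] | Sequence[str],
        snp_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> "HaplotypePanel":
        """Build a panel from per-sample haplotype strings.

        ``samples`` is a sequence of per-sample tuples of binary strings
        (one string per chromosome copy), or plain strings for haploids.
        """
        rows = []
        for s in samples:
            copies = (s,) if isinstance(s, str) else tuple(s)
            rows.append([[int(a) for a in copy] for copy in copies])
        h = np.asarray(rows, dtype=np.uint8)
        return cls(h, snp_ids or [], sample_ids)


def build_dosage_matrix(
    panel: HaplotypePanel, templates: Sequence[str]
) -> pd.DataFrame:
    """Dosage matrix of every template for every sample.

    Columns follow the input template order and are labelled with the
    template patterns; entries are match fractions over the sample's
    haplotype copies.
    """
    h = panel.haplotypes
    n, _, u = h.shape
    cols: dict[str, np.ndarray] = {}
    for t in templates:
        validate_template(t)
        if len(t) != u:
            raise ValueError(f"template {t!r} length != region size {u}")
        pos = np.array([j for j, c in enumerate(t) if c != "X"])
        vals = np.array([int(t[j]) for j in pos], dtype=np.uint8)
        match = (h[:, :, pos] == vals).all(axis=2)
        cols[t] = match.mean(axis=1)
    index = panel.sample_ids if panel.sample_ids is not None else range(n)
    return pd.DataFrame(cols, index=index, columns=list(templates), dtype=float)


def template_frequency(dosages: pd.DataFrame, column: str) -> float:
    """Population frequency of a template: mean dosage of its column."""
    return float(dosages[column].mean())
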