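"""Marker quality control: the filter cascade and genotype-class masking.

Three analysis stages consume three nested marker sets:

1. :func:`filter_markers` — drop markers with call rate < 95%, monomorphic
   markers, and markers with minor allele frequency (MAF) < 0.05, in that
   order (clustering set);
2. :func:`mask_small_genotype_classes` — set to missing every entry of a
   genotype class observed in fewer than 10 individuals, then re-apply the
   filter cascade (association set);
3. :func:`complete_case_markers` — keep only markers with no missing calls
   (PCA set).

All boundaries are strict readings of the inequalities: a call rate of
exactly 95%, a MAF of exactly 0.05 and a class of exactly 10 individuals are
all kept.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import GenotypeDataset


@dataclass
class QcReport:
    """Per-rule removal counts for one QC stage."""

    stage: str
    input_markers: int
    removed_call_rate: int = 0
    removed_monomorphic: int = 0
    removed_maf: int = 0
    masked_entries: int = 0
    survivors: int = 0

    def __post_init__(self) -> None:
        pass

    def validate(self) -> None:
        removed = self.removed_call_rate + self.removed_monomorphic + self.removed_maf
        if self.survivors + removed != self.input_markers:
            raise ValueError("QcReport counts inconsistent: survivors + removed != input")

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def compute_maf(
    n_aa: int, n_ab: int, n_bb: int, allele_a: str = "A", allele_b: str = "B"
) -> tuple[str, float]:
    """Minor allele and its frequency from genotype-class counts.

    ``n_aa``/``n_ab``/``n_bb`` count individuals homozygous for allele *a*,
    heterozygous, and homozygous for allele *b*; missing individuals must
    already be excluded.  MAF = (2·n_minor_hom + n_het) / (2·n_total) ≤ 0.5.
    An exact 50/50 tie is labelled with the lexicographically smaller allele.
    """
    n_total = n_aa + n_ab + n_bb
    if n_total == 0:
        raise ValueError("no genotyped individuals: all class counts are zero")
    freq_a = (2 * n_aa + n_ab) / (2 * n_total)
    if freq_a < 0.5:
        return allele_a, freq_a
    if freq_a > 0.5:
        return allele_b, 1.0 - freq_a
    return min(allele_a, allele_b), 0.5


def genotype_class_counts(ds: GenotypeDataset) -> np.ndarray:
    """(n_markers, 3) counts of dosage classes 0/1/2, ignoring missing."""
    counts = np.empty((ds.n_markers, 3), dtype=np.int64)
    for c in (0, 1, 2):
        counts[:, c] = (ds.dosage == c).sum(axis=0)
    return counts


def marker_maf(ds: GenotypeDataset) -> np.ndarray:
    """Per-marker MAF (folded frequency of the counted allele), NaN if all missing."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(ds.dosage, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_markers(
    ds: GenotypeDataset, call_rate_min: float = 0.95, maf_min: float = 0.05
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the three-rule filter cascade in its fixed order.

    Rule 1 removes markers whose call rate is strictly below
    ``call_rate_min``; rule 2 removes markers monomorphic among non-missing
    calls; rule 3 removes markers with MAF strictly below ``maf_min``.
    Per-rule counts depend on the order and are reported for the order run.
    An empty survivor set is legal.
    """
    if ds.n_markers == 0:
        raise ValueError("dataset has no markers")
    report = QcReport(stage="filter", input_markers=ds.n_markers)

    call_rate = 1.0 - np.isnan(ds.dosage).mean(axis=0)
    keep1 = call_rate >= call_rate_min
    report.removed_call_rate = int((~keep1).sum())

    counts = genotype_class_counts(ds)
    poly = (counts > 0).sum(axis=1) >= 2
    keep2 = keep1 & poly
    report.removed_monomorphic = int((keep1 & ~poly).sum())

    maf = marker_maf(ds)
    with np.errstate(invalid="ignore"):
        keep3 = keep2 & (maf >= maf_min)
    report.removed_maf = int((keep2 & ~(maf >= maf_min)).sum())

    report.survivors = int(keep3.sum())
    report.validate()
    return ds.subset_markers(keep3), report


def mask_small_genotype_classes(
    ds: GenotypeDataset,
    min_class: int = 10,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
) -> tuple[GenotypeDataset, QcReport]:
    """Mask rare genotype classes to missing, then re-run the filter cascade.

    For every marker, each dosage class (0, 1 or 2) observed in fewer than
    ``min_class`` individuals (strictly; a class of exactly ``min_class`` is
    kept) has its entries set to missing — this guards the association scan
    against spurious hits driven by a handful of birds.  Markers are then
    re-checked with :func:`filter_markers` under the same thresholds.
    """
    dosage = ds.dosage.copy()
    counts = genotype_class_counts(ds)
    masked = 0
    for c in (0, 1, 2):
        small = (counts[:, c] > 0) & (counts[:, c] < min_class)
        if small.any():
            cells = (dosage[:, small] == c)
            masked += int(cells.sum())
            block = dosage[:, small]
            block[cells] = np.nan
            dosage[:, small] = block
    masked_ds = GenotypeDataset(dosage, ds.markers.copy(), ds.samples.copy())
    out, report = filter_markers(masked_ds, call_rate_min=call_rate_min, maf_min=maf_min)
    report.stage = "mask_small_classes"
    report.masked_entries = masked
    return out, report


def complete_case_markers(ds: GenotypeDataset) -> tuple[GenotypeDataset, QcReport]:
    """Keep only markers with zero missing entries (the PCA marker set)."""
    keep = ~np.isnan(ds.dosage).any(axis=0)
    report = QcReport(
        stage="complete_case",
        input_markers=ds.n_markers,
        removed_call_rate=int((~keep).sum()),
        survivors=int(keep.sum()),
    )
    report.validate()
    return ds.subset_markers(keep), report
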