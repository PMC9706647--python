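"""Readers and writers for every on-disk representation the pipeline touches.

Genotypes live in memory as a sample x marker dosage matrix counting copies
of the dataset-wide minor allele (0/1/2, ``NaN`` for a missing call), with a
marker map (chromosome, 1-based bp position, alleles) and per-sample metadata
(breed, type, sex).  Genomic coordinates are 1-based inclusive everywhere
inside the package; BED export converts to 0-based half-open exactly once.

No statistics live here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait column names, with units embedded.
TRAITS = [
    "wing_length_cm",
    "shank_length_cm",
    "shank_thickness_mm",
    "keel_length_cm",
    "body_weight_kg",
]

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "breed", "type", "sex"]


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class GenotypeDataset:
    """Biallelic SNP dosages plus marker map and sample metadata.

    Attributes
    ----------
    dosage : ndarray of float, shape (n_samples, n_markers)
        Copies of the dataset-wide minor allele; ``NaN`` marks a missing call.
    markers : DataFrame
        Columns ``marker_id, chromosome, position_bp, allele_a, allele_b,
        minor_allele`` in matrix column order.
    samples : DataFrame
        Columns ``sample_id, breed, type, sex`` in matrix row order.
    """

    dosage: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be a 2-D sample x marker matrix")
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        legal = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not legal.all():
            bad = self.dosage[~legal][0]
            raise DataError(f"illegal dosage value {bad!r}; expected 0, 1, 2 or missing")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise DataError(f"duplicated sample_id {dup!r}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()].iloc[0]
            raise DataError(f"duplicated marker_id {dup!r}")
        # breed -> type must be a function
        bt = self.samples.groupby("breed", observed=True)["type"].nunique()
        if (bt > 1).any():
            raise DataError(f"breed {bt[bt > 1].index[0]!r} maps to more than one type")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to markers where ``keep`` is True (or an index array)."""
        keep = np.asarray(keep)
        return GenotypeDataset(
            dosage=self.dosage[:, keep].copy(),
            markers=self.markers.iloc[np.arange(self.n_markers)[keep] if keep.dtype == bool else keep]
            .reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.dosage.copy(), self.markers.copy(), self.samples.copy())


@dataclass
class TraitTable:
    """Per-sample raw (and, after sex correction, corrected) trait values.

    ``raw`` and ``corrected`` are wide DataFrames indexed by ``sample_id``
    with one column per trait, in trait units.  ``corrected`` is ``None``
    until the phenotype-correction stage has run.
    """

    raw: pd.DataFrame
    corrected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.raw.index.duplicated().any():
            raise DataError(f"duplicated sample_id {self.raw.index[self.raw.index.duplicated()][0]!r}")
        if self.corrected is not None and not self.corrected.index.isin(self.raw.index).all():
            raise DataError("corrected values present for samples absent from raw")

    @property
    def traits(self) -> list[str]:
        return list(self.raw.columns)


@dataclass
class GenomicRegion:
    """A merged significant interval (1-based inclusive bounds).

    ``source`` identifies the scan that produced it, e.g. ``"assoc:keel_length_cm"``
    or ``"pca:PC1"``.  ``stats`` carries the top marker's statistics for reporting.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    marker_ids: list[str]
    top_marker: str
    source: str
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise DataError(f"region start {self.start_bp} > end {self.end_bp}")
        if self.top_marker not in self.marker_ids:
            raise DataError("top marker must be a region member")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# genotype I/O


def orient_to_minor(dosage: np.ndarray, markers: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosages so they count the dataset-wide minor allele.

    On input, dosage counts copies of ``allele_b`` (e.g. the VCF ALT allele).
    Markers whose counted-allele frequency exceeds 0.5 are flipped; at an
    exact tie the lexicographically smaller allele is counted.  A
    ``minor_allele`` column is added to the marker map.
    """
    dosage = np.asarray(dosage, dtype=float)
    with np.errstate(invalid="ignore"):
        freq_b = np.nanmean(dosage, axis=0) / 2.0
    freq_b = np.where(np.isnan(freq_b), 0.0, freq_b)
    a = markers["allele_a"].to_numpy()
    b = markers["allele_b"].to_numpy()
    flip = (freq_b > 0.5) | ((freq_b == 0.5) & (a < b))
    out = dosage.copy()
    out[:, flip] = 2.0 - out[:, flip]
    markers = markers.copy()
    markers["minor_allele"] = np.where(flip, a, b)
    return out, markers


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"sample metadata {path} lacks columns {sorted(missing)}")
    return df[SAMPLE_COLUMNS]


def _read_vcf(path: Path, samples_path: str | Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta = read_sample_metadata(samples_path).set_index("sample_id")
    absent = [s for s in sample_ids if s not in meta.index]
    if absent:
        raise DataError(f"sample metadata missing listed sample(s): {absent}")
    rows, recs = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}
    for v in vcf:
        if len(v.ALT) != 1:
            raise DataError(f"multi-allelic record rejected: {v.ID or f'{v.CHROM}:{v.POS}'}")
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise DataError(f"non-SNP record rejected: {v.ID or f'{v.CHROM}:{v.POS}'}")
        rows.append([code[g] for g in v.gt_types])
        recs.append((v.ID or f"{v.CHROM}_{v.POS}", str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    if not recs:
        raise DataError(f"no variant records in {path}")
    dosage = np.array(rows, dtype=float).T  # samples x markers
    markers = pd.DataFrame(recs, columns=MARKER_COLUMNS)
    dosage, markers = orient_to_minor(dosage, markers)
    samples = meta.loc[sample_ids].reset_index()[SAMPLE_COLUMNS]
    return GenotypeDataset(dosage, markers, samples)


def _read_dosage_table(path: Path, markers_path: str | Path, samples_path: str | Path) -> GenotypeDataset:
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    markers = pd.read_csv(markers_path, sep="\t", dtype={"chromosome": str})
    missing_cols = set(MARKER_COLUMNS) - set(markers.columns)
    if missing_cols:
        raise DataError(f"marker map {markers_path} lacks columns {sorted(missing_cols)}")
    if table.shape[1] != len(markers):
        raise DataError(
            f"dosage table has {table.shape[1]} marker columns but marker map "
            f"{markers_path} has {len(markers)} rows"
        )
    if list(table.columns) != list(markers["marker_id"]):
        raise DataError("dosage table column order does not match marker map order")
    meta = read_sample_metadata(samples_path).set_index("sample_id")
    absent = [s for s in table.index if s not in meta.index]
    if absent:
        raise DataError(f"sample metadata missing listed sample(s): {absent}")
    dosage = table.to_numpy(dtype=float)
    if "minor_allele" not in markers.columns:
        dosage, markers = orient_to_minor(dosage, markers)
    samples = meta.loc[table.index].reset_index()[SAMPLE_COLUMNS]
    return GenotypeDataset(dosage, markers, samples)


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    *,
    markers_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> GenotypeDataset:
    """Load genotypes from VCF or a TSV dosage table.

    Parameters
    ----------
    path
        VCF file (biallelic SNP records only) or dosage table (TSV, one row
        per sample, one column per marker, first column ``sample_id``).
    format
        ``"vcf"`` or ``"dosage_table"``.
    markers_path
        Marker map TSV (required for ``dosage_table``): columns
        ``marker_id, chromosome, position_bp, allele_a, allele_b``.
    samples_path
        Sample metadata TSV (always required): columns
        ``sample_id, breed, type, sex``.

    Dosages are re-oriented to count the dataset-wide minor allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if samples_path is None:
        raise DataError("samples_path (sample metadata TSV) is required")
    if format == "vcf":
        return _read_vcf(path, samples_path)
    if format == "dosage_table":
        if markers_path is None:
            raise DataError("markers_path is required for dosage_table format")
        return _read_dosage_table(path, markers_path, samples_path)
    raise DataError(f"unknown genotype format {format!r}")


def write_genotypes(ds: GenotypeDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a dataset as ``<prefix>.dosage.tsv``, ``<prefix>.markers.tsv``,
    ``<prefix>.samples.tsv``; returns the paths.  Round-trips exactly through
    :func:`read_genotypes` with ``format="dosage_table"``."""
    prefix = Path(prefix)
    paths = {
        "dosage": prefix.with_suffix(".dosage.tsv"),
        "markers": prefix.with_suffix(".markers.tsv"),
        "samples": prefix.with_suffix(".samples.tsv"),
    }
    table = pd.DataFrame(ds.dosage, index=ds.samples["sample_id"], columns=ds.markers["marker_id"])
    # integer dosages; NA for missing
    table = table.astype("Int64")
    table.to_csv(paths["dosage"], sep="\t", na_rep="NA")
    ds.markers.to_csv(paths["markers"], sep="\t", index=False)
    ds.samples[SAMPLE_COLUMNS].to_csv(paths["samples"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# phenotype I/O


def read_phenotypes(path: str | Path) -> TraitTable:
    """Read a phenotype TSV (``sample_id``, optional ``sex``, one column per trait).

    Non-numeric cells become missing.  Trait columns absent from the file are
    skipped with a warning; unknown columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise DataError(f"{path} lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise DataError(f"duplicated sample_id {dup!r} in {path}")
    present = [t for t in TRAITS if t in df.columns]
    absent = [t for t in TRAITS if t not in df.columns]
    if absent:
        logger.warning("phenotype file %s missing trait column(s): %s", path, ", ".join(absent))
    raw = df.set_index("sample_id")[present].apply(pd.to_numeric, errors="coerce")
    return TraitTable(raw=raw)


def write_phenotypes(tt: TraitTable, path: str | Path) -> None:
    out = tt.raw.copy()
    out.to_csv(path, sep="\t", na_rep="NA")
    if tt.corrected is not None:
        p = Path(path)
        tt.corrected.to_csv(p.with_name(p.stem + ".corrected" + p.suffix), sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# region / interval I/O


def write_regions(regions: list[GenomicRegion], path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write merged regions as a BED file (0-based half-open) plus a TSV
    sidecar with top-marker statistics.

    Regions are sorted by chromosome then start.  Internal 1-based inclusive
    bounds ``[start, end]`` become the BED interval ``start-1, end``.
    """
    path = Path(path)
    regions = sorted(regions, key=lambda r: (r.chromosome, r.start_bp, r.end_bp))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.top_marker}\n")
    if tsv_path is None:
        tsv_path = path.with_suffix(".tsv")
    stat_keys: list[str] = []
    for r in regions:
        for k in r.stats:
            if k not in stat_keys:
                stat_keys.append(k)
    rows = []
    for r in regions:
        row = {
            "chromosome": r.chromosome,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "n_markers": len(r.marker_ids),
            "top_marker": r.top_marker,
            "source": r.source,
        }
        row.update({k: r.stats.get(k, "") for k in stat_keys})
        rows.append(row)
    cols = ["chromosome", "start_bp", "end_bp", "n_markers", "top_marker", "source"] + stat_keys
    pd.DataFrame(rows, columns=cols).to_csv(tsv_path, sep="\t", index=False)


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a labelled BED file of known intervals (e.g. published QTL).

    Returns a DataFrame with 1-based inclusive ``start_bp``/``end_bp`` and a
    ``label`` column (BED column 4; empty if absent).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start0 < 0 or end <= start0:
                raise DataError(f"{path}:{lineno}: invalid interval [{start0}, {end})")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((str(parts[0]), start0 + 1, end, label))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "label"])
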