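"""Per-marker association scan with a breed covariate, FDR control, genomic
inflation, LD estimation and LD-based region merging.

The significance test per marker compares the full linear model
Y' = mu + Breed + SNP + e (SNP as a genotype-class factor) against the
reduced model Y' = mu + Breed + e with an F test; the reported effect size
beta is the coefficient from a second fit replacing the factor with the
0/1/2 minor-allele dosage, so beta is the additive effect per copy of the
minor allele.  Variance explained is
100 * (RSS_reduced - RSS_full) / RSS_reduced from the factor fit.

P-values are adjusted per trait with the Benjamini–Hochberg step-up
procedure; calibration is summarized by the genomic inflation factor
(median observed chi-square quantile over the 1-df null median).  Adjacent
significant markers on a chromosome are merged into one region when their
EM-estimated linkage disequilibrium exceeds r^2 = 0.5.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import GenomicRegion, GenotypeDataset, TraitTable

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with one degree of freedom.
CHI2_1DF_MEDIAN = stats.chi2.ppf(0.5, df=1)


@dataclass
class AssocRecord:
    """One marker x trait association result."""

    marker_id: str
    trait: str
    p_value: float
    q_value: float = np.nan
    beta: float = np.nan
    se: float = np.nan
    var_explained_pct: float = np.nan
    n_class0: int = 0
    n_class1: int = 0
    n_class2: int = 0
    maf: float = np.nan
    skipped: str | None = None


@dataclass
class ScanSummary:
    trait: str
    n_markers: int
    inflation_lambda: float
    n_significant_05: int
    n_significant_01: int


def _design(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped) for a label vector."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def fit_marker(yprime: np.ndarray, breed: np.ndarray, g: np.ndarray,
               marker_id: str = "", trait: str = "") -> AssocRecord:
    """Fit one marker: F test of the genotype factor over breed, additive beta.

    Parameters
    ----------
    yprime : sex-corrected trait values (may contain NaN)
    breed : per-sample breed labels
    g : dosages in {0, 1, 2, NaN}

    Only pairwise-complete observations enter the fit.  Markers with a single
    observed genotype class are skipped; markers whose genotype is constant
    within every breed are collinear with the breed factor and flagged
    (p undefined).
    """
    yprime = np.asarray(yprime, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = np.isfinite(yprime) & np.isfinite(g)
    y = yprime[mask]
    gg = g[mask]
    bb = np.asarray(breed)[mask]
    n = len(y)
    rec = AssocRecord(marker_id=marker_id, trait=trait, p_value=np.nan)
    rec.n_class0 = int((gg == 0).sum())
    rec.n_class1 = int((gg == 1).sum())
    rec.n_class2 = int((gg == 2).sum())
    freq = gg.mean() / 2.0 if n else np.nan
    rec.maf = float(min(freq, 1 - freq)) if n else np.nan
    classes = np.unique(gg)
    if len(classes) < 2:
        rec.skipped = "single genotype class"
        return rec
    if len(np.unique(bb)) < 2:
        rec.skipped = "single breed"
        return rec

    X_red = np.column_stack([np.ones(n), _design(bb)])
    G = _design(gg)  # k-1 class indicator columns
    X_full = np.column_stack([X_red, G])
    rank_red = np.linalg.matrix_rank(X_red)
    rank_full = np.linalg.matrix_rank(X_full)
    df_g = rank_full - rank_red
    if df_g == 0:
        rec.skipped = "genotype collinear with breed"
        return rec

    beta_r, rss_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    beta_f, rss_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_r = float(rss_r[0]) if len(rss_r) else float(np.sum((y - X_red @ beta_r) ** 2))
    rss_f = float(rss_f[0]) if len(rss_f) else float(np.sum((y - X_full @ beta_f) ** 2))
    df_resid = n - rank_full
    if df_resid <= 0 or rss_f <= 0:
        rec.skipped = "saturated model"
        return rec
    F = ((rss_r - rss_f) / df_g) / (rss_f / df_resid)
    rec.p_value = float(stats.f.sf(F, df_g, df_resid))
    rec.var_explained_pct = float(100.0 * (rss_r - rss_f) / rss_r) if rss_r > 0 else np.nan

    # additive fit: beta per minor-allele copy
    X_add = np.column_stack([X_red, gg])
    rank_add = np.linalg.matrix_rank(X_add)
    if rank_add > rank_red:
        coef, rss_a, *_ = np.linalg.lstsq(X_add, y, rcond=None)
        rss_a = float(rss_a[0]) if len(rss_a) else float(np.sum((y - X_add @ coef) ** 2))
        df_a = n - rank_add
        if df_a > 0:
            sigma2 = rss_a / df_a
            xtx_inv = np.linalg.pinv(X_add.T @ X_add)
            rec.beta = float(coef[-1])
            rec.se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return rec


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    NaN inputs yield NaN outputs and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def genomic_inflation(p: np.ndarray, literal: bool = False) -> float:
    """Genomic inflation factor lambda from a vector of p-values.

    Default: transform p to 1-df chi-square quantiles and divide the observed
    median by the null median (0.4549...).  ``literal=True`` instead divides
    the median p-value by its null expectation 0.5 (an alternative literal
    reading of the same recipe).
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if literal:
        return float(np.median(p) / 0.5)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(g1: np.ndarray, g2: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> float:
    """LD r^2 between two markers from unphased dosages via EM.

    Haplotype frequencies are estimated by expectation-maximization
    (initialized at linkage equilibrium; double heterozygotes are the only
    phase-ambiguous class); r^2 = D^2 / (pA pa pB pb).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = np.isfinite(g1) & np.isfinite(g2)
    x, y = g1[mask], g2[mask]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairwise-complete samples")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("r^2 undefined for a monomorphic marker")
    # 3x3 joint genotype counts; index = copies of the counted allele
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((x == i) & (y == j))
    pA = x.mean() / 2.0
    pB = y.mean() / 2.0
    # haplotype frequencies hAB, hAb, haB, hab
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_dh = counts[1, 1]  # double heterozygotes: the only phase-ambiguous class
    # haplotypes contributed by each unambiguous genotype (i, j)
    contrib = {
        (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2),
    }
    base = np.zeros(4)
    for (i, j), hap in contrib.items():
        base += counts[i, j] * np.asarray(hap, dtype=float)
    for _ in range(max_iter):
        denom = h[0] * h[3] + h[1] * h[2]
        r_frac = 0.5 if denom == 0 else h[0] * h[3] / denom
        hap_counts = base + n_dh * np.array([r_frac, 1 - r_frac, 1 - r_frac, r_frac])
        h_new = hap_counts / (2.0 * n)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    pA = h[0] + h[1]
    pB = h[0] + h[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise ValueError("r^2 undefined: an allele was driven to fixation")
    D = h[0] - pA * pB
    return float(np.clip(D * D / denom, 0.0, 1.0))


def merge_ld_regions(
    sig: pd.DataFrame, ds: GenotypeDataset, r2_min: float = 0.5, source: str = "assoc"
) -> list[GenomicRegion]:
    """Merge consecutive significant markers in strong LD into regions.

    ``sig`` needs columns ``marker_id, chromosome, position_bp, p_value``.
    Within a chromosome, each consecutive pair of significant markers joins
    the same region iff their r^2 strictly exceeds ``r2_min``; regions are
    the transitive closure of these adjacent joins.  The top marker is the
    lowest raw p (ties: lowest position).
    """
    col = {mid: i for i, mid in enumerate(ds.markers["marker_id"])}
    regions: list[GenomicRegion] = []
    sig = sig.sort_values(["chromosome", "position_bp"], kind="mergesort")
    for chrom, grp in sig.groupby("chromosome", sort=False):
        grp = grp.reset_index(drop=True)
        current: list[int] = [0]
        chains: list[list[int]] = []
        for i in range(1, len(grp)):
            a = ds.dosage[:, col[grp.loc[i - 1, "marker_id"]]]
            b = ds.dosage[:, col[grp.loc[i, "marker_id"]]]
            try:
                r2 = ld_r2(a, b)
            except ValueError:
                r2 = 0.0
            if r2 > r2_min:
                current.append(i)
            else:
                chains.append(current)
                current = [i]
        chains.append(current)
        for chain in chains:
            sub = grp.loc[chain]
            top = sub.sort_values(["p_value", "position_bp"], kind="mergesort").iloc[0]
            regions.append(
                GenomicRegion(
                    chromosome=str(chrom),
                    start_bp=int(sub["position_bp"].min()),
                    end_bp=int(sub["position_bp"].max()),
                    marker_ids=list(sub["marker_id"]),
                    top_marker=str(top["marker_id"]),
                    source=source,
                    stats={k: top[k] for k in sub.columns if k not in
                           ("marker_id", "chromosome", "position_bp")},
                )
            )
    return regions


# ---------------------------------------------------------------------------
# whole-trait scan


def assoc_scan(
    ds: GenotypeDataset, traits: TraitTable, trait: str
) -> tuple[pd.DataFrame, ScanSummary]:
    """Fit every marker for one trait; attach BH-FDR q-values and lambda.

    Returns the per-marker table (Manhattan-ready: chromosome, position,
    p, q, beta, SE, Var%, class counts, MAF) and a :class:`ScanSummary`.
    """
    if traits.corrected is None:
        raise ValueError("run pheno.sex_correct before the association scan")
    y = traits.corrected[trait].reindex(ds.samples["sample_id"]).to_numpy()
    breed = ds.samples["breed"].to_numpy()
    records = [
        fit_marker(y, breed, ds.dosage[:, j],
                   marker_id=ds.markers["marker_id"].iloc[j], trait=trait)
        for j in range(ds.n_markers)
    ]
    df = pd.DataFrame([vars(r) for r in records])
    df.insert(1, "chromosome", ds.markers["chromosome"].to_numpy())
    df.insert(2, "position_bp", ds.markers["position_bp"].to_numpy())
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    valid = df["p_value"].dropna()
    lam = genomic_inflation(valid.to_numpy()) if len(valid) else np.nan
    summary = ScanSummary(
        trait=trait,
        n_markers=int(len(valid)),
        inflation_lambda=lam,
        n_significant_05=int((df["q_value"] < 0.05).sum()),
        n_significant_01=int((df["q_value"] < 0.01).sum()),
    )
    return df, summary
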