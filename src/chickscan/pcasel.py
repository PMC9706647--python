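"""PCA of the complete-case genotype matrix and the signed-contribution
significance scan.

PCA is the singular value decomposition of the column-centered (optionally
scaled) dosage matrix; component standard deviations use the n-1 denominator.
For a chosen component, each marker's *variable correlation* is its loading
times the component SD, its cos^2 is the squared variable correlation, and
its *contribution* is cos^2 as a percentage of the component total — so
contributions over all markers sum to 100.

The selection statistic multiplies the sign of the marker's rotation entry
by its percentage contribution ("pcaDObs").  Treating the empirical
distribution of this statistic as Normal(mean, SD), each marker receives
p = 2 * P[X > |pcaDObs|] (capped at 1), Bonferroni-adjusted over the markers
entering the PCA; markers with adjusted p < 0.05 are selected and merged
into regions when within 2 Mb of each other.  Component scores can also be
rank-correlated with the measured traits (Spearman).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GenomicRegion, GenotypeDataset, TraitTable


@dataclass
class PcaModel:
    """Scores, rotation (unit-norm loading columns), component SDs."""

    sample_ids: list[str]
    marker_ids: list[str]
    scores: np.ndarray     # n_samples x n_components
    rotation: np.ndarray   # n_markers x n_components
    sdev: np.ndarray       # per-component SD (n-1 denominator)
    explained: np.ndarray  # fraction of total variance per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component_index(self, component: int) -> int:
        """1-based component number -> column index, with range check."""
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component {component} out of range 1..{self.n_components}")
        return component - 1


def run_pca(ds: GenotypeDataset, scale: bool = False) -> PcaModel:
    """SVD-based PCA of the centered dosage matrix (complete cases only).

    Equivalent to the standard centered, unscaled PCA of a sample x marker
    matrix: scores are the sample coordinates, the rotation columns are the
    orthonormal marker loadings, and sdev^2 are the component variances with
    an n-1 denominator.  Missing entries and constant marker columns are
    errors — quality control must remove them first.
    """
    X = ds.dosage
    if np.isnan(X).any():
        raise ValueError("PCA requires complete cases; run qc.complete_case_markers first")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 markers")
    col_var = X.var(axis=0)
    if (col_var == 0).any():
        j = int(np.argmax(col_var == 0))
        raise ValueError(f"constant marker column {ds.markers['marker_id'].iloc[j]!r}; "
                         "monomorphic markers must be removed by QC")
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    sdev = S / np.sqrt(n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    return PcaModel(
        sample_ids=list(ds.samples["sample_id"]),
        marker_ids=list(ds.markers["marker_id"]),
        scores=U * S,
        rotation=Vt.T,
        sdev=sdev,
        explained=sdev**2 / total_var,
    )


def contributions(model: PcaModel, component: int = 1) -> pd.DataFrame:
    """Per-marker variable correlation, cos^2 and percentage contribution.

    varcor = loading * component SD; cos^2 = varcor^2; contribution =
    100 * cos^2 / sum(cos^2).  Contributions sum to 100 over all markers.
    """
    c = model.component_index(component)
    if model.sdev[c] == 0:
        raise ValueError(f"component {component} has zero standard deviation")
    varcor = model.rotation[:, c] * model.sdev[c]
    cos2 = varcor**2
    return pd.DataFrame(
        {
            "marker_id": model.marker_ids,
            "varcor": varcor,
            "cos2": cos2,
            "contribution": 100.0 * cos2 / cos2.sum(),
        }
    )


def pcadobs_significance(
    records: pd.DataFrame,
    model: PcaModel,
    component: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Attach the signed contribution statistic and its normal-model p-values.

    pcaDObs_i = sign(rotation_i) * contribution_i (sign(0) counts as +).  With
    mu and sigma the sample mean and SD (n-1) of the pcaDObs vector,
    raw p_i = min(1, 2 * P[Normal(mu, sigma) > |pcaDObs_i|]) and
    P_Bonf_i = min(1, raw p_i * M) with M the number of markers scanned.
    ``selected`` marks P_Bonf < ``alpha``.
    """
    c = model.component_index(component)
    if len(records) < 2:
        raise ValueError("need at least 2 markers")
    sign = np.where(model.rotation[:, c] >= 0, 1.0, -1.0)
    pcadobs = sign * records["contribution"].to_numpy()
    # The SVD fixes component orientation only up to sign, so the normal model
    # is fitted under the canonical orientation with nonnegative mean: p-values
    # and the selected set do not depend on the arbitrary sign choice.
    mu = abs(pcadobs.mean())
    sd = pcadobs.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate pcaDObs distribution (zero spread)")
    raw_p = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(pcadobs), loc=mu, scale=sd))
    m = len(records)
    out = records.copy()
    out["pcadobs"] = pcadobs
    out["p_value"] = raw_p
    out["p_bonf"] = np.minimum(1.0, raw_p * m)
    out["selected"] = out["p_bonf"] < alpha
    return out


def merge_distance_regions(
    selected: pd.DataFrame, max_gap: int = 2_000_000, source: str = "pca:PC1"
) -> list[GenomicRegion]:
    """Chain selected markers within ``max_gap`` bp of each other into regions.

    ``selected`` needs columns ``marker_id, chromosome, position_bp, p_value,
    pcadobs``.  A marker joins the current region iff it sits on the same
    chromosome no more than ``max_gap`` bp after the previous member; region
    ends may therefore lie further apart than ``max_gap``.  The top marker is
    the smallest raw p (ties: largest |pcaDObs|, then lowest position).
    """
    regions: list[GenomicRegion] = []
    sel = selected.sort_values(["chromosome", "position_bp"], kind="mergesort")
    for chrom, grp in sel.groupby("chromosome", sort=False):
        grp = grp.reset_index(drop=True)
        chains: list[list[int]] = [[0]]
        for i in range(1, len(grp)):
            if grp.loc[i, "position_bp"] - grp.loc[i - 1, "position_bp"] <= max_gap:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            sub = grp.loc[chain].copy()
            sub["_absd"] = -sub["pcadobs"].abs()
            top = sub.sort_values(["p_value", "_absd", "position_bp"], kind="mergesort").iloc[0]
            regions.append(
                GenomicRegion(
                    chromosome=str(chrom),
                    start_bp=int(sub["position_bp"].min()),
                    end_bp=int(sub["position_bp"].max()),
                    marker_ids=list(sub["marker_id"]),
                    top_marker=str(top["marker_id"]),
                    source=source,
                    stats={k: top[k] for k in ("p_value", "p_bonf", "pcadobs", "contribution")
                           if k in sub.columns},
                )
            )
    return regions


def pc_trait_correlation(
    model: PcaModel, component: int, traits: TraitTable
) -> pd.DataFrame:
    """Spearman rank correlation of component scores with each raw trait."""
    c = model.component_index(component)
    scores = pd.Series(model.scores[:, c], index=model.sample_ids)
    rows = []
    for trait in traits.raw.columns:
        y = traits.raw[trait].reindex(scores.index)
        ok = y.notna()
        if ok.sum() < 3 or y[ok].nunique() < 2:
            rows.append((trait, np.nan, np.nan, int(ok.sum())))
            continue
        rho, p = stats.spearmanr(scores[ok], y[ok])
        rows.append((trait, float(rho), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["trait", "spearman_rho", "p_value", "n"])
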