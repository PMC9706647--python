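"""Phenotype preparation: within-breed sex correction and type comparisons.

Before the association scan each trait is corrected for sex differences
within each breed with the one-factor linear model Y = mu + Sex + e fitted
per breed; the corrected value is the fitted intercept (the reference-sex
mean) plus the residual, so males and females end up on a common scale while
between-breed differences are preserved for the Breed term of the scan.

Type differences per trait and sex are tested with a two-sample two-tailed
Student's t test (pooled variance by default, Welch optionally) at a
Bonferroni family threshold of alpha / (n_traits * n_sexes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class TypeComparison:
    trait: str
    sex: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    t_statistic: float
    p_value: float
    threshold: float
    significant: bool


def sex_correct(
    traits: TraitTable, samples: pd.DataFrame, reference_sex: str = "female"
) -> TraitTable:
    """Per breed x trait OLS of Y on sex; corrected Y' = intercept + residual.

    With a single binary factor this closed form is exact: Y' equals the raw
    value minus its own breed-sex mean plus the breed's reference-sex mean.
    Breeds containing a single sex are passed through unchanged (the sex
    effect is inestimable) with a warning.  Missing raw values stay missing.
    """
    meta = samples.set_index("sample_id")
    common = traits.raw.index.intersection(meta.index)
    raw = traits.raw.loc[common]
    breed = meta.loc[common, "breed"]
    sex = meta.loc[common, "sex"]
    corrected = raw.copy()
    for b in breed.unique():
        in_breed = breed == b
        sexes = sex[in_breed].unique()
        if len(sexes) < 2:
            logger.warning("breed %s has a single sex; sex correction skipped for it", b)
            continue
        if reference_sex not in sexes:
            raise ValueError(f"reference sex {reference_sex!r} absent from breed {b!r}")
        for trait in raw.columns:
            y = raw.loc[in_breed, trait]
            group_mean = y.groupby(sex[in_breed]).transform("mean")
            ref_mean = y[sex[in_breed] == reference_sex].mean()
            corrected.loc[in_breed, trait] = y - group_mean + ref_mean
    return TraitTable(raw=traits.raw, corrected=corrected)


def compare_types(
    traits: TraitTable,
    samples: pd.DataFrame,
    alpha_family: float = 0.05,
    welch: bool = False,
) -> list[TypeComparison]:
    """Student's t test of type means per trait x sex, Bonferroni-thresholded.

    The significance threshold is ``alpha_family / (n_traits * n_sexes)``
    (0.005 for five traits and two sexes at family alpha 0.05).  Groups with
    fewer than two observations are skipped with a warning.
    """
    meta = samples.set_index("sample_id")
    common = traits.raw.index.intersection(meta.index)
    raw = traits.raw.loc[common]
    types = sorted(meta.loc[common, "type"].unique())
    sexes = sorted(meta.loc[common, "sex"].unique())
    if len(types) != 2:
        raise ValueError(f"expected exactly 2 types, found {types}")
    threshold = alpha_family / (len(raw.columns) * len(sexes))
    out: list[TypeComparison] = []
    for trait in raw.columns:
        for sx in sexes:
            sel = meta.loc[common, "sex"] == sx
            g1 = raw.loc[sel & (meta.loc[common, "type"] == types[0]), trait].dropna()
            g2 = raw.loc[sel & (meta.loc[common, "type"] == types[1]), trait].dropna()
            if len(g1) < 2 or len(g2) < 2:
                logger.warning("skipping %s/%s: a type group has < 2 observations", trait, sx)
                continue
            t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
            out.append(
                TypeComparison(
                    trait=trait,
                    sex=sx,
                    mean_1=float(g1.mean()),
                    sd_1=float(g1.std(ddof=1)),
                    n_1=len(g1),
                    mean_2=float(g2.mean()),
                    sd_2=float(g2.std(ddof=1)),
                    n_2=len(g2),
                    t_statistic=float(t),
                    p_value=float(p),
                    threshold=threshold,
                    significant=bool(p < threshold),
                )
            )
    return out


def comparisons_to_frame(comparisons: list[TypeComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
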