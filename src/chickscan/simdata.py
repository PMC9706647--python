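"""Synthetic genotype/phenotype generator with hierarchical breed/type structure.

The generative model is Balding–Nichols-style hierarchical drift: each marker
gets an ancestral allele frequency p ~ Uniform(0.1, 0.9); each chicken *type*
draws its frequency from Beta(p(1-F_type)/F_type, (1-p)(1-F_type)/F_type);
each *breed* then drifts analogously from its type with F_breed; individual
genotypes are Binomial(2, breed frequency).  Planted type-differentiated loci
override the type-level frequencies with configured values, and planted
causal loci add configured additive effects (trait units per counted-allele
copy) to otherwise breed-baseline + sex-effect + Gaussian-noise phenotypes.

Markers are placed uniformly at random along the configured chromosomes and
sorted; no background LD is simulated beyond what shared drift induces.

A :class:`TruthLedger` records the latent frequencies and planted loci so
that recovery tests can score the analysis stages against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataio import TRAITS, GenotypeDataset, TraitTable

ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass
class CausalLocus:
    marker_index: int
    trait: str
    effect: float  # trait units per copy of the counted allele


@dataclass
class DifferentiatedLocus:
    marker_index: int
    freq_type1: float  # counted-allele frequency in the first type
    freq_type2: float


@dataclass
class SimulationConfig:
    """Everything :func:`simulate` needs; identical config + seed => identical data."""

    n_markers: int = 2000
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 195_000_000, "2": 148_000_000, "4": 91_000_000,
                                 "10": 20_000_000, "Z": 82_000_000}
    )
    type_names: tuple[str, ...] = ("Game", "Bantam")
    breeds_per_type: tuple[int, ...] = (4, 5)
    breed_labels: tuple[str, ...] | None = None
    samples_per_breed: tuple[int, int] = (18, 30)  # inclusive range when sizes not given
    breed_sizes: tuple[int, ...] | None = None
    males_per_breed: tuple[int, ...] | None = None
    sex_ratio: float = 0.5
    F_type: float = 0.10
    F_breed: float = 0.08
    causal_loci: list[CausalLocus] = field(default_factory=list)
    differentiated_loci: list[DifferentiatedLocus] = field(default_factory=list)
    #: causal loci draw their ancestral frequency from this range and skip
    #: drift, so they segregate within every breed (None: treat like any
    #: other marker)
    causal_freq_range: tuple[float, float] | None = (0.25, 0.5)
    breed_baselines: dict[str, dict[str, float]] = field(default_factory=dict)
    sex_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {t: s for t, s in zip(TRAITS, (0.9, 0.45, 0.9, 0.7, 0.25))}
    )
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.F_type < 1 and 0 <= self.F_breed < 1):
            raise ValueError("drift coefficients must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for d in self.differentiated_loci:
            if not (0 <= d.freq_type1 <= 1 and 0 <= d.freq_type2 <= 1):
                raise ValueError("differentiated-locus frequencies must lie in [0, 1]")
            if d.marker_index >= self.n_markers:
                raise ValueError("differentiated locus index out of range")
        for c in self.causal_loci:
            if c.marker_index >= self.n_markers:
                raise ValueError("causal locus index out of range")
        for sd in self.residual_sd.values():
            if sd < 0:
                raise ValueError("residual_sd must be nonnegative")

    @property
    def breed_names(self) -> list[str]:
        if self.breed_labels is not None:
            if len(self.breed_labels) != sum(self.breeds_per_type):
                raise ValueError("breed_labels length must equal the total breed count")
            return list(self.breed_labels)
        names = []
        for t, k in zip(self.type_names, self.breeds_per_type):
            names += [f"{t}{i + 1}" for i in range(k)]
        return names

    @property
    def breed_types(self) -> dict[str, str]:
        names = iter(self.breed_names)
        out = {}
        for t, k in zip(self.type_names, self.breeds_per_type):
            for _ in range(k):
                out[next(names)] = t
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["causal_loci"] = [CausalLocus(**c) for c in raw.get("causal_loci", [])]
        raw["differentiated_loci"] = [DifferentiatedLocus(**d) for d in raw.get("differentiated_loci", [])]
        for key in ("type_names", "breeds_per_type", "breed_labels", "samples_per_breed",
                    "breed_sizes", "males_per_breed", "causal_freq_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthLedger:
    """Latent frequencies and planted loci behind a simulated dataset."""

    ancestral_freq: np.ndarray              # (n_markers,)
    type_freq: np.ndarray                   # (n_types, n_markers)
    breed_freq: np.ndarray                  # (n_breeds, n_markers)
    type_names: list[str]
    breed_names: list[str]
    causal_loci: list[CausalLocus]
    differentiated_loci: list[DifferentiatedLocus]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"ancestral_freq": self.ancestral_freq})
        for i, t in enumerate(self.type_names):
            df[f"freq_{t}"] = self.type_freq[i]
        for i, b in enumerate(self.breed_names):
            df[f"freq_{b}"] = self.breed_freq[i]
        causal_by_idx: dict[int, list[str]] = {}
        for c in self.causal_loci:
            causal_by_idx.setdefault(c.marker_index, []).append(f"{c.trait}:{c.effect:g}")
        df["causal"] = ["; ".join(causal_by_idx.get(i, [])) for i in range(len(df))]
        diff_idx = {d.marker_index for d in self.differentiated_loci}
        df["differentiated"] = [int(i in diff_idx) for i in range(len(df))]
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _drift(freq: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One level of Balding–Nichols drift; F = 0 passes frequencies through."""
    if F == 0:
        return freq.copy()
    # guard Beta parameters against exactly fixed input frequencies
    p = np.clip(freq, 1e-9, 1 - 1e-9)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def place_markers(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic (given the seed) uniform marker placement, sorted by position.

    Chromosomes receive markers proportionally to their length.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    assign = rng.choice(len(chroms), size=config.n_markers, p=lengths / lengths.sum())
    pos = (rng.random(config.n_markers) * lengths[assign]).astype(np.int64) + 1
    pair_idx = rng.integers(0, len(ALLELE_PAIRS), size=config.n_markers)
    df = pd.DataFrame(
        {
            "chromosome": [chroms[i] for i in assign],
            "position_bp": pos,
            "allele_a": [ALLELE_PAIRS[i][0] for i in pair_idx],
            "allele_b": [ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )
    order = {c: i for i, c in enumerate(chroms)}
    df = df.sort_values(by=["chromosome", "position_bp"],
                        key=lambda s: s.map(order) if s.name == "chromosome" else s,
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "marker_id", [f"snp{i:06d}" for i in range(len(df))])
    return df


def _breed_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    if config.breed_sizes is not None:
        if len(config.breed_sizes) != len(config.breed_names):
            raise ValueError("breed_sizes length must equal the number of breeds")
        return list(config.breed_sizes)
    lo, hi = config.samples_per_breed
    return list(rng.integers(lo, hi + 1, size=len(config.breed_names)))


def simulate(config: SimulationConfig) -> tuple[GenotypeDataset, TraitTable, TruthLedger]:
    """Draw one dataset from the hierarchical drift + additive trait model."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    markers = place_markers(config)
    m = config.n_markers
    breed_names = config.breed_names
    breed_types = config.breed_types
    n_types = len(config.type_names)

    ancestral = rng.uniform(0.1, 0.9, size=m)
    diff_idx = {d.marker_index for d in config.differentiated_loci}
    causal_idx = sorted({c.marker_index for c in config.causal_loci} - diff_idx)
    if causal_idx and config.causal_freq_range is not None:
        lo, hi = config.causal_freq_range
        ancestral[causal_idx] = rng.uniform(lo, hi, size=len(causal_idx))
    type_freq = np.stack([_drift(ancestral, config.F_type, rng) for _ in range(n_types)])
    for d in config.differentiated_loci:
        type_freq[0, d.marker_index] = d.freq_type1
        type_freq[1, d.marker_index] = d.freq_type2
    type_index = {t: i for i, t in enumerate(config.type_names)}
    breed_freq = np.stack(
        [_drift(type_freq[type_index[breed_types[b]]], config.F_breed, rng) for b in breed_names]
    )
    if causal_idx and config.causal_freq_range is not None:
        # trait-affecting loci segregate within breeds: no drift at these sites
        type_freq[:, causal_idx] = ancestral[causal_idx]
        breed_freq[:, causal_idx] = ancestral[causal_idx]

    sizes = _breed_sizes(config, rng)
    sample_rows = []
    geno_blocks = []
    for bi, (breed, n) in enumerate(zip(breed_names, sizes)):
        if config.males_per_breed is not None:
            n_male = config.males_per_breed[bi]
        else:
            n_male = int(round(n * config.sex_ratio))
        sexes = ["male"] * n_male + ["female"] * (n - n_male)
        for j, sex in enumerate(sexes):
            sample_rows.append((f"{breed}_{j + 1:02d}", breed, breed_types[breed], sex))
        geno_blocks.append(rng.binomial(2, breed_freq[bi], size=(n, m)).astype(float))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "breed", "type", "sex"])
    dosage = np.vstack(geno_blocks)

    # phenotypes from the true (pre-missingness) dosages
    n_total = len(samples)
    raw = pd.DataFrame(index=samples["sample_id"], columns=TRAITS, dtype=float)
    is_male = (samples["sex"] == "male").to_numpy()
    for trait in TRAITS:
        base = np.array([config.breed_baselines.get(b, {}).get(trait, 0.0) for b in samples["breed"]])
        sexeff = np.array([config.sex_effects.get(b, {}).get(trait, 0.0) for b in samples["breed"]])
        y = base + sexeff * is_male
        for c in config.causal_loci:
            if c.trait == trait:
                y = y + c.effect * dosage[:, c.marker_index]
        sd = config.residual_sd.get(trait, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n_total)
        raw[trait] = y

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    ds = GenotypeDataset(dosage=dosage, markers=markers.assign(minor_allele=markers["allele_b"]),
                         samples=samples)
    # orient to the dataset-wide minor allele while keeping the ledger's
    # counted-allele convention: flip ledger frequencies alongside dosages
    from .dataio import orient_to_minor

    oriented, mk = orient_to_minor(ds.dosage, markers)
    flipped = (mk["minor_allele"] == markers["allele_a"]).to_numpy()
    ds = GenotypeDataset(oriented, mk, samples)
    ledger = TruthLedger(
        ancestral_freq=np.where(flipped, 1 - ancestral, ancestral),
        type_freq=np.where(flipped, 1 - type_freq, type_freq),
        breed_freq=np.where(flipped, 1 - breed_freq, breed_freq),
        type_names=list(config.type_names),
        breed_names=breed_names,
        causal_loci=[
            CausalLocus(c.marker_index, c.trait, -c.effect if flipped[c.marker_index] else c.effect)
            for c in config.causal_loci
        ],
        differentiated_loci=list(config.differentiated_loci),
    )
    return ds, TraitTable(raw=raw), ledger


# ---------------------------------------------------------------------------
# study-shaped default configuration


#: Breed codes, types, sizes and sex splits of the diversity panel the
#: generator emulates: 4 Game-type and 5 Bantam-type breeds, 201 birds.
PANEL_BREEDS = [
    # (breed, type, n, n_male)
    ("ASrb", "Game", 19, 9),
    ("MAxx", "Game", 30, 15),
    ("OFrbx", "Game", 25, 12),
    ("IKxx", "Game", 20, 10),
    ("CHgesch", "Bantam", 22, 10),
    ("CHschw", "Bantam", 29, 13),
    ("KSgw", "Bantam", 20, 10),
    ("OHgh", "Bantam", 18, 8),
    ("OHsh", "Bantam", 18, 10),
]

#: Type-level trait means (Game, Bantam) in trait units; Game birds are larger
#: on every trait.
TYPE_MEANS = {
    "wing_length_cm": (24.0, 17.0),
    "shank_length_cm": (11.0, 6.5),
    "shank_thickness_mm": (14.0, 9.0),
    "keel_length_cm": (13.5, 8.5),
    "body_weight_kg": (3.2, 1.1),
}

#: Male minus female shift as a fraction of the type mean.
SEX_SHIFT_FRACTION = 0.10


def default_panel_config(seed: int, n_markers: int = 6000) -> SimulationConfig:
    """A configuration shaped like the study panel: 9 breeds (4 Game + 5
    Bantam) with the panel sample sizes and sex splits, 5 traits, ``n_markers``
    SNPs over 5 chromosomes, 20 type-differentiated loci (counted-allele
    frequencies 0.9 vs 0.1), per-trait causal loci, and one chromosome-4
    region where a causal locus coincides with differentiated loci.
    """
    cfg = SimulationConfig(
        n_markers=n_markers,
        type_names=("Game", "Bantam"),
        breeds_per_type=(4, 5),
        breed_labels=tuple(b for b, *_ in PANEL_BREEDS),
        breed_sizes=tuple(n for _, _, n, _ in PANEL_BREEDS),
        males_per_breed=tuple(nm for *_, nm in PANEL_BREEDS),
        seed=seed,
    )
    placement = place_markers(cfg)
    chrom = placement["chromosome"].to_numpy()
    pos = placement["position_bp"].to_numpy()

    # deterministic per-breed baseline/sex-effect jitter (independent of the
    # marker placement stream)
    jrng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    baselines: dict[str, dict[str, float]] = {}
    sexeff: dict[str, dict[str, float]] = {}
    for b, t, _, _ in PANEL_BREEDS:
        ti = 0 if t == "Game" else 1
        baselines[b] = {}
        sexeff[b] = {}
        for trait, means in TYPE_MEANS.items():
            mu = means[ti]
            baselines[b][trait] = mu * (1 + jrng.uniform(-0.05, 0.05))
            sexeff[b][trait] = mu * SEX_SHIFT_FRACTION * (1 + jrng.uniform(-0.3, 0.3))

    # a ~4 Mb window on chromosome 4 where a causal locus (segregating within
    # breeds, so the breed-adjusted scan can see it) sits amid a cluster of
    # type-differentiated loci (which drive the PCA selection): the two scans'
    # regions coincide there, while the differentiated loci themselves carry
    # little within-breed variance
    on4 = np.flatnonzero(chrom == "4")
    mid = on4[len(on4) // 2]
    coincident = int(mid)
    left = sorted((int(i) for i in on4 if pos[i] < pos[mid] and pos[mid] - pos[i] <= 2_000_000),
                  key=lambda i: pos[mid] - pos[i])
    right = sorted((int(i) for i in on4 if pos[i] > pos[mid] and pos[i] - pos[mid] <= 2_000_000),
                   key=lambda i: pos[i] - pos[mid])
    diff_window = sorted(left[:3] + right[:3])

    # spread the remaining differentiated loci across chromosomes
    others = [i for i in range(n_markers) if i not in set(diff_window) | {coincident}]
    spread = [int(i) for i in np.linspace(0, len(others) - 1, 14).astype(int)]
    differentiated = [DifferentiatedLocus(i, 0.9, 0.1) for i in diff_window]
    differentiated += [DifferentiatedLocus(others[i], 0.9, 0.1) for i in spread]

    # per-trait causal loci; effects in trait units per counted-allele copy
    def pick(chrom_label: str, frac: float) -> int:
        idx = np.flatnonzero(chrom == chrom_label)
        return int(idx[int(frac * (len(idx) - 1))])

    causal = [
        CausalLocus(pick("1", 0.25), "wing_length_cm", 0.40),
        CausalLocus(pick("2", 0.60), "wing_length_cm", -0.35),
        CausalLocus(pick("1", 0.70), "shank_length_cm", 0.30),
        CausalLocus(pick("2", 0.20), "shank_thickness_mm", 0.55),
        CausalLocus(pick("10", 0.50), "shank_thickness_mm", -0.45),
        CausalLocus(coincident, "keel_length_cm", -0.90),
        CausalLocus(pick("Z", 0.40), "keel_length_cm", 0.30),
        CausalLocus(coincident, "body_weight_kg", -0.23),
        CausalLocus(pick("1", 0.45), "body_weight_kg", 0.15),
    ]

    cfg.causal_loci = causal
    cfg.differentiated_loci = differentiated
    cfg.breed_baselines = baselines
    cfg.sex_effects = sexeff
    return cfg
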