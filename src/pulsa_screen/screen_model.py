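"""Synthetic ground truth for a pooled, FACS-sorted CRISPR knockout screen.

The generative model mirrors a genome-wide knockout screen read out by a
binary cell phenotype (formation of a fluorescent reporter inclusion):

* a Brunello-like guide library (default 4 sgRNAs per gene plus a block of
  non-targeting controls, NTCs);
* per-gene effects expressed as additive shifts on the log-odds that a cell
  forms an inclusion (positive effect = knockout promotes aggregation);
* per-guide knockout efficacy — the probability that an infected cell is
  actually edited;
* single-guide infection (low MOI), log-normal library skew, log-normal
  reporter expression, and a latent ``punctate_fraction`` describing how much
  of a cell's reporter fluorescence is concentrated in its inclusion.

Everything is seeded and deterministic; containers are plain pandas objects
wrapped in light dataclasses so downstream stages can stay vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

#: Sentinel gene label for non-targeting control guides.
NTC_GENE = "NTC"

_BASES = np.array(list("ACGT"))

#: A sampler maps (rng, size) to a float array of that size.
Sampler = Callable[[np.random.Generator, int], np.ndarray]


def uniform_magnitudes(low: float = 2.0, high: float = 4.0) -> Sampler:
    """Effect-size sampler: |effect logit| ~ Uniform(low, high)."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size)

    return sample


def constant(value: float) -> Sampler:
    """Sampler that always returns ``value``."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, float(value))

    return sample


def beta_efficacies(a: float = 8.0, b: float = 2.0) -> Sampler:
    """Knockout-efficacy sampler: efficacy ~ Beta(a, b) (default mean 0.8)."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(a, b, size)

    return sample


def scaled_beta(a: float = 5.0, b: float = 2.0, low: float = 0.3, high: float = 0.95) -> Sampler:
    """Punctate-fraction sampler: Beta(a, b) rescaled onto [low, high]."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return low + (high - low) * rng.beta(a, b, size)

    return sample


@dataclass(frozen=True)
class GuideLibrary:
    """An sgRNA library: one row per guide with ``guide_id, gene, spacer``.

    Non-targeting controls carry the sentinel gene label :data:`NTC_GENE`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["guide_id", "gene", "spacer"]
        if list(t.columns[:3]) != required:
            raise ValueError(f"library table must have columns {required}, got {list(t.columns)}")
        if t["guide_id"].duplicated().any():
            dup = t.loc[t["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id {dup!r}")
        if t["spacer"].duplicated().any():
            dup = t.loc[t["spacer"].duplicated(), "spacer"].iloc[0]
            raise ValueError(f"duplicate spacer {dup!r}")
        if len(t):
            lengths = t["spacer"].str.len()
            if lengths.nunique() != 1:
                raise ValueError("spacers must all have the same length")
            alphabet = set("".join(t["spacer"]))
            if not alphabet <= set("ACGT"):
                raise ValueError(f"spacer alphabet outside ACGT: {sorted(alphabet - set('ACGT'))}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def guide_ids(self) -> np.ndarray:
        return self.table["guide_id"].to_numpy()

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    @property
    def spacers(self) -> np.ndarray:
        return self.table["spacer"].to_numpy()

    @property
    def spacer_length(self) -> int:
        if not len(self.table):
            return 0
        return len(self.table["spacer"].iloc[0])

    @property
    def is_ntc(self) -> np.ndarray:
        return (self.table["gene"] == NTC_GENE).to_numpy()

    @property
    def targeting_genes(self) -> list[str]:
        """Distinct targeted genes, in library order (NTC sentinel excluded)."""
        return list(dict.fromkeys(self.table.loc[~self.is_ntc, "gene"]))

    def to_csv(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        self.table.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GuideLibrary":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep, dtype=str))


@dataclass(frozen=True)
class ScreenTruth:
    """Planted ground truth: gene effects, guide efficacies, baseline log-odds.

    ``gene_effect`` maps gene → additive shift in the log-odds of inclusion
    formation for cells with a successful knockout of that gene; the NTC
    sentinel maps to exactly 0. ``guide_efficacy`` maps guide → probability
    that an infected cell carries a functional knockout.
    """

    library: GuideLibrary
    gene_effect: Mapping[str, float]
    guide_efficacy: Mapping[str, float]
    base_logit: float

    def __post_init__(self) -> None:
        if self.gene_effect.get(NTC_GENE, 0.0) != 0.0:
            raise ValueError("NTC sentinel must have effect exactly 0")
        eff = np.array([self.guide_efficacy[g] for g in self.library.guide_ids], dtype=float)
        if len(eff) and (eff.min() < 0.0 or eff.max() > 1.0):
            raise ValueError("guide efficacies must lie in [0, 1]")

    @property
    def effect_per_guide(self) -> np.ndarray:
        """Effect logit of each guide's gene, aligned to library order."""
        return np.array([self.gene_effect.get(g, 0.0) for g in self.library.genes], dtype=float)

    @property
    def efficacy_per_guide(self) -> np.ndarray:
        return np.array([self.guide_efficacy[g] for g in self.library.guide_ids], dtype=float)

    def effects_frame(self) -> pd.DataFrame:
        genes = sorted(self.gene_effect)
        return pd.DataFrame({"gene": genes, "effect_logit": [self.gene_effect[g] for g in genes]})

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "guide_id": self.library.guide_ids,
                "gene": self.library.genes,
                "effect_logit": self.effect_per_guide,
                "guide_efficacy": self.efficacy_per_guide,
            }
        )
        df["base_logit"] = self.base_logit
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _random_unique_spacers(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` distinct random DNA strings of the given length."""
    if length < 1 and n > 0:
        raise ValueError("spacer_length must be >= 1")
    if n > 0 and 4.0**length < n:
        raise ValueError(
            f"spacer space 4^{length} cannot hold {n} unique spacers"
        )
    seen: dict[str, None] = {}
    while len(seen) < n:
        batch = max(n - len(seen), 16)
        mat = rng.integers(0, 4, size=(batch, length))
        for row in _BASES[mat]:
            if len(seen) >= n:
                break
            seen.setdefault("".join(row), None)
    return np.array(list(seen), dtype=object)


def generate_library(
    n_genes: int,
    guides_per_gene: int = 4,
    n_ntc: int = 1000,
    spacer_length: int = 20,
    seed: int = 0,
) -> GuideLibrary:
    """Generate a Brunello-like synthetic library.

    ``n_genes`` targeted genes with ``guides_per_gene`` guides each, plus
    ``n_ntc`` non-targeting controls; spacers are drawn uniquely at random
    from the 4^``spacer_length`` space. Deterministic for a fixed seed.
    """
    if min(n_genes, guides_per_gene, n_ntc) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_targeting = n_genes * guides_per_gene
    total = n_targeting + n_ntc
    spacers = _random_unique_spacers(total, spacer_length, rng)

    width = max(4, len(str(max(n_genes, 1))))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(n_genes)]
    guide_ids = [
        f"{gene}_g{j + 1}" for gene in genes for j in range(guides_per_gene)
    ]
    gene_col = [gene for gene in genes for _ in range(guides_per_gene)]
    ntc_width = max(4, len(str(max(n_ntc, 1))))
    guide_ids += [f"NTC_{i + 1:0{ntc_width}d}" for i in range(n_ntc)]
    gene_col += [NTC_GENE] * n_ntc

    table = pd.DataFrame({"guide_id": guide_ids, "gene": gene_col, "spacer": spacers[:total]})
    return GuideLibrary(table)


def assign_effects(
    library: GuideLibrary,
    n_up: int,
    n_down: int,
    magnitude_sampler: Sampler | None = None,
    efficacy_sampler: Sampler | None = None,
    base_logit: float = -2.2,
    seed: int = 0,
    down_magnitude_sampler: Sampler | None = None,
) -> ScreenTruth:
    """Plant ``n_up`` aggregation-promoting and ``n_down`` -suppressing genes.

    Remaining genes (and the NTC sentinel) get effect 0; every guide receives
    a knockout efficacy from ``efficacy_sampler`` (default Beta(8, 2)).
    ``base_logit`` is the log-odds of inclusion formation in an unperturbed
    cell, a free screen parameter (default −2.2, ≈10% baseline aggregation).
    ``down_magnitude_sampler`` lets suppressor magnitudes differ from
    promoter magnitudes (the logit → fold-change map saturates on the
    depletion side, so equal logits give unequal fold changes); it defaults
    to ``magnitude_sampler``.
    """
    magnitude_sampler = magnitude_sampler or uniform_magnitudes()
    down_magnitude_sampler = down_magnitude_sampler or magnitude_sampler
    efficacy_sampler = efficacy_sampler or beta_efficacies()
    rng = np.random.default_rng(seed)

    genes = library.targeting_genes
    if n_up + n_down > len(genes):
        raise ValueError(
            f"requested {n_up}+{n_down} regulator genes but library targets only {len(genes)}"
        )
    chosen = rng.choice(len(genes), size=n_up + n_down, replace=False)
    magnitudes = np.concatenate(
        [magnitude_sampler(rng, n_up), down_magnitude_sampler(rng, n_down)]
    )
    effect = {g: 0.0 for g in genes}
    for k, gi in enumerate(chosen):
        sign = 1.0 if k < n_up else -1.0
        effect[genes[gi]] = sign * abs(float(magnitudes[k]))
    effect[NTC_GENE] = 0.0

    efficacies = efficacy_sampler(rng, len(library))
    guide_efficacy = dict(zip(library.guide_ids, np.clip(efficacies, 0.0, 1.0)))
    return ScreenTruth(library, effect, guide_efficacy, float(base_logit))


def simulate_population(
    truth: ScreenTruth,
    n_cells: int,
    guide_abundance_spread: float = 0.3,
    expression_spread: float = 0.5,
    punctate_fraction_sampler: Sampler | None = None,
    mean_fluorescence: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the infected, reporter-expressing cell population.

    Each cell draws one guide (low-MOI assumption) with per-guide abundances
    log-normally dispersed (sigma = ``guide_abundance_spread``); knockout
    success is Bernoulli(guide efficacy); inclusion formation is Bernoulli of
    ``sigmoid(base_logit + effect_logit * ko_success)``; total reporter
    fluorescence is log-normal around ``mean_fluorescence`` (arbitrary
    units). Aggregated cells draw a ``punctate_fraction`` from the sampler
    (default Beta(5, 2) scaled to [0.3, 0.95]); diffuse cells have 0.

    Returns a DataFrame with one row per cell: ``cell_id, guide_idx,
    guide_id, ko_success, total_fluorescence, aggregated, punctate_fraction``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sampler = punctate_fraction_sampler or scaled_beta()
    rng = np.random.default_rng(seed)
    lib = truth.library
    n_guides = len(lib)
    if n_guides == 0:
        raise ValueError("library is empty")

    if guide_abundance_spread > 0:
        weights = rng.lognormal(0.0, guide_abundance_spread, n_guides)
    else:
        weights = np.ones(n_guides)
    guide_idx = rng.choice(n_guides, size=n_cells, p=weights / weights.sum())

    ko = rng.random(n_cells) < truth.efficacy_per_guide[guide_idx]
    logit = truth.base_logit + truth.effect_per_guide[guide_idx] * ko
    aggregated = rng.random(n_cells) < expit(logit)

    fluor = rng.lognormal(math.log(mean_fluorescence), expression_spread, n_cells)
    punctate = np.zeros(n_cells)
    n_agg = int(aggregated.sum())
    if n_agg:
        punctate[aggregated] = sampler(rng, n_agg)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "guide_idx": guide_idx.astype(np.int64),
            "guide_id": pd.Categorical.from_codes(guide_idx, categories=lib.guide_ids),
            "ko_success": ko,
            "total_fluorescence": fluor,
            "aggregated": aggregated,
            "punctate_fraction": punctate,
        }
    )
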