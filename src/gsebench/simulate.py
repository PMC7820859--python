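"""Synthetic expression data, gene set collections and relevance rankings.

Every benchmark assay in this package runs on generated data, so the
generators are first-class, deterministic components: each is a pure function
of its parameters and an integer seed.

Three generators cover the benchmark triple:

* :func:`simulate_expression` — a genes x samples matrix in microarray
  (Gaussian log-intensity) or RNA-seq (negative-binomial count) mode, with a
  controlled fraction of differentially expressed (DE) genes, a common effect
  size on the log2 scale, and optional within-block inter-gene correlation
  induced by shared latent factors.
* :func:`sample_random_sets` — uniform random gene sets of defined size, the
  ingredient of the set-size dependency assay.
* :func:`make_scenario` — gene sets with designated "truly enriched" members
  oversampling the DE genes, plus a noisy relevance ranking whose scores track
  each set's true DE-gene fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import DataKind, ExpressionDataset, GeneSetCollection, RelevanceRanking
from .io import (
    read_expression_tsv,
    read_gmt,
    read_relevance_table,
    write_expression_tsv,
    write_gmt,
    write_relevance_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "sample_random_sets",
    "make_scenario",
    "save_scenario",
    "load_scenario",
]

#: Baseline mean/SD of log2 intensities in microarray mode.
LOG_INTENSITY_MEAN = 7.0
LOG_INTENSITY_GENE_SD = 1.0
LOG_INTENSITY_NOISE_SD = 1.0

#: Log-normal parameters of gene-wise mean counts in RNA-seq mode
#: (median ~150 counts, long right tail).
COUNT_MEANLOG = 5.0
COUNT_SDLOG = 1.5


@dataclass
class SimulationTruth:
    """Ground truth attached to one simulated dataset/scenario.

    Attributes
    ----------
    de_genes
        Genes simulated as differentially expressed.
    effect_sizes
        Signed log2 effect per DE gene (case minus control).
    enriched_sets
        Set ids designated truly enriched (filled by :func:`make_scenario`).
    cor_blocks
        Groups of genes sharing a latent correlation factor (empty when the
        simulation had zero within-set correlation).
    """

    de_genes: set[str] = field(default_factory=set)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    enriched_sets: set[str] = field(default_factory=set)
    cor_blocks: list[list[str]] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": sorted(self.de_genes),
                "effect_sizes": {g: self.effect_sizes[g] for g in sorted(self.effect_sizes)},
                "enriched_sets": sorted(self.enriched_sets),
                "cor_blocks": self.cor_blocks,
                "seed": self.seed,
                "params": self.params,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            de_genes=set(d["de_genes"]),
            effect_sizes=dict(d["effect_sizes"]),
            enriched_sets=set(d["enriched_sets"]),
            cor_blocks=[list(b) for b in d.get("cor_blocks", [])],
            seed=int(d["seed"]),
            params=d.get("params", {}),
        )


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_expression(
    n_genes: int = 2000,
    n_per_group: int = 15,
    de_fraction: float = 0.3,
    effect_size: float = 1.0,
    within_set_cor: float = 0.0,
    kind: DataKind | str = DataKind.LOG_INTENSITY,
    seed: int = 0,
    dispersion: float = 0.1,
    cor_block_size: int = 20,
    name: str = "sim",
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Simulate a two-group expression dataset with known DE genes.

    In ``log_intensity`` mode each gene ``g`` in sample ``s`` is

        ``x_gs = mu_g + delta_g * [s in case group] + e_gs``

    with gene baselines ``mu_g ~ N(7, 1)``, unit-variance Gaussian noise, and
    ``delta_g = +-effect_size`` (random sign) for DE genes, 0 otherwise. In
    ``counts`` mode gene means are log-normal and counts are drawn from a
    negative binomial with common dispersion ``phi = dispersion``
    (variance ``mu + phi mu^2``); the DE effect multiplies the case-group mean
    by ``2**(+-effect_size)``. ``tpm`` mode rescales the count means to a
    library of one million without integer rounding.

    ``within_set_cor`` > 0 partitions the genes into consecutive blocks of
    ``cor_block_size`` genes; genes in a block share a per-sample latent
    factor with loading ``sqrt(within_set_cor)``, giving pairwise within-block
    correlation ~``within_set_cor`` (exact in log-intensity mode, approximate
    on the log scale for counts). The blocks are recorded in the returned
    truth so that gene sets can be aligned with them.

    Identical parameters and seed give bit-identical output.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if not 0.0 <= within_set_cor < 1.0:
        raise ValueError("within_set_cor must lie in [0, 1)")
    kind = DataKind(kind)
    rng = _rng(seed)

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    n_samples = 2 * n_per_group
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    groups = ["ctrl"] * n_per_group + ["case"] * n_per_group
    case_mask = np.array([g == "case" for g in groups])

    n_de = int(round(de_fraction * n_genes))
    if de_fraction > 0 and n_de < 1:
        logger.warning("de_fraction %.3g rounds to zero genes; using 1", de_fraction)
        n_de = 1
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.empty(0, dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    delta = np.zeros(n_genes)
    delta[de_idx] = signs * effect_size

    # shared latent factors inducing within-block correlation
    cor_blocks: list[list[str]] = []
    latent = np.zeros((n_genes, n_samples))
    if within_set_cor > 0:
        n_blocks = int(np.ceil(n_genes / cor_block_size))
        u = rng.standard_normal((n_blocks, n_samples))
        block_of_gene = np.arange(n_genes) // cor_block_size
        latent = np.sqrt(within_set_cor) * u[block_of_gene]
        cor_blocks = [
            [gene_ids[i] for i in range(n_genes) if block_of_gene[i] == b]
            for b in range(n_blocks)
        ]

    resid_scale = np.sqrt(1.0 - within_set_cor)
    noise = resid_scale * rng.standard_normal((n_genes, n_samples)) + latent

    if kind is DataKind.LOG_INTENSITY:
        mu = LOG_INTENSITY_MEAN + LOG_INTENSITY_GENE_SD * rng.standard_normal(n_genes)
        matrix = (
            mu[:, None]
            + delta[:, None] * case_mask[None, :]
            + LOG_INTENSITY_NOISE_SD * noise
        )
    else:
        # gene-wise mean counts, log-normal across genes
        log_mu = COUNT_MEANLOG + COUNT_SDLOG * rng.standard_normal(n_genes)
        mu = np.exp(log_mu)
        fold = 2.0 ** (delta[:, None] * case_mask[None, :])
        mean_gs = mu[:, None] * fold
        if within_set_cor > 0:
            # latent factor acts multiplicatively on the log2 scale
            mean_gs = mean_gs * 2.0 ** (0.5 * latent)
        if kind is DataKind.COUNTS:
            if dispersion > 0:
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mean_gs / shape)
                matrix = rng.poisson(lam).astype(float)
            else:
                matrix = rng.poisson(mean_gs).astype(float)
        else:  # TPM: normalize expected abundance to a million, no counting noise
            noisy = mean_gs * np.exp(0.2 * noise)
            matrix = noisy / noisy.sum(axis=0, keepdims=True) * 1e6

    dataset = ExpressionDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        groups=groups,
        kind=kind,
        name=name,
    )
    truth = SimulationTruth(
        de_genes={gene_ids[i] for i in de_idx},
        effect_sizes={gene_ids[i]: float(delta[i]) for i in de_idx},
        cor_blocks=cor_blocks,
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_per_group": n_per_group,
            "de_fraction": de_fraction,
            "effect_size": effect_size,
            "within_set_cor": within_set_cor,
            "kind": kind.value,
            "dispersion": dispersion,
        },
    )
    return dataset, truth


def sample_random_sets(
    universe: Sequence[str],
    size: int,
    count: int,
    seed: int = 0,
    prefix: str = "RS",
) -> GeneSetCollection:
    """``count`` gene sets, each a uniform sample of ``size`` distinct genes.

    Used by the set-size dependency assay, which draws e.g. 100 random sets at
    each of several defined sizes and asks what fraction a method calls
    significant.
    """
    universe = list(universe)
    if size > len(universe):
        raise ValueError(f"set size {size} exceeds universe size {len(universe)}")
    if size < 1 or count < 1:
        raise ValueError("size and count must be positive")
    rng = _rng(seed)
    arr = np.asarray(universe, dtype=object)
    sets = {
        f"{prefix}{size}_{k:04d}": [str(g) for g in rng.choice(arr, size=size, replace=False)]
        for k in range(count)
    }
    return GeneSetCollection(sets=sets, name=f"random_s{size}")


def make_scenario(
    dataset: ExpressionDataset,
    truth: SimulationTruth,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    frac_enriched: float = 0.2,
    relevance_noise: float = 1.0,
    seed: int = 0,
    enriched_de_prop: float = 0.7,
    relevance_scale: float = 10.0,
) -> tuple[GeneSetCollection, RelevanceRanking, SimulationTruth]:
    """Build a gene set collection plus relevance ranking around a dataset.

    A fraction ``frac_enriched`` of the sets is designated truly enriched:
    each draws ``enriched_de_prop`` of its members from the DE genes of
    ``truth`` and the remainder from the non-DE genes. The other sets are
    uniform draws from the whole universe. The relevance score of set ``i`` is

        ``S_p(i) = relevance_scale * f_DE(i) + |eps_i|``

    where ``f_DE(i)`` is the set's true DE-gene fraction and ``eps_i`` is
    half-normal with scale ``relevance_noise`` — an imperfect but informative
    surrogate for a literature-derived relevance ranking. ``relevance_noise=0``
    makes the relevance order exactly the true DE-fraction order.

    Returns the collection, the ranking, and a copy of ``truth`` with
    ``enriched_sets`` filled in.
    """
    if not 0.0 <= frac_enriched <= 1.0:
        raise ValueError("frac_enriched must lie in [0, 1]")
    n_enriched = int(round(frac_enriched * n_sets))
    if n_enriched > 0 and not truth.de_genes:
        raise ValueError("frac_enriched > 0 requires a truth with DE genes")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid set_size_range")
    rng = _rng(seed)
    universe = list(dataset.gene_ids)
    de = sorted(truth.de_genes)
    non_de = [g for g in universe if g not in truth.de_genes]

    sets: dict[str, list[str]] = {}
    enriched_ids: set[str] = set()
    for k in range(n_sets):
        sid = f"GS{k:03d}"
        size = int(rng.integers(lo, hi + 1))
        if k < n_enriched:
            n_from_de = min(int(round(enriched_de_prop * size)), len(de))
            picked = list(rng.choice(np.asarray(de, dtype=object), n_from_de, replace=False))
            rest = size - n_from_de
            if rest > 0:
                picked += list(
                    rng.choice(np.asarray(non_de, dtype=object), rest, replace=False)
                )
            enriched_ids.add(sid)
        else:
            picked = list(rng.choice(np.asarray(universe, dtype=object), size, replace=False))
        sets[sid] = [str(g) for g in picked]
    collection = GeneSetCollection(sets=sets, name="scenario")

    de_frac = np.array(
        [len(set(genes) & truth.de_genes) / len(genes) for genes in sets.values()]
    )
    noise = np.abs(rng.standard_normal(n_sets)) * relevance_noise
    scores = relevance_scale * de_frac + noise
    if not np.any(scores > 0):
        raise ValueError(
            "all relevance scores are zero; increase relevance_noise or provide DE genes"
        )
    relevance = RelevanceRanking(
        scores={sid: float(s) for sid, s in zip(sets, scores)},
        phenotype="simulated",
    )
    new_truth = SimulationTruth(
        de_genes=set(truth.de_genes),
        effect_sizes=dict(truth.effect_sizes),
        enriched_sets=enriched_ids,
        cor_blocks=[list(b) for b in truth.cor_blocks],
        seed=truth.seed,
        params={
            **truth.params,
            "n_sets": n_sets,
            "set_size_range": list(set_size_range),
            "frac_enriched": frac_enriched,
            "relevance_noise": relevance_noise,
            "scenario_seed": seed,
        },
    )
    return collection, relevance, new_truth


# -- scenario (de)serialization ------------------------------------------

MATRIX_FILE = "matrix.tsv"
GMT_FILE = "sets.gmt"
RELEVANCE_FILE = "relevance.tsv"
TRUTH_FILE = "truth.json"


def save_scenario(
    directory: str | Path,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    relevance: RelevanceRanking,
    truth: SimulationTruth,
) -> Path:
    """Write the benchmark triple plus ground truth into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(dataset, directory / MATRIX_FILE)
    write_gmt(collection, directory / GMT_FILE)
    write_relevance_table(relevance, directory / RELEVANCE_FILE)
    (directory / TRUTH_FILE).write_text(truth.to_json(), encoding="utf-8")
    return directory


def load_scenario(
    directory: str | Path, kind: DataKind | str | None = None
) -> tuple[ExpressionDataset, GeneSetCollection, RelevanceRanking, SimulationTruth]:
    """Read back a scenario written by :func:`save_scenario`."""
    directory = Path(directory)
    truth = SimulationTruth.from_json((directory / TRUTH_FILE).read_text(encoding="utf-8"))
    use_kind = DataKind(kind) if kind is not None else DataKind(
        truth.params.get("kind", "log_intensity")
    )
    dataset = read_expression_tsv(directory / MATRIX_FILE, kind=use_kind)
    collection = read_gmt(directory / GMT_FILE)
    relevance = read_relevance_table(directory / RELEVANCE_FILE)
    return dataset, collection, relevance, truth
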