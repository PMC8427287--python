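"""Two-condition expression data with planted condition-specific hubs.

The generator emulates the structure the two-state network comparison is
designed to detect: modules of co-expressed genes, a subset of which
("planted" genes) gain their co-expression only under stress. Gene
log-expression follows a latent-factor Gaussian copula — each module has a
per-sample latent factor, and a member gene's log-expression is
``sqrt(rho) * factor + sqrt(1 - rho) * noise`` — so the pairwise log-scale
correlation between two members with loadings rho1 and rho2 is
``sqrt(rho1 * rho2)``, which makes edge formation at a correlation
threshold analytically predictable. Counts are drawn negative-binomial
around ``exp(mean_log_expression + signal)``.

Planted genes load on their module factor with ``rho_on`` under stress and
``rho_off`` under normal; every non-planted module member loads with
``rho_on`` in both states; genes outside any module are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    REGION_CLASSES,
    ConfigurationError,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    SNPRecord,
    SNPTable,
)

import pandas as pd

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-state experiment.

    Defaults are sized so the full pipeline runs in seconds while keeping
    the planted-signal statistics realistic: 600 genes of which 200 sit in
    ten 20-gene modules, 30 planted differential hubs, 30 samples per
    state, module correlation 0.95 when active, and negative-binomial
    counts with dispersion 0.01 around a mean of exp(6.5) ~ 665.
    """

    n_genes: int = 600
    n_samples_per_state: int = 30
    n_modules: int = 10
    module_size: int = 20
    n_planted: int = 30
    rho_on: float = 0.95
    rho_off: float = 0.0
    nb_dispersion: float = 0.01
    mean_log_expression: float = 6.5
    snp_fraction_planted: float = 0.8
    snp_fraction_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_modules <= 0 or self.module_size <= 0:
            raise ConfigurationError("gene, module and module-size counts must be positive")
        if self.n_samples_per_state < 4:
            raise ConfigurationError("need at least 4 samples per state")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("modules do not fit in the gene panel")
        if self.n_planted < 0 or self.n_planted > self.n_modules * self.module_size:
            raise ConfigurationError("n_planted must fit inside the modules")
        if not (0 < self.rho_on < 1):
            raise ConfigurationError("rho_on must lie in (0, 1)")
        if not (0 <= self.rho_off < self.rho_on):
            raise ConfigurationError("rho_off must lie in [0, rho_on)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        for name in ("snp_fraction_planted", "snp_fraction_background"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: the differential-hub genes and module membership."""

    planted_gene_ids: set[str]
    module_assignment: dict[str, int | None]


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # Gamma-Poisson mixture: var = mu + dispersion * mu^2
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_two_state_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate matched normal- and stress-state count matrices.

    Both matrices share one gene panel and have ``n_samples_per_state``
    samples each (sample ids ``normal_01`` ... / ``stress_01`` ...). The
    result is a pure function of the config, including its seed.

    Returns
    -------
    (normal, stress, truth)
        The two count matrices and the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_samples_per_state

    module_of = np.full(config.n_genes, -1)
    for m in range(config.n_modules):
        module_of[m * config.module_size : (m + 1) * config.module_size] = m
    planted_mask = np.zeros(config.n_genes, dtype=bool)
    planted_mask[: config.n_planted] = True  # fills modules in order

    matrices: dict[str, ExpressionMatrix] = {}
    for state in ("normal", "stress"):
        factors = rng.standard_normal((config.n_modules, n))
        noise = rng.standard_normal((config.n_genes, n))
        signal = np.empty((config.n_genes, n))
        for g in range(config.n_genes):
            m = module_of[g]
            if m < 0:
                signal[g] = noise[g]
                continue
            if planted_mask[g]:
                rho = config.rho_on if state == "stress" else config.rho_off
            else:
                rho = config.rho_on
            signal[g] = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * noise[g]
        mu = np.exp(config.mean_log_expression + signal)
        counts = _nb_counts(rng, mu, config.nb_dispersion)
        sample_ids = [f"{state}_{j:02d}" for j in range(1, n + 1)]
        matrices[state] = ExpressionMatrix(
            values=pd.DataFrame(counts, index=genes, columns=sample_ids),
            sample_state={s: state for s in sample_ids},
            sample_stage={s: "pooled" for s in sample_ids},
            sample_replicate={s: j + 1 for j, s in enumerate(sample_ids)},
        )

    truth = GroundTruth(
        planted_gene_ids={genes[g] for g in np.flatnonzero(planted_mask)},
        module_assignment={
            genes[g]: (int(module_of[g]) if module_of[g] >= 0 else None)
            for g in range(config.n_genes)
        },
    )
    return matrices["normal"], matrices["stress"], truth


def generate_snp_table(
    truth: GroundTruth, all_genes: Sequence[str], config: SimulationConfig
) -> SNPTable:
    """Simulate variant evidence partially overlapping the planted genes.

    Each planted gene receives at least one SNP record with probability
    ``snp_fraction_planted``; background genes with probability
    ``snp_fraction_background``. Region classes are sampled uniformly.
    """
    rng = np.random.default_rng([config.seed, 211])
    records: list[SNPRecord] = []
    classes = list(REGION_CLASSES)
    for gene in all_genes:
        p = (
            config.snp_fraction_planted
            if gene in truth.planted_gene_ids
            else config.snp_fraction_background
        )
        if rng.random() >= p:
            continue
        for _ in range(int(rng.integers(1, 4))):
            ref, alt = rng.choice(4, size=2, replace=False)
            records.append(
                SNPRecord(
                    gene_id=gene,
                    position=int(rng.integers(1, 5001)),
                    ref_allele=str(_NUCLEOTIDES[ref]),
                    alt_allele=str(_NUCLEOTIDES[alt]),
                    region_class=classes[int(rng.integers(len(classes)))],
                )
            )
    return SNPTable(records=records)


def generate_annotation(
    all_genes: Sequence[str],
    interval: GenomicInterval,
    truth: GroundTruth,
    in_interval_fraction_planted: float,
    seed: int,
    gene_length: int = 1000,
    gene_gap: int = 500,
) -> GeneAnnotation:
    """Place genes on the genome so a chosen fraction of planted genes
    falls inside the query interval.

    ``round(fraction * n_planted)`` planted genes (chosen at random from
    the planted set) are laid out inside ``interval``; every other gene is
    placed outside it, on the same chromosome beyond the interval end.
    Gene intervals never overlap.
    """
    if not (0 <= in_interval_fraction_planted <= 1):
        raise ConfigurationError("in_interval_fraction_planted must lie in [0, 1]")
    rng = np.random.default_rng([seed, 733])
    planted = sorted(g for g in truth.planted_gene_ids if g in set(all_genes))
    n_inside = int(round(in_interval_fraction_planted * len(planted)))
    pitch = gene_length + gene_gap
    if n_inside * pitch > interval.length:
        raise ConfigurationError(
            f"interval of length {interval.length} cannot hold {n_inside} genes "
            f"at {pitch} bp per gene"
        )
    inside = set(rng.choice(planted, size=n_inside, replace=False)) if n_inside else set()

    entries: dict[str, tuple[str, int, int]] = {}
    pos_in = interval.start
    pos_out = interval.end + gene_gap
    for gene in all_genes:
        if gene in inside:
            entries[gene] = (interval.chromosome, pos_in, pos_in + gene_length)
            pos_in += pitch
        else:
            entries[gene] = (interval.chromosome, pos_out, pos_out + gene_length)
            pos_out += pitch
    return GeneAnnotation(entries=entries)
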