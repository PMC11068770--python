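"""Synthetic genotypes and multi-environment phenotypes with known truth.

The generator emulates an unbalanced multi-environment association panel of
the kind produced by evaluating one diversity panel (~292 inbred accessions,
~7,600 biallelic chip SNPs on 7 chromosomes) in several environment x
treatment contexts: the same accessions recur across contexts, a handful of
planted QTL have effects correlated across environments, a polygenic
background is structured by the realised genomic relationship matrix, and
both genotype calls and phenotype cells are missing completely at random.

Per environment ``e`` the phenotype is::

    y_e = mu_e + sum_q x_q beta_{q,e} + g_e + eps_e

with unit target phenotypic variance: each QTL explains
``qtl_variance_fraction`` (averaged over environments), the polygenic
background explains ``polygenic_h2``, and iid noise fills the rest.  QTL
effect vectors across environments are multivariate normal with pairwise
correlation ``effect_correlation``; the polygenic background is likewise
correlated across environments (``polygenic_correlation``, defaulting to the
QTL value), which is what makes null t-values correlated between contexts
that share accessions — the structure the meta-analysis correction exists
for.

Sites are Hardy-Weinberg independent draws (no linkage disequilibrium): the
meta statistic does not require LD, and independent sites keep every
downstream calibration property exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .genotype import GenotypeMatrix, _vanraden
from .phenotype import PHENOTYPE_COLUMNS

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the emulated study: 292 accessions, 7,642 SNPs on 7
    chromosomes, four environment contexts per trait, five planted QTL at 5%
    of phenotypic variance each with cross-environment effect correlation
    0.5, a polygenic background at h2 = 0.5, and modest missingness.
    """

    n_accessions: int = 292
    n_snps: int = 7642
    n_chromosomes: int = 7
    chrom_length_bp: int = 600_000_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_environments: int = 4
    n_qtl: int = 5
    qtl_variance_fraction: float = 0.05
    effect_correlation: float = 0.5
    polygenic_h2: float = 0.5
    polygenic_correlation: float | None = None
    genotype_missing_rate: float = 0.05
    phenotype_missing_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_snps < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("counts must be positive")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(
                f"need 0 < maf_low <= maf_high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )
        if self.chrom_length_bp < 1:
            raise ConfigurationError("chrom_length_bp must be positive")
        if not -1.0 <= self.effect_correlation <= 1.0:
            raise ConfigurationError(
                f"effect_correlation must lie in [-1, 1], got {self.effect_correlation}"
            )
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ConfigurationError(
                f"polygenic_h2 must lie in [0, 1), got {self.polygenic_h2}"
            )
        total = self.qtl_variance_fraction * self.n_qtl + self.polygenic_h2
        if total >= 1.0:
            raise ConfigurationError(
                f"qtl_variance_fraction * n_qtl + polygenic_h2 = {total:.3f} "
                "must stay below 1 (residual variance must be positive)"
            )
        for name in ("genotype_missing_rate", "phenotype_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.n_environments >= 2:
            rho_min = -1.0 / (self.n_environments - 1)
            for name in ("effect_correlation", "polygenic_correlation"):
                v = getattr(self, name)
                if v is not None and v < rho_min:
                    raise ConfigurationError(
                        f"{name}={v} makes the {self.n_environments}-environment "
                        f"equicorrelation matrix indefinite (min {rho_min:.3f})"
                    )

    @property
    def rho_polygenic(self) -> float:
        if self.polygenic_correlation is None:
            return self.effect_correlation
        return self.polygenic_correlation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth of one simulated data set."""

    qtl_snp_ids: list[str]
    effects: np.ndarray          # n_qtl x n_environments
    polygenic: np.ndarray        # n_accessions x n_environments
    intercepts: np.ndarray       # n_environments
    residual_variance: float
    environments: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "qtl_snp_ids": self.qtl_snp_ids,
                "effects": np.asarray(self.effects).tolist(),
                "polygenic": np.asarray(self.polygenic).tolist(),
                "intercepts": np.asarray(self.intercepts).tolist(),
                "residual_variance": self.residual_variance,
                "environments": self.environments,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes with uniform allele frequencies.

    Each SNP draws an allele frequency uniformly from
    [maf_low, maf_high] and dosages as Binomial(2, p) per accession;
    positions are uniform per chromosome and sorted; missing calls are
    masked at ``genotype_missing_rate``.  The complete matrix is attached as
    ``true_dosage`` for downstream phenotype simulation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(config.maf_low, config.maf_high, config.n_snps)
    true = rng.binomial(2, p, size=(config.n_accessions, config.n_snps)).astype(float)

    chunks = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    chroms = np.empty(config.n_snps, dtype=object)
    positions = np.empty(config.n_snps, dtype=int)
    for c, idx in enumerate(chunks, start=1):
        chroms[idx] = f"Chr{c}"
        positions[idx] = np.sort(
            rng.integers(1, config.chrom_length_bp + 1, size=len(idx))
        )
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_snps)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"SNP{i + 1:06d}" for i in range(config.n_snps)],
            "chrom": chroms,
            "pos": positions,
            "allele1": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "allele2": [_ALLELE_PAIRS[k][1] for k in pair_idx],
        }
    )
    dosage = true.copy()
    if config.genotype_missing_rate > 0:
        mask = rng.random(dosage.shape) < config.genotype_missing_rate
        dosage[mask] = np.nan
    accession_ids = [f"ACC{i + 1:04d}" for i in range(config.n_accessions)]
    return GenotypeMatrix(dosage, accession_ids, snp_map, true_dosage=true)


def _equicorrelation_sqrt(n: int, rho: float) -> np.ndarray:
    """Symmetric square root of the n x n equicorrelation matrix."""
    R = np.full((n, n), rho)
    np.fill_diagonal(R, 1.0)
    w, Q = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)
    return Q @ np.diag(np.sqrt(w)) @ Q.T


def simulate_phenotypes(
    G: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Multi-environment phenotypes with planted QTL and polygenic background.

    Returns the long phenotype table (one row per accession x environment,
    trait ``Y``, treatment ``treated``, replicate 1, NaN cells dropped) and
    the :class:`SimTruth` object.  Deterministic given the config seed; the
    phenotype stream is decoupled from the genotype stream so regenerating
    phenotypes does not perturb genotypes.
    """
    config.validate()
    if config.n_qtl > G.n_snps:
        raise ConfigurationError(
            f"n_qtl={config.n_qtl} exceeds the {G.n_snps} available SNPs"
        )
    rng = np.random.default_rng(config.seed + 1)
    X = G.true_dosage
    if X is None:
        called = ~np.isnan(G.dosage)
        freq = np.nansum(G.dosage, axis=0) / (2.0 * called.sum(axis=0))
        X = np.where(called, G.dosage, 2.0 * freq)
    n_acc, n_env = config.n_accessions, config.n_environments
    environments = [f"E{e + 1:02d}" for e in range(n_env)]

    # planted QTL: prefer informative sites so the per-QTL variance target
    # is realisable; fall back to all sites for tiny panels
    var_x = X.var(axis=0)
    candidates = np.flatnonzero(var_x > 1e-8)
    if len(candidates) < config.n_qtl:
        raise ConfigurationError(
            f"only {len(candidates)} polymorphic SNPs for {config.n_qtl} QTL"
        )
    qtl_idx = rng.choice(candidates, size=config.n_qtl, replace=False)

    genetic = np.zeros((n_acc, n_env))
    effects = np.zeros((config.n_qtl, n_env))
    if config.n_qtl:
        C_eff = _equicorrelation_sqrt(n_env, config.effect_correlation)
        z = rng.standard_normal((config.n_qtl, n_env)) @ C_eff.T
        for q, j in enumerate(qtl_idx):
            xc = X[:, j] - X[:, j].mean()
            ms = float(np.mean(z[q] ** 2))
            scale = np.sqrt(config.qtl_variance_fraction / (var_x[j] * ms))
            effects[q] = z[q] * scale
            genetic += np.outer(xc, effects[q])

    polygenic = np.zeros((n_acc, n_env))
    if config.polygenic_h2 > 0:
        K = _vanraden(X)
        w, Q = np.linalg.eigh(K)
        Ksqrt = Q @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ Q.T
        C_pol = _equicorrelation_sqrt(n_env, config.rho_polygenic)
        polygenic = (
            np.sqrt(config.polygenic_h2)
            * Ksqrt @ rng.standard_normal((n_acc, n_env)) @ C_pol.T
        )

    sigma_e2 = 1.0 - config.qtl_variance_fraction * config.n_qtl - config.polygenic_h2
    intercepts = rng.standard_normal(n_env)
    y = (
        intercepts[None, :]
        + genetic
        + polygenic
        + np.sqrt(sigma_e2) * rng.standard_normal((n_acc, n_env))
    )
    if config.phenotype_missing_rate > 0:
        blank = rng.random(y.shape) < config.phenotype_missing_rate
        y = np.where(blank, np.nan, y)

    rows = []
    for e, env in enumerate(environments):
        for i, acc in enumerate(G.accession_ids):
            if np.isnan(y[i, e]):
                continue
            rows.append((acc, env, "treated", "Y", 1, y[i, e]))
    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    truth = SimTruth(
        qtl_snp_ids=[G.snp_ids[j] for j in qtl_idx],
        effects=effects,
        polygenic=polygenic,
        intercepts=intercepts,
        residual_variance=float(sigma_e2),
        environments=environments,
    )
    return table, truth
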