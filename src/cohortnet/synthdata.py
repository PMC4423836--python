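"""Synthetic case-control cohorts with planted ground truth.

The real study population (a prospective cohort of middle-aged men followed
for coronary events) is not publicly deposited, so this module generates
cohorts with the same statistical skeleton: SNP genotypes in Hardy-Weinberg
proportions, correlated continuous risk factors with additive per-allele
genetic effects, a binary exposure, and a binary outcome produced by a
liability-threshold (probit) disease model.  Every draw flows from a single
integer seed, and the generator returns a :class:`PlantedTruth` naming the
indicator columns that genuinely carry outcome signal — the oracle for
feature-selection recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import CohortTable, VariableSpec


class SimulationError(RuntimeError):
    """Raised when a requested cohort cannot be realized (e.g. too few cases)."""


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Effects are additive per minor allele, expressed in phenotype SD units.
    ``liability_weights`` maps variable names to their weight on the latent
    disease liability (phenotypes enter standardized, SNPs as centred allele
    counts, binaries as 0/1).  ``hub_variable`` optionally names a SNP given
    nonzero effects on at least five phenotypes, emulating a pleiotropic hub.
    """

    n_cases: int = 102
    n_controls: int = 150
    n_snps: int = 37
    n_continuous: int = 14
    n_binary: int = 1
    allele_freqs: np.ndarray | None = None
    effect_matrix: np.ndarray | None = None  # (n_snps, n_continuous)
    phenotype_correlation: np.ndarray | None = None
    liability_weights: dict[str, float] = field(default_factory=dict)
    liability_noise_sd: float = 1.0
    case_fraction: float = 0.15  # target population incidence for thresholding
    binary_prevalence: float = 0.28
    hub_variable: str | None = None
    oversample: float = 2.0  # pool head-room beyond the minimum feasible size
    seed: int = 0

    def __post_init__(self):
        if self.allele_freqs is None:
            # spread of intermediate frequencies; fixed, not seed-dependent
            self.allele_freqs = np.linspace(0.15, 0.5, self.n_snps)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.allele_freqs.size != self.n_snps:
            raise ValueError("allele_freqs length must equal n_snps")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.effect_matrix is None:
            self.effect_matrix = np.zeros((self.n_snps, self.n_continuous))
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (self.n_snps, self.n_continuous):
            raise ValueError("effect_matrix must be (n_snps, n_continuous)")
        if self.phenotype_correlation is None:
            self.phenotype_correlation = np.eye(self.n_continuous)
        self.phenotype_correlation = np.asarray(self.phenotype_correlation, float)
        C = self.phenotype_correlation
        if C.shape != (self.n_continuous, self.n_continuous) or not np.allclose(C, C.T):
            raise ValueError("phenotype_correlation must be symmetric of matching size")
        if self.n_continuous and np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("phenotype_correlation must be positive definite")

    @property
    def snp_names(self) -> list[str]:
        return [f"SNP{i + 1:02d}" for i in range(self.n_snps)]

    @property
    def phenotype_names(self) -> list[str]:
        return [f"pheno{i + 1:02d}" for i in range(self.n_continuous)]

    @property
    def binary_names(self) -> list[str]:
        return [f"bin{i + 1}" for i in range(self.n_binary)]

    def variable_specs(self) -> list[VariableSpec]:
        specs = [VariableSpec(n, "continuous") for n in self.phenotype_names]
        specs += [VariableSpec(n, "binary") for n in self.binary_names]
        specs += [VariableSpec(n, "genotype3") for n in self.snp_names]
        return specs


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``informative_indicators`` lists the indicator column labels whose
    case/control frequency shifts under the configured liability weights:
    for each nonzero-weight variable its extreme categories (class/tertile
    1 and 3, or both binary classes).  The middle class of a three-class
    variable carries only weak marginal signal under an additive effect and
    is not counted.
    """

    informative_indicators: tuple[str, ...]
    hub_variable: str | None
    liability_weights: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "informative_indicators": list(self.informative_indicators),
                    "hub_variable": self.hub_variable,
                    "liability_weights": self.liability_weights,
                },
                indent=1,
            )
        )


def _informative_labels(config: SimConfig) -> tuple[str, ...]:
    labels: list[str] = []
    kind_by_name = {s.name: s for s in config.variable_specs()}
    for name, w in sorted(config.liability_weights.items()):
        if w == 0:
            continue
        spec = kind_by_name[name]
        if spec.kind == "binary":
            labels.extend(f"{name}:{lab}" for lab in spec.labels)
        else:
            labels.append(f"{name}:{spec.labels[0]}")
            labels.append(f"{name}:{spec.labels[2]}")
    return tuple(labels)


def generate_cohort(config: SimConfig) -> tuple[CohortTable, PlantedTruth]:
    """Draw one cohort under the configured generative model.

    Genotypes are per-SNP Hardy-Weinberg draws (p^2, 2pq, q^2 via a
    Binomial(2, q) allele count).  Continuous phenotypes are the additive
    genetic effects plus correlated Gaussian noise.  Disease liability is a
    weighted sum of standardized phenotypes, centred allele counts and
    binaries plus N(0, sd) noise; the case threshold is the empirical
    (1 - case_fraction) quantile of the pool liability, after which exactly
    ``n_cases`` cases and ``n_controls`` controls are sampled.

    Raises
    ------
    SimulationError
        If the oversampled pool yields too few cases or controls.
    """
    rng = np.random.default_rng(config.seed)
    n_target = config.n_cases + config.n_controls
    frac = config.case_fraction
    pool = int(
        np.ceil(
            max(config.n_cases / frac, config.n_controls / (1 - frac))
            * config.oversample
        )
    )

    G = rng.binomial(2, config.allele_freqs, size=(pool, config.n_snps)).astype(float)
    if config.n_continuous:
        L_noise = rng.multivariate_normal(
            np.zeros(config.n_continuous), config.phenotype_correlation, size=pool,
            method="cholesky",
        )
    else:
        L_noise = np.zeros((pool, 0))
    G_centered = G - 2 * config.allele_freqs
    phenos = G_centered @ config.effect_matrix + L_noise
    binaries = rng.binomial(1, config.binary_prevalence, size=(pool, config.n_binary)).astype(float)

    liability = rng.normal(0.0, config.liability_noise_sd, size=pool)
    cols = {}
    for j, name in enumerate(config.phenotype_names):
        cols[name] = phenos[:, j]
    for j, name in enumerate(config.binary_names):
        cols[name] = binaries[:, j]
    for j, name in enumerate(config.snp_names):
        cols[name] = G[:, j]
    for name, w in config.liability_weights.items():
        if name not in cols:
            raise ValueError(f"liability weight on unknown variable {name!r}")
        x = cols[name]
        if name in config.snp_names:
            z = x - x.mean()
        elif name in config.binary_names:
            z = x
        else:
            z = (x - x.mean()) / x.std()
        liability = liability + w * z

    threshold = np.quantile(liability, 1 - frac)
    is_case = liability > threshold
    case_idx = np.flatnonzero(is_case)
    control_idx = np.flatnonzero(~is_case)
    if case_idx.size < config.n_cases or control_idx.size < config.n_controls:
        raise SimulationError(
            f"pool of {pool} yielded {case_idx.size} cases / {control_idx.size} "
            f"controls; need {config.n_cases}/{config.n_controls}"
        )
    take_cases = rng.choice(case_idx, size=config.n_cases, replace=False)
    take_controls = rng.choice(control_idx, size=config.n_controls, replace=False)
    take = np.concatenate([take_cases, take_controls])
    take.sort()  # interleave cases and controls in pool order

    values = pd.DataFrame(
        {name: cols[name][take] for name in
         config.phenotype_names + config.binary_names + config.snp_names}
    )
    outcome = is_case[take].astype(int)
    individuals = [f"ind{i + 1:04d}" for i in range(n_target)]
    cohort = CohortTable(
        individuals=individuals,
        variables=config.variable_specs(),
        values=values,
        outcome=outcome,
    )
    truth = PlantedTruth(
        informative_indicators=_informative_labels(config),
        hub_variable=config.hub_variable,
        liability_weights=dict(config.liability_weights),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# study-shaped default configurations
# ---------------------------------------------------------------------------


def nphs2_like_config(seed: int = 0) -> SimConfig:
    """Default cohort shaped like the study sample.

    102 cases and 150 controls; 37 SNP loci; 14 continuous risk factors
    (10 circulating biomarkers + 4 anthropometric measures) plus a binary
    smoking-like exposure.  ``SNP01`` is the designated pleiotropic hub
    with effects on six phenotypes, emulating a lipase-gene hub; a handful
    of phenotypes and SNPs carry liability weight so outcome-linked
    structure exists to recover.
    """
    n_snps, n_pheno = 37, 14
    effects = np.zeros((n_snps, n_pheno))
    # hub SNP: moderate effect on six phenotypes
    effects[0, :6] = 0.6
    # a few focal SNP->phenotype effects
    effects[1, 6] = 0.5
    effects[2, 7] = 0.5
    effects[3, 8] = 0.4
    # modest block correlation among the first six phenotypes (lipid-like axis)
    corr = np.eye(n_pheno)
    corr[:6, :6] = np.where(np.eye(6, dtype=bool), 1.0, 0.35)
    weights = {
        "pheno01": 0.5,
        "pheno02": 0.4,
        "pheno07": 0.4,
        "bin1": 0.6,
        "SNP02": 0.3,
        "SNP05": 0.3,
    }
    return SimConfig(
        n_cases=102,
        n_controls=150,
        n_snps=n_snps,
        n_continuous=n_pheno,
        n_binary=1,
        effect_matrix=effects,
        phenotype_correlation=corr,
        liability_weights=weights,
        hub_variable="SNP01",
        seed=seed,
    )


def recovery_config(seed: int = 0) -> SimConfig:
    """Small cohort for feature-selection recovery studies.

    300 cases / 300 controls; two informative SNPs with a strong per-allele
    liability effect among eight noise SNPs and two noise binaries, giving
    34 indicator columns of which the four extreme-genotype columns of the
    informative SNPs are planted truth.
    """
    n_snps = 10
    freqs = np.full(n_snps, 0.5)
    return SimConfig(
        n_cases=300,
        n_controls=300,
        n_snps=n_snps,
        n_continuous=0,
        n_binary=2,
        allele_freqs=freqs,
        liability_weights={"SNP01": 1.0, "SNP02": 1.0},
        case_fraction=0.5,
        oversample=1.6,
        seed=seed,
    )


def noise_config(seed: int = 0) -> SimConfig:
    """Pure-noise variant of :func:`recovery_config`: no liability weights,
    so the outcome is independent of every variable."""
    cfg = recovery_config(seed)
    cfg.liability_weights = {}
    return cfg


def generate_contrast_cohort(
    n_per_group: int = 150,
    n_vars: int = 12,
    block_size: int = 6,
    case_corr: float = 0.45,
    control_corr: float = 0.85,
    seed: int = 0,
) -> CohortTable:
    """Paired groups differing only in inter-variable correlation density.

    Both groups share the same continuous variables arranged in correlation
    blocks; the control group's within-block correlations are denser than
    the cases'.  The outcome column *is* group membership (1 = case), so
    per-group network complexity can be contrasted without any marginal
    outcome association confounding the comparison.
    """
    rng = np.random.default_rng(seed)

    def block_corr(r: float) -> np.ndarray:
        C = np.eye(n_vars)
        for start in range(0, n_vars, block_size):
            stop = min(start + block_size, n_vars)
            blk = slice(start, stop)
            sub = np.full((stop - start, stop - start), r)
            np.fill_diagonal(sub, 1.0)
            C[blk, blk] = sub
        return C

    mean = np.zeros(n_vars)
    cases = rng.multivariate_normal(mean, block_corr(case_corr), size=n_per_group,
                                    method="cholesky")
    controls = rng.multivariate_normal(mean, block_corr(control_corr), size=n_per_group,
                                       method="cholesky")
    values = pd.DataFrame(
        np.vstack([cases, controls]),
        columns=[f"var{i + 1:02d}" for i in range(n_vars)],
    )
    outcome = np.concatenate([np.ones(n_per_group, int), np.zeros(n_per_group, int)])
    return CohortTable(
        individuals=[f"ind{i + 1:04d}" for i in range(2 * n_per_group)],
        variables=[VariableSpec(c, "continuous") for c in values.columns],
        values=values,
        outcome=outcome,
    )


def write_cohort(cohort: CohortTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write a cohort as CSV plus the YAML schema ``datamodel`` reads back."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    schema_path = prefix.with_suffix(".schema.yaml")
    df = cohort.values.copy()
    df.insert(0, "id", cohort.individuals)
    df["outcome"] = cohort.outcome
    df.to_csv(csv_path, index=False)
    schema = {
        "outcome": "outcome",
        "variables": [
            {"name": s.name, "kind": s.kind, "labels": list(s.labels)}
            for s in cohort.variables
        ],
    }
    schema_path.write_text(yaml.safe_dump(schema, sort_keys=False))
    return csv_path, schema_path
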