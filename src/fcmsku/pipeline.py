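"""I/O, the genome-wide FC-mSKU runner, and the simulation-study harness.

File formats: TSV tables keyed by a sample-id first column (phenotypes,
covariates), a samples x SNPs genotype TSV, the PLINK .bed/.bim/.fam triple
(additive minor-allele coding), and GMT pathway files.  The harness
regenerates the type-I-error and power study: per replicate it simulates a
fresh single-pathway dataset, runs mSKU per phenotype on the full SNP block,
combines the t marginal p-values with the dependence-adjusted Fisher method,
and reports the rejection proportion at the nominal level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .fc import PhenotypeCorrelation, fc_combine, phenotype_correlation
from .kernels import KernelSpec, center_kernel, default_kernel_bundle, kernel_matrix
from .msku import MaxKernelResult, _KernelEnsemble, max_statistic_pvalue, msku_test
from .synthdata import (
    CovariateMatrix,
    GenotypeMatrix,
    PhenotypeMatrix,
    SimulationConfig,
    make_scenario_pq_coefficients,
    scenario_h,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
)

__all__ = [
    "PathwaySet",
    "SimulationReport",
    "read_genotypes",
    "read_table",
    "read_pathways",
    "write_genotypes_tsv",
    "write_table",
    "write_plink",
    "run_study",
    "simulation_study",
]

logger = logging.getLogger("fcmsku")


@dataclass
class PathwaySet:
    """Named SNP sets; names unique, member lists non-empty and deduplicated."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class SimulationReport:
    """Empirical rejection rate of one simulation-study cell."""

    config: SimulationConfig
    rejection_rate: float
    mc_se: float
    n_replicates: int
    seed: int
    marginal_rejection_rates: list[float] = field(default_factory=list)
    global_pvalues: Optional[np.ndarray] = None
    marginal_pvalues: Optional[np.ndarray] = None  # B x t when collected

    def to_dict(self) -> dict:
        cfg = {k: v for k, v in vars(self.config).items() if v is not None}
        return {
            "config": cfg,
            "rejection_rate": self.rejection_rate,
            "mc_se": self.mc_se,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "marginal_rejection_rates": self.marginal_rejection_rates,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_table(values: np.ndarray, names: Sequence[str],
                sample_ids: Sequence[str], path: Union[str, Path]) -> None:
    """Write a sample-keyed TSV (phenotypes or covariates)."""
    df = pd.DataFrame(values, columns=list(names))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Union[str, Path]) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a sample-keyed TSV; returns (values, column names, sample ids)."""
    df = pd.read_csv(path, sep="\t")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return values, list(df.columns[1:]), sample_ids


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(genotypes.values, columns=genotypes.snp_ids)
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def _read_genotypes_tsv(path: Union[str, Path]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.isfinite(raw) & ~np.isin(raw, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype token {raw[i, j]!r} at sample {sample_ids[i]}, "
            f"SNP {snp_ids[j]} is not in {{0,1,2,NA}}"
        )
    raw = _impute_missing(raw)
    return GenotypeMatrix(values=raw.astype(np.int8), snp_ids=snp_ids,
                          sample_ids=sample_ids)


def _impute_missing(raw: np.ndarray) -> np.ndarray:
    """Round-the-mean imputation per SNP for missing genotypes, logged."""
    missing = ~np.isfinite(raw)
    if missing.any():
        logger.info("imputing %d missing genotypes to rounded SNP means",
                    int(missing.sum()))
        col_mean = np.nanmean(np.where(missing, np.nan, raw), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        raw = np.where(missing, fill[None, :], raw)
    return raw


# Minimal PLINK 1 .bed/.bim/.fam codec (SNP-major).  Two-bit codes per the
# PLINK spec: 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2; the additive
# dosage counts A1 (minor) alleles.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSE = np.array([2, -1, 1, 0], dtype=np.int8)  # -1 marks missing
_DOSE_TO_CODE = {2: 0, 1: 2, 0: 3}


def write_plink(genotypes: GenotypeMatrix, prefix: Union[str, Path]) -> None:
    prefix = Path(prefix)
    n, p = genotypes.values.shape
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.empty((p, n), dtype=np.uint8)
        for dose, code in _DOSE_TO_CODE.items():
            codes[genotypes.values.T == dose] = code
        nbytes = (n + 3) // 4
        packed = np.zeros((p, nbytes * 4), dtype=np.uint8)
        packed[:, :n] = codes
        packed = packed.reshape(p, nbytes, 4)
        byte = (packed[:, :, 0] | (packed[:, :, 1] << 2)
                | (packed[:, :, 2] << 4) | (packed[:, :, 3] << 6))
        fh.write(byte.astype(np.uint8).tobytes())
    bim = pd.DataFrame({
        "chrom": 1, "snp": genotypes.snp_ids, "cm": 0,
        "pos": np.arange(1, p + 1), "a1": "A", "a2": "G",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame({
        "fid": genotypes.sample_ids, "iid": genotypes.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)


def _read_plink(prefix: Union[str, Path]) -> GenotypeMatrix:
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing PLINK file {prefix.with_suffix(ext)}")
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    snp_ids = bim[1].astype(str).tolist()
    sample_ids = fam[1].astype(str).tolist()
    n, p = len(sample_ids), len(snp_ids)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    nbytes = (n + 3) // 4
    body = np.frombuffer(data[3:], dtype=np.uint8).reshape(p, nbytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = ((body[:, :, None] >> shifts) & 0b11).reshape(p, nbytes * 4)[:, :n]
    dose = _CODE_TO_DOSE[codes].T.astype(float)  # n x p
    dose[dose < 0] = np.nan
    dose = _impute_missing(np.where(np.isnan(dose), np.nan, dose))
    return GenotypeMatrix(values=dose.astype(np.int8), snp_ids=snp_ids,
                          sample_ids=sample_ids)


def read_genotypes(path: Union[str, Path], format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a TSV table or a PLINK prefix."""
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError("format must be 'tsv' or 'plink'")


def read_pathways(path: Union[str, Path], min_snps: int = 2) -> PathwaySet:
    """Read a GMT file (name, description, members per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line {lineno}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate pathway name {name!r} (line {lineno})")
        members = list(dict.fromkeys(m for m in parts[2:] if m))
        if len(members) < min_snps:
            logger.warning("dropping pathway %s with %d member(s) (< %d)",
                           name, len(members), min_snps)
            continue
        sets[name] = members
    return PathwaySet(sets=sets)


# ---------------------------------------------------------------------------
# Genome-wide runner
# ---------------------------------------------------------------------------


def run_study(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    covariates: CovariateMatrix,
    pathways: PathwaySet,
    kernel_bundle: Optional[Sequence[KernelSpec]] = None,
    screening_label: Optional[np.ndarray] = None,
    alpha_m: float = 0.05,
    bh: bool = False,
    with_records: bool = False,
) -> Union[pd.DataFrame, tuple[pd.DataFrame, pd.DataFrame]]:
    """Run FC-mSKU for every pathway; one row per tested pathway.

    Columns: pathway id, SNP counts, one marginal p per phenotype, the
    combined global p, and (optionally) its Benjamini-Hochberg adjustment.
    Pathways with no SNP present in the genotype matrix are skipped.
    Kernel matrices are built per pathway and released before the next one.
    With ``with_records`` a second table is returned holding one detailed
    row per pathway x phenotype test (per-kernel Q values, Q_max, p,
    screening flag).
    """
    if kernel_bundle is None:
        kernel_bundle = default_kernel_bundle()
    if phenotypes.values.shape[0] != genotypes.n_samples:
        raise ValueError("phenotype / genotype sample counts differ")
    corr = phenotype_correlation(phenotypes, covariates)
    known = set(genotypes.snp_ids)
    rows = []
    records = []
    for name, members in pathways.items():
        present = [s for s in members if s in known]
        if not present:
            logger.info("skipping pathway %s: no SNPs in genotype matrix", name)
            continue
        row: dict = {"pathway": name, "n": genotypes.n_samples,
                     "snps_in_pathway": len(members)}
        marginals = []
        snps_used = None
        for k, pname in enumerate(phenotypes.names):
            res = msku_test(
                genotypes, present, phenotypes.values[:, k], covariates,
                kernel_bundle, screening_label=screening_label, alpha_m=alpha_m,
            )
            marginals.append(res.p_value)
            snps_used = res.snps_used
            row[f"p_{pname}"] = res.p_value
            if with_records:
                records.append(res.to_record(name, pname, len(members)))
        row["snps_used"] = snps_used
        row["global_p"] = fc_combine(np.array(marginals), corr).global_p
        rows.append(row)
    if not rows:
        raise ValueError("no testable pathway: all SNP sets absent from genotypes")
    table = pd.DataFrame(rows)
    if bh:
        table["global_p_bh"] = multipletests(table["global_p"], method="fdr_bh")[1]
    if with_records:
        return table, pd.DataFrame(records)
    return table


# ---------------------------------------------------------------------------
# Simulation-study harness
# ---------------------------------------------------------------------------


def _replicate_seeds(master_seed: int, replicate: int, n_streams: int) -> list[int]:
    """Independent integer seeds for one replicate (counter-based)."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(replicate)))
    return [int(s) for s in ss.generate_state(n_streams)]


def _study_seed(master_seed: int) -> int:
    """Seed for study-level draws frozen across replicates (P/Q effect sets)."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), 0, 1))
    return int(ss.generate_state(1)[0])


def simulate_replicate(
    config: SimulationConfig,
    replicate: int,
    coefficients=None,
) -> tuple[GenotypeMatrix, CovariateMatrix, PhenotypeMatrix]:
    """Generate one replicate's dataset under the configured scenario."""
    sg, sc, sp = _replicate_seeds(config.seed, replicate, 3)
    geno = simulate_genotypes(config.n, config.p, config.maf_low,
                              config.maf_high, config.ld_r, seed=sg)
    covar = simulate_covariates(config.n, seed=sc)
    h = scenario_h(geno, config.scenario, coefficients,
                   b_p=config.b_p, b_q=config.b_q)
    pheno = simulate_phenotypes(geno, covar, h, t=config.t, rho=config.rho,
                                error_sd=config.error_sd, seed=sp)
    return geno, covar, pheno


def _global_p_one_replicate(
    geno: GenotypeMatrix,
    covar: CovariateMatrix,
    pheno: PhenotypeMatrix,
    kernel_bundle: Sequence[KernelSpec],
) -> tuple[float, np.ndarray]:
    """FC-mSKU global p treating the full SNP block as one pathway.

    Shares the centred kernels across phenotypes; returns (global p,
    marginal p-values).
    """
    X = geno.values.astype(float)
    n, t = X.shape[0], pheno.values.shape[1]
    design = np.column_stack([np.ones(n), covar.values])
    coef, *_ = np.linalg.lstsq(design, pheno.values, rcond=None)
    E = pheno.values - design @ coef
    centered = [center_kernel(kernel_matrix(X, spec)) for spec in kernel_bundle]
    ens = _KernelEnsemble(centered)
    _, V, Q = ens.stats(E)
    marginal = np.empty(t)
    for k in range(t):
        omega = ens.correlation(E[:, k])
        marginal[k] = max_statistic_pvalue(float(Q[:, k].max()), omega)
    corr = phenotype_correlation(pheno, covar)
    return fc_combine(marginal, corr).global_p, marginal


def simulation_study(
    config: SimulationConfig,
    kernel_bundle: Optional[Sequence[KernelSpec]] = None,
    collect_pvalues: bool = False,
) -> SimulationReport:
    """Empirical rejection rate of FC-mSKU over ``config.n_replicates``.

    Each replicate simulates fresh genotypes, covariates and phenotypes,
    treats the whole simulated SNP block as one pathway, runs mSKU for each
    of the t phenotypes (no screening: the generator has no auxiliary
    label), and FC-combines the marginals.  Scenario P/Q coefficient sets
    are drawn once from the master seed and frozen across replicates.
    Replicate seeds derive from (master seed, replicate index), so any
    subset of replicates is independently reproducible.
    """
    if kernel_bundle is None:
        kernel_bundle = default_kernel_bundle()
    coefficients = None
    if config.scenario in ("P", "Q"):
        coefficients = make_scenario_pq_coefficients(
            config.p, seed=_study_seed(config.seed)
        )
    B = config.n_replicates
    global_ps = np.empty(B)
    marginal_ps = np.empty((B, config.t))
    for rep in range(B):
        geno, covar, pheno = simulate_replicate(config, rep, coefficients)
        gp, marginal = _global_p_one_replicate(geno, covar, pheno, kernel_bundle)
        global_ps[rep] = gp
        marginal_ps[rep] = marginal
    rate = float((global_ps < config.alpha_level).mean())
    return SimulationReport(
        config=config,
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1 - rate) / B)),
        n_replicates=B,
        seed=config.seed,
        marginal_rejection_rates=(marginal_ps < config.alpha_level)
        .mean(axis=0)
        .tolist(),
        global_pvalues=global_ps if collect_pvalues else None,
        marginal_pvalues=marginal_ps if collect_pvalues else None,
    )
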