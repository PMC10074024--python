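"""Readers and writers: phased VCF, IMPUTE2 haps/sample, phenotype TSV,
and the JSON/TSV run report.

Conventions: SNP positions are 0-based within the region, left to right
in genomic coordinate order of the input file; the REF allele maps to
'0' and the ALT allele to '1'.  Region filters use 1-based inclusive
coordinates (the VCF convention).  Unphased diploid genotypes are a hard
error — template dosages are meaningless without phase.  Samples with
missing alleles in the region are dropped by default (logged), or
imputed to the major allele on request.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cv_engines import HtrxResult
from .dosage import HaplotypePanel, build_dosage_matrix
from .model_fit import PhenotypeTable

__all__ = [
    "read_phased_genotypes",
    "read_phenotypes",
    "write_phased_vcf",
    "write_haps_sample",
    "write_phenotypes",
    "RunReport",
    "write_report",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, 2**62
    start, _, end = span.partition("-")
    return chrom, int(start), int(end) if end else int(start)


def _finish_panel(
    alleles: np.ndarray,
    snp_ids: list[str],
    sample_ids: list[str],
    drop_missing: bool,
) -> HaplotypePanel:
    """alleles: (n, ploidy, u) int8 with -1 for missing."""
    any_missing = (alleles < 0).any(axis=(1, 2))
    if any_missing.any():
        if drop_missing:
            kept = ~any_missing
            logger.warning(
                "dropping %d/%d samples with missing alleles in the region",
                int(any_missing.sum()),
                alleles.shape[0],
            )
            alleles = alleles[kept]
            sample_ids = [s for s, k in zip(sample_ids, kept) if k]
        else:
            for j in range(alleles.shape[2]):
                site = alleles[:, :, j]
                obs = site[site >= 0]
                major = 1 if obs.size and obs.mean() > 0.5 else 0
                site[site < 0] = major
            logger.warning("imputed missing alleles to the major allele")
    if alleles.shape[2] == 0:
        raise ValueError("zero SNPs in the requested region")
    return HaplotypePanel(
        alleles.astype(np.uint8), snp_ids, list(sample_ids)
    )


def _read_vcf(
    path: str | Path, region: str | None, drop_missing: bool
) -> HaplotypePanel:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    want = _parse_region(region) if region else None
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    ploidy: int | None = None
    for var in vcf:
        if want is not None:
            chrom, start, end = want
            if var.CHROM != chrom or not (start <= var.POS <= end):
                continue
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d (%s/%s)",
                var.CHROM,
                var.POS,
                var.REF,
                ",".join(var.ALT),
            )
            continue
        gts = var.genotypes  # per sample: [a0, (a1,) phased_bool]
        site = []
        for s, g in enumerate(gts):
            alleles = [a for a in g[:-1] if a is not None]
            phased = bool(g[-1])
            if len(alleles) >= 2 and not phased and -1 not in alleles:
                raise ValueError(
                    f"unphased genotype for sample {samples[s]} at "
                    f"{var.CHROM}:{var.POS} ('/' separator); phase the data first"
                )
            site.append(alleles)
        width = max(len(a) for a in site)
        if ploidy is None:
            ploidy = width
        if width != ploidy:
            raise ValueError(f"inconsistent ploidy at {var.CHROM}:{var.POS}")
        arr = np.array(
            [a + [-1] * (ploidy - len(a)) for a in site], dtype=np.int8
        )
        cols.append(arr)
        snp_ids.append(var.ID if var.ID and var.ID != "." else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError("zero SNPs in the requested region")
    alleles = np.stack(cols, axis=2)  # (n, ploidy, u)
    return _finish_panel(alleles, snp_ids, samples, drop_missing)


def _read_haps(
    path: str | Path, region: str | None, drop_missing: bool
) -> HaplotypePanel:
    path = Path(path)
    sample_path = path.with_suffix(".sample")
    haps = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    samp = pd.read_csv(sample_path, sep=r"\s+")
    sample_ids = samp["ID_1"].astype(str).tolist()[1:]  # row 0 is the type row
    want = _parse_region(region) if region else None
    n = len(sample_ids)
    n_hap_cols = haps.shape[1] - 5
    if n_hap_cols % n != 0:
        raise ValueError(".haps column count does not match .sample IDs")
    ploidy = n_hap_cols // n
    rows: list[np.ndarray] = []
    snp_ids: list[str] = []
    for _, row in haps.iterrows():
        chrom, rsid, pos = str(row[0]), str(row[1]), int(row[2])
        if want is not None:
            wchrom, start, end = want
            if chrom != wchrom or not (start <= pos <= end):
                continue
        vals = row.iloc[5:].to_numpy()
        arr = np.where(np.isin(vals, ["0", "1"]), vals, "-1").astype(np.int8)
        rows.append(arr.reshape(n, ploidy))
        snp_ids.append(rsid if rsid not in (".", "nan") else f"{chrom}:{pos}")
    if not rows:
        raise ValueError("zero SNPs in the requested region")
    alleles = np.stack(rows, axis=2)
    return _finish_panel(alleles, snp_ids, sample_ids, drop_missing)


def read_phased_genotypes(
    path: str | Path,
    region: str | None = None,
    drop_missing: bool = True,
) -> HaplotypePanel:
    """Load a phased panel from VCF or IMPUTE2 ``.haps``/``.sample``.

    The format is chosen by extension (``.haps`` vs anything VCF-like).
    ``region`` is ``chrom:start-end`` with 1-based inclusive bounds.
    """
    p = Path(path)
    if p.suffix == ".haps":
        return _read_haps(p, region, drop_missing)
    return _read_vcf(p, region, drop_missing)


def read_phenotypes(
    path: str | Path,
    outcome_column: str,
    covariate_columns: list[str] | None = None,
    panel: HaplotypePanel | None = None,
    family: str | None = None,
    id_column: str = "sample_id",
) -> PhenotypeTable:
    """Load a phenotype TSV and align it to a genotype panel.

    Inner-joins on sample ID in panel order.  Any panel sample missing
    from the table is a hard error.  The family is auto-detected (a 0/1
    outcome gives ``logistic``) unless ``family`` overrides it.
    """
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    covariate_columns = covariate_columns or []
    cols = [id_column, outcome_column, *covariate_columns]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file lacks columns {missing_cols}")
    df = df.dropna(subset=cols).set_index(id_column)
    sample_ids = None
    if panel is not None:
        if panel.sample_ids is None:
            raise ValueError("panel has no sample IDs to join on")
        unmatched = [s for s in panel.sample_ids if s not in df.index]
        if unmatched:
            raise ValueError(
                f"{len(unmatched)} panel samples missing from phenotype file, "
                f"e.g. {unmatched[:5]}"
            )
        df = df.loc[panel.sample_ids]
        sample_ids = list(panel.sample_ids)
    y = df[outcome_column].to_numpy(dtype=float)
    if family is None:
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    cov = df[covariate_columns].to_numpy(dtype=float) if covariate_columns else None
    return PhenotypeTable(y, cov, family, sample_ids)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path, chrom: str = "1") -> None:
    """Write a panel as a minimal phased VCF (text, GT only)."""
    ids = panel.sample_ids or [f"sample{i}" for i in range(panel.n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j in range(panel.u):
            site = panel.haplotypes[:, :, j]
            gts = ["|".join(str(a) for a in row) for row in site]
            fh.write(
                f"{chrom}\t{j + 1}\t{panel.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_haps_sample(panel: HaplotypePanel, prefix: str | Path, chrom: str = "1") -> None:
    """Write a panel as IMPUTE2 ``.haps`` + ``.sample`` files."""
    prefix = Path(prefix)
    ids = panel.sample_ids or [f"sample{i}" for i in range(panel.n)]
    with open(prefix.with_suffix(".haps"), "w") as fh:
        for j in range(panel.u):
            site = panel.haplotypes[:, :, j].reshape(-1)
            fh.write(
                f"{chrom} {panel.snp_ids[j]} {j + 1} A G "
                + " ".join(str(a) for a in site)
                + "\n"
            )
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in ids:
            fh.write(f"{s} {s} 0\n")


def write_phenotypes(
    pheno: PhenotypeTable,
    path: str | Path,
    covariate_names: list[str] | None = None,
) -> None:
    """Write a phenotype table as TSV with a sample_id column."""
    ids = pheno.sample_ids or [f"sample{i}" for i in range(pheno.n)]
    data = {"sample_id": ids, "outcome": pheno.y}
    names = covariate_names or [f"cov{j}" for j in range(pheno.n_covariates)]
    for j, nm in enumerate(names):
        data[nm] = pheno.covariates[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


@dataclass
class RunReport:
    """Everything needed to reproduce and interpret one HTRX run."""

    config: dict
    n: int
    u: int
    family: str
    snp_ids: list[str]
    algorithm: str
    winner: list[str]
    fold_test_r2: list[float]
    mean_r2: float
    z: int
    null_model_selected: bool
    candidate_log: list[dict] = field(default_factory=list)
    winner_coefficients: dict[str, float] = field(default_factory=dict)
    winner_frequencies: dict[str, float] = field(default_factory=dict)
    version: str = ""
    master_seed: int | None = None
    schema_version: int = REPORT_SCHEMA_VERSION


def build_report(
    cfg,
    panel: HaplotypePanel,
    pheno: PhenotypeTable,
    result: HtrxResult,
) -> RunReport:
    """Assemble a :class:`RunReport`, refitting the winner on all data
    for reportable coefficients and template frequencies."""
    from . import __version__
    from .model_fit import fit_glm

    winner = list(result.winner or ())
    coefs: dict[str, float] = {}
    freqs: dict[str, float] = {}
    if winner:
        dos = build_dosage_matrix(panel, winner)
        model = fit_glm(dos.to_numpy(), pheno, feature_names=winner)
        offset = 1 + pheno.n_covariates
        coefs = {t: float(model.coef[offset + i]) for i, t in enumerate(winner)}
        freqs = {t: float(dos[t].mean()) for t in winner}
    cand_log = [
        {
            "templates": list(c.templates),
            "penalty": c.penalty,
            "criterion": None if np.isnan(c.criterion) else float(c.criterion),
            "replicate": c.source,
        }
        for c in result.candidates
    ]
    return RunReport(
        config=dataclasses.asdict(cfg),
        n=panel.n,
        u=panel.u,
        family=pheno.family,
        snp_ids=list(panel.snp_ids),
        algorithm=result.algorithm,
        winner=winner,
        fold_test_r2=[float(v) for v in result.fold_test_r2],
        mean_r2=float(result.mean_r2),
        z=result.z,
        null_model_selected=result.null_model_selected,
        candidate_log=cand_log,
        winner_coefficients=coefs,
        winner_frequencies=freqs,
        version=__version__,
        master_seed=cfg.seed,
    )


def write_report(report: RunReport, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` (machine) and ``<prefix>.tsv`` (human).

    The TSV lists the winning templates with coefficient and frequency;
    the JSON carries the full report and round-trips losslessly.
    """
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    tsv_path = prefix.with_suffix(".tsv")
    with open(json_path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
        fh.write("\n")
    rows = [
        {
            "template": t,
            "coefficient": report.winner_coefficients.get(t, float("nan")),
            "frequency": report.winner_frequencies.get(t, float("nan")),
        }
        for t in report.winner
    ]
    df = pd.DataFrame(rows, columns=["template", "coefficient", "frequency"])
    df.to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path
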