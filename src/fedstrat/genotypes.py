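"""Genotype dosage matrices: containers, I/O, QC filtering, and SNP alignment.

Genotypes are stored as minor-allele dosages (0, 1, or 2 minor alleles per
diploid sample), the standard encoding for PCA-based ancestry analysis.
Missing genotypes are represented as NaN in memory and as ``NA`` on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: token used for missing genotypes in the TSV dialect
MISSING_TOKEN = "NA"


class GenotypeFormatError(ValueError):
    """Raised when an input file cannot be parsed as genotypes."""


class EmptyAfterQCError(ValueError):
    """Raised when quality-control filtering removes every SNP."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {kind} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """A samples × SNPs minor-allele dosage matrix.

    Parameters
    ----------
    values
        ``n × m`` array; every non-missing entry must be 0, 1 or 2 and
        missing entries are NaN.
    sample_ids
        ``n`` unique sample identifiers (row order).
    snp_ids
        ``m`` unique SNP identifiers in the canonical column order shared
        by all parties of the protocol.
    population_labels
        Optional ground-truth population per sample; used only for
        evaluation, never by the protocol itself.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)
    population_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x SNPs array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} snp_ids for {m} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0/1/2 or missing, got {bad}")
        if self.population_labels is not None:
            self.population_labels = [str(p) for p in self.population_labels]
            if len(self.population_labels) != n:
                raise ValueError("population_labels length must match samples")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    # -- per-SNP summaries ---------------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Fraction of missing genotypes per SNP."""
        return np.isnan(self.values).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing genotypes.

        Columns with no observed genotypes yield NaN.
        """
        obs = ~np.isnan(self.values)
        counts = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(self.values, axis=0) / (2.0 * counts)
        p = np.where(counts == 0, np.nan, p)
        return np.minimum(p, 1.0 - p)

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted (dosage) allele per SNP."""
        obs = ~np.isnan(self.values)
        counts = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(self.values, axis=0) / (2.0 * counts)
        return np.where(counts == 0, np.nan, p)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        labels = (
            [self.population_labels[i] for i in index]
            if self.population_labels is not None
            else None
        )
        return GenotypeMatrix(
            self.values[index, :].copy(),
            [self.sample_ids[i] for i in index],
            list(self.snp_ids),
            labels,
        )

    def take_snps(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            self.values[:, index].copy(),
            list(self.sample_ids),
            [self.snp_ids[i] for i in index],
            list(self.population_labels) if self.population_labels else None,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
        )
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise GenotypeFormatError(f"cannot parse {path} as genotype TSV: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise GenotypeFormatError(f"non-numeric dosage in {path}: {exc}") from exc
    return GenotypeMatrix(values, [str(s) for s in df.index], [str(c) for c in df.columns])


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: htslib import is heavyweight

    try:
        reader = VCF(str(path))
    except Exception as exc:  # noqa: BLE001
        raise GenotypeFormatError(f"cannot open {path} as VCF: {exc}") from exc
    samples = list(reader.samples)
    columns: list[np.ndarray] = []
    snp_ids: list[str] = []
    for var in reader:
        if len(var.ALT) != 1:
            log.warning("skipping non-biallelic record %s:%s", var.CHROM, var.POS)
            continue
        alt = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:2]]
            if any(a < 0 for a in alleles):
                continue
            alt[i] = float(sum(1 for a in alleles if a == 1))
        # orient to the minor allele observed in this file; ties count ALT
        obs = alt[~np.isnan(alt)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            alt = 2.0 - alt
        snp_ids.append(var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}")
        columns.append(alt)
    values = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(values, samples, snp_ids)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or the package's TSV dialect.

    VCF genotypes are converted to minor-allele dosages: the minor allele is
    the one with frequency <= 0.5 in the file itself, so a SNP whose REF
    allele is minor is stored as ``2 - ALT count``. Missing GTs become NaN.
    Non-biallelic records are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a genotype matrix as TSV (header: sample_id + SNP ids)."""
    if format != "tsv":
        raise ValueError(f"unsupported output format: {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.snp_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.values):
            cells = [MISSING_TOKEN if np.isnan(v) else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_population_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id/population TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeFormatError(f"{path}: expected columns sample_id, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_population_labels(g: GenotypeMatrix, path: str | Path) -> None:
    if g.population_labels is None:
        raise ValueError("matrix carries no population labels")
    pd.DataFrame(
        {"sample_id": g.sample_ids, "population": g.population_labels}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and alignment
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix, maf_min: float = 0.01, missing_max: float = 0.05
) -> GenotypeMatrix:
    """Drop SNPs with MAF below ``maf_min`` or missing rate above ``missing_max``.

    Samples are untouched and the relative SNP order is preserved. The MAF is
    computed over non-missing genotypes only.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must lie in [0, 1]")
    maf = g.maf()
    # a column with no observed genotypes has undefined MAF: it can only
    # survive when the MAF filter is disabled (maf_min == 0)
    maf_ok = np.where(np.isnan(maf), maf_min <= 0.0, maf >= maf_min)
    keep = np.flatnonzero(maf_ok & (g.missing_rate() <= missing_max))
    if keep.size == 0:
        raise EmptyAfterQCError(
            f"no SNPs survive QC (maf_min={maf_min}, missing_max={missing_max})"
        )
    return g.take_snps(keep)


def restrict_to_snps(g: GenotypeMatrix, snp_ids: Sequence[str]) -> GenotypeMatrix:
    """Subset/reorder columns to an agreed SNP list (e.g. a trained model's)."""
    pos = {s: j for j, s in enumerate(g.snp_ids)}
    absent = [s for s in snp_ids if s not in pos]
    if absent:
        raise ValueError(f"matrix lacks {len(absent)} requested SNPs, e.g. {absent[0]!r}")
    return g.take_snps([pos[s] for s in snp_ids])


def align_snp_sets(matrices: Sequence[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict all matrices to their common SNPs in lexicographic order.

    All parties of the protocol must agree on the SNP set and its order;
    this produces that canonical ordering.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to align")
    shared = set(matrices[0].snp_ids)
    for g in matrices[1:]:
        shared &= set(g.snp_ids)
    if not shared:
        raise ValueError("SNP intersection across matrices is empty")
    order = sorted(shared)
    out = []
    for g in matrices:
        pos = {s: j for j, s in enumerate(g.snp_ids)}
        out.append(g.take_snps([pos[s] for s in order]))
    return out
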