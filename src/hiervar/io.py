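"""Core data containers and readers/writers.

The tool touches three tabular inputs — genotypes (VCF), per-variant
functional-score annotations (TSV), and per-sample phenotypes (TSV) —
and writes three result tables (per-variant fits, ROC points, AUC
summary). Variant identity throughout is the string
``"chrom:pos:ref:alt"`` with the 1-based VCF position.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Placeholder written to TSV cells that are not applicable
#: (e.g. ``true_causal`` in real-data mode).
NA_TOKEN = "."


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele-count (dosage) matrix.

    Every dosage is in {0, 1, 2} and every variant column has at least
    one nonzero entry: monomorphic ("unobserved") variants are dropped
    at read time and are invalid here.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not np.issubdtype(self.dosages.dtype, np.integer):
            if not np.all(self.dosages == np.floor(self.dosages)):
                raise ValueError("dosages must be integers (no imputed dosages)")
            self.dosages = self.dosages.astype(np.int64)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variant_ids) != m:
            raise ValueError(f"{len(self.variant_ids)} variant ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant ids")
        if self.dosages.size:
            if self.dosages.min() < 0 or self.dosages.max() > 2:
                raise ValueError("dosage entries must be in {0, 1, 2}")
        if m and not np.all(self.dosages.sum(axis=0) >= 1):
            bad = [v for v, s in zip(self.variant_ids, self.dosages.sum(axis=0)) if s == 0]
            raise ValueError(f"monomorphic (unobserved) variant columns: {bad[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def carrier_matrix(self) -> np.ndarray:
        """Dominant coding: 1 if the individual carries >=1 alternate allele."""
        return (self.dosages > 0).astype(np.int64)


@dataclass
class AnnotationTable:
    """Per-variant functional score (C-score, CADD-PHRED-like units)."""

    variant_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) != len(self.variant_ids):
            raise ValueError("one score per variant id required")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in annotation table")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite functional scores")

    def reindex(self, variant_ids: list[str]) -> "AnnotationTable":
        """Return scores aligned to ``variant_ids``; missing ids are an error."""
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in lookup]
        if missing:
            raise KeyError(
                f"variant(s) absent from annotation table: {missing[:5]}"
            )
        idx = [lookup[v] for v in variant_ids]
        return AnnotationTable(list(variant_ids), self.scores[idx])


@dataclass
class PhenotypeTable:
    """Per-sample phenotype: continuous value and/or binary case status."""

    sample_ids: list[str]
    y_continuous: np.ndarray | None = None
    case_status: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype table")
        if self.y_continuous is not None:
            self.y_continuous = np.asarray(self.y_continuous, dtype=float)
            if len(self.y_continuous) != len(self.sample_ids):
                raise ValueError("y_continuous length mismatch")
        if self.case_status is not None:
            self.case_status = np.asarray(self.case_status, dtype=np.int64)
            if len(self.case_status) != len(self.sample_ids):
                raise ValueError("case_status length mismatch")
            if not np.isin(self.case_status, [0, 1]).all():
                raise ValueError("case_status must be 0/1")

    def require_cases_and_controls(self) -> None:
        if self.case_status is None:
            raise ValueError("case_status not set")
        n_case = int(self.case_status.sum())
        if n_case == 0 or n_case == len(self.case_status):
            raise ValueError("need at least one case and one control")


def check_aligned(genotypes: GenotypeMatrix, annotations: AnnotationTable) -> None:
    """Refuse to proceed unless the two sources describe the same variants."""
    g, a = set(genotypes.variant_ids), set(annotations.variant_ids)
    if g != a:
        only_g = sorted(g - a)[:5]
        only_a = sorted(a - g)[:5]
        raise ValueError(
            "variant id mismatch between genotypes and annotations; "
            f"genotype-only: {only_g}, annotation-only: {only_a}"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, strict_missing: bool = False) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF (plain or bgzipped) into dosages.

    Dosage is the alternate-allele count of the GT field. Missing
    genotypes (``./.``) count as reference (dosage 0) and are tallied in
    a warning, unless ``strict_missing`` is set, in which case they are
    an error. Multiallelic records and non-SNVs are skipped with a
    warning; monomorphic columns are dropped.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in VCF {path}")

    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    n_missing = 0
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping multiallelic record %s:%s", rec.CHROM, rec.POS)
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            logger.warning("skipping non-SNV record %s:%s", rec.CHROM, rec.POS)
            continue
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        if gts is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        dosage = np.zeros(len(samples), dtype=np.int64)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            miss = sum(1 for a in alleles if a < 0)
            if miss:
                if strict_missing:
                    raise ValueError(
                        f"missing genotype for sample {samples[i]} at "
                        f"{rec.CHROM}:{rec.POS} (strict mode)"
                    )
                n_missing += 1
            dosage[i] = sum(1 for a in alleles if a == 1)
        vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if dosage.sum() == 0:
            logger.warning("dropping monomorphic variant %s", vid)
            continue
        columns.append(dosage)
        variant_ids.append(vid)

    if n_missing:
        logger.warning(
            "treated %d missing genotypes as reference (dosage 0)", n_missing
        )
    if not columns:
        raise ValueError(f"no observed biallelic SNVs in {path}")
    return GenotypeMatrix(np.column_stack(columns), samples, variant_ids)


def read_annotations(
    path: str | os.PathLike,
    id_column: str = "variant_id",
    score_column: str = "score",
) -> AnnotationTable:
    """Read a tab-separated variant -> functional score table."""
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    for col in (id_column, score_column):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    if df[id_column].duplicated().any():
        dup = df[id_column][df[id_column].duplicated()].iloc[0]
        raise ValueError(f"duplicate variant id in annotation table: {dup}")
    scores = pd.to_numeric(df[score_column], errors="coerce")
    if scores.isna().any() and len(df):
        bad = df[id_column][scores.isna()].iloc[0]
        raise ValueError(f"non-numeric or missing score for variant {bad}")
    return AnnotationTable(df[id_column].tolist(), scores.to_numpy(dtype=float))


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read a tab-separated phenotype table (sample_id, case_status and/or y_continuous)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table lacks column 'sample_id'")
    y = df["y_continuous"].to_numpy(dtype=float) if "y_continuous" in df.columns else None
    cs = None
    if "case_status" in df.columns:
        cs = pd.to_numeric(df["case_status"], errors="raise").to_numpy()
    if y is None and cs is None:
        raise ValueError("phenotype table needs case_status and/or y_continuous")
    return PhenotypeTable(df["sample_id"].tolist(), y, cs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

FIT_COLUMNS = [
    "variant_id", "score", "true_causal", "beta_hat", "beta_tilde",
    "se", "z", "carried_in_case",
]
ROC_COLUMNS = ["method", "rr_config", "fpr", "tpr"]
SUMMARY_COLUMNS = ["method", "rr_config", "mean_auc", "mc_se_auc", "n_replicates"]


def _write_tsv(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    out = df.reindex(columns=columns) if len(df) else pd.DataFrame(columns=columns)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")


def write_results(
    fit_table: pd.DataFrame,
    roc_table: pd.DataFrame,
    summary_table: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write the three result TSVs with fixed column order.

    Returns the paths keyed by table name. Not-applicable cells are
    written as ``"."``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fit": out / "per_variant.tsv",
        "roc": out / "roc_points.tsv",
        "summary": out / "summary.tsv",
    }
    _write_tsv(fit_table, FIT_COLUMNS, paths["fit"])
    _write_tsv(roc_table, ROC_COLUMNS, paths["roc"])
    _write_tsv(summary_table, SUMMARY_COLUMNS, paths["summary"])
    return paths


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 so synthetic cohorts exercise the VCF reader.

    Variant ids must follow the ``chrom:pos:ref:alt`` convention; records
    are emitted in column order with unphased GT fields.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids) + "\n"
        )
        for j, vid in enumerate(genotypes.variant_ids):
            chrom, pos, ref, alt = vid.split(":")
            gts = ["0/0", "0/1", "1/1"]
            row = [gts[d] for d in genotypes.dosages[:, j]]
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(row) + "\n"
            )


def write_annotations(annotations: AnnotationTable, path: str | os.PathLike) -> None:
    """Write an annotation TSV readable by :func:`read_annotations`."""
    pd.DataFrame(
        {"variant_id": annotations.variant_ids, "score": annotations.scores}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_phenotypes(phenotypes: PhenotypeTable, path: str | os.PathLike) -> None:
    """Write a phenotype TSV readable by :func:`read_phenotypes`."""
    data: dict[str, object] = {"sample_id": phenotypes.sample_ids}
    if phenotypes.y_continuous is not None:
        data["y_continuous"] = phenotypes.y_continuous
    if phenotypes.case_status is not None:
        data["case_status"] = phenotypes.case_status
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")
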