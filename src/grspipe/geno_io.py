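"""Readers and writers for the genotype / summary-statistic / phenotype formats.

The in-memory substrate of the pipeline is :class:`GenotypeDataset`: a sample
table, a variant table and an ``int8`` dosage matrix counting copies of
``allele1`` (the PLINK .bim A1), with :data:`MISSING` (-1) as the out-of-band
missing sentinel.  Association statistics, weights and phenotypes travel as
pandas DataFrames with fixed lower-case column schemas.

On-disk formats:

* PLINK-1 binary filesets (``.bed``/``.bim``/``.fam``); the .bed codec is
  implemented here (magic ``6C 1B``, SNP-major ``01``, 2-bit genotypes packed
  four to a byte, little-endian within a byte).
* Tab-delimited summary statistics, weight tables and phenotype tables, with
  ``NA`` as the missing token.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

#: Out-of-band dosage sentinel for a missing genotype (never 0).
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit PLINK genotype code -> dosage of allele1 (A1).
#   00 = hom A1A1 -> 2;  01 = missing;  10 = het -> 1;  11 = hom A2A2 -> 0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage+1 -> 2-bit code (index 0 is the missing sentinel -1)
_DOSAGE_TO_CODE = np.array([1, 3, 2, 0], dtype=np.uint8)

SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
VARIANT_COLUMNS = ["snp", "chrom", "cm", "pos", "a1", "a2"]

#: Canonical association-table schema (the "AssocTable" currency).  ``a1`` is
#: the effect allele of ``beta`` (log OR per copy of a1), ``a2`` the other.
ASSOC_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "z", "p",
                 "n", "info", "eaf"]

WEIGHT_COLUMNS = ["snp", "ea", "weight", "source"]

VALID_ALLELES = frozenset("ACGT")


@dataclass
class GenotypeDataset:
    """Samples x variants dosage matrix plus its describing tables.

    ``dosages[i, j]`` counts copies of ``variants.a1[j]`` carried by sample
    ``samples.iid[i]``; :data:`MISSING` marks an absent call.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        if len(self.variants) and (self.variants["pos"] < 1).any():
            raise ValidationError("variant positions must be >= 1 (1-based)")
        dup = self.variants.duplicated(subset=["chrom", "snp"])
        if dup.any():
            raise ValidationError(
                f"duplicate variant ids within a chromosome: "
                f"{self.variants.loc[dup, 'snp'].tolist()[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele1_freq(self) -> np.ndarray:
        """Sample frequency of allele1 per variant, ignoring missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-missing column -> nan
            f = d.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(f, dtype=float)

    def maf(self) -> np.ndarray:
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            samples=self.samples.iloc[si],
            variants=self.variants.iloc[vi],
            dosages=self.dosages[np.ix_(si, vi)],
        )


@dataclass
class ScoreVector:
    """Per-sample genetic risk score with its provenance."""

    scores: pd.Series                 # index = sample iid
    n_snps_requested: int
    n_snps_used: int
    missing_policy: str
    weight_source: str = "trained"
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_snps_used > self.n_snps_requested:
            raise ValidationError("n_snps_used exceeds n_snps_requested")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValidationError("scores must be finite")


# ---------------------------------------------------------------------------
# PLINK-1 binary fileset
# ---------------------------------------------------------------------------

def load_genotype_fileset(path_prefix) -> GenotypeDataset:
    """Read a PLINK-1 ``.bed``/``.bim``/``.fam`` trio into a dataset."""
    prefix = Path(path_prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FormatError(f"missing fileset member: {f}")

    samples = _read_fam(fam)
    variants = _read_bim(bim)
    n, m = len(samples), len(variants)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: not a PLINK-1 bed (bad magic bytes)")
    if len(raw) < 3 or raw[2] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major (mode 0x01) beds are supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed}: expected {bytes_per_snp * m} data bytes for {n} samples x "
            f"{m} variants, found {body.size}")
    if m == 0 or n == 0:
        return GenotypeDataset(samples, variants, np.zeros((n, m), dtype=np.int8))

    blocks = body.reshape(m, bytes_per_snp)
    # unpack 4 two-bit codes per byte, lowest bits = first sample
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0x3
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypeDataset(samples, variants, dosages)


def write_genotype_fileset(dataset: GenotypeDataset, path_prefix) -> None:
    """Write a dataset as a PLINK-1 trio readable by :func:`load_genotype_fileset`."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.n_samples, dataset.n_variants

    _write_fam(dataset.samples, prefix.with_suffix(".fam"))
    _write_bim(dataset.variants, prefix.with_suffix(".bim"))

    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    if n:
        codes[:, :n] = _DOSAGE_TO_CODE[dataset.dosages.T.astype(np.int16) + 1]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


def _read_fam(path: Path) -> pd.DataFrame:
    try:
        fam = pd.read_csv(path, sep=r"\s+", header=None, names=SAMPLE_COLUMNS,
                          dtype={"fid": str, "iid": str, "father": str,
                                 "mother": str})
    except pd.errors.EmptyDataError:
        fam = pd.DataFrame(columns=SAMPLE_COLUMNS)
    return fam


def _write_fam(samples: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame({c: samples.get(c, pd.Series(dtype=object))
                        for c in SAMPLE_COLUMNS})
    out = out.fillna({"father": "0", "mother": "0", "sex": 0, "phenotype": -9})
    out.to_csv(path, sep="\t", header=False, index=False)


def _read_bim(path: Path) -> pd.DataFrame:
    names = ["chrom", "snp", "cm", "pos", "a1", "a2"]   # .bim column order
    try:
        bim = pd.read_csv(path, sep=r"\s+", header=None, names=names,
                          dtype={"snp": str, "chrom": str, "a1": str, "a2": str})
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=names)
    return bim[VARIANT_COLUMNS]


def _write_bim(variants: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame({"chrom": variants["chrom"], "snp": variants["snp"],
                        "cm": variants.get("cm", 0), "pos": variants["pos"],
                        "a1": variants["a1"], "a2": variants["a2"]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

_SUMSTAT_REQUIRED = ["SNP", "CHR", "BP", "A1", "A2", "SE", "P"]


def load_summary_stats(tsv_path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into the canonical AssocTable.

    Requires columns SNP, CHR, BP, A1, A2, (BETA or OR), SE, P; accepts
    optional INFO, EAF, N.  An OR column is converted to beta = ln(OR).
    A1 is the effect allele.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"SNP": str, "CHR": str,
                                                "A1": str, "A2": str},
                     na_values=["NA"])
    missing = [c for c in _SUMSTAT_REQUIRED if c not in df.columns]
    if "BETA" not in df.columns and "OR" not in df.columns:
        missing.append("BETA|OR")
    if missing:
        raise SchemaError(f"summary stats missing required columns: {missing}")

    beta = df["BETA"].astype(float) if "BETA" in df.columns \
        else np.log(df["OR"].astype(float))
    out = pd.DataFrame({
        "snp": df["SNP"], "chrom": df["CHR"], "pos": df["BP"].astype(int),
        "a1": df["A1"].str.upper(), "a2": df["A2"].str.upper(),
        "beta": beta, "se": df["SE"].astype(float), "p": df["P"].astype(float),
        "n": df["N"].astype(float) if "N" in df.columns else np.nan,
        "info": df["INFO"].astype(float) if "INFO" in df.columns else np.nan,
        "eaf": df["EAF"].astype(float) if "EAF" in df.columns else np.nan,
    })
    out["z"] = out["beta"] / out["se"]
    out = out[ASSOC_COLUMNS]
    validate_assoc(out)
    return out


def validate_assoc(assoc: pd.DataFrame) -> None:
    """Enforce the AssocTable invariants (finite rows only)."""
    missing = [c for c in ASSOC_COLUMNS if c not in assoc.columns]
    if missing:
        raise SchemaError(f"association table missing columns: {missing}")
    if assoc["snp"].duplicated().any():
        dups = assoc.loc[assoc["snp"].duplicated(), "snp"].tolist()[:5]
        raise ValidationError(f"duplicate variant ids in association table: {dups}")
    tested = assoc["beta"].notna()
    p = assoc.loc[tested, "p"]
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("P values must lie in (0, 1]")
    if (assoc.loc[tested, "se"] <= 0).any():
        raise ValidationError("SE must be > 0 where beta is finite")
    zchk = assoc.loc[tested, "beta"] / assoc.loc[tested, "se"]
    if not np.allclose(zchk, assoc.loc[tested, "z"], atol=1e-6):
        raise ValidationError("z is not consistent with beta/se")


def write_summary_stats(assoc: pd.DataFrame, tsv_path) -> None:
    out = pd.DataFrame({
        "SNP": assoc["snp"], "CHR": assoc["chrom"], "BP": assoc["pos"],
        "A1": assoc["a1"], "A2": assoc["a2"], "BETA": assoc["beta"],
        "SE": assoc["se"], "P": assoc["p"], "N": assoc["n"],
        "INFO": assoc["info"], "EAF": assoc["eaf"],
    })
    out.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Weights and phenotypes
# ---------------------------------------------------------------------------

def load_weights(tsv_path) -> pd.DataFrame:
    """Read a (SNP, EA, WEIGHT[, SOURCE]) weight table defining a GRS."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"SNP": str, "EA": str},
                     na_values=["NA"])
    missing = [c for c in ("SNP", "EA", "WEIGHT") if c not in df.columns]
    if missing:
        raise SchemaError(f"weight table missing required columns: {missing}")
    if df.empty:
        return pd.DataFrame(columns=WEIGHT_COLUMNS)
    ea = df["EA"].str.upper()
    bad = ~ea.isin(VALID_ALLELES)
    if bad.any():
        raise ValidationError(
            f"non-ACGT effect allele(s): {sorted(set(df.loc[bad, 'EA'].astype(str)))}")
    w = df["WEIGHT"].astype(float)
    if not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite (no NA)")
    out = pd.DataFrame({"snp": df["SNP"], "ea": ea, "weight": w,
                        "source": df.get("SOURCE", "published")})
    if out["snp"].duplicated().any():
        raise ValidationError("duplicate variant ids in weight table")
    return out[WEIGHT_COLUMNS]


def write_weights(weights: pd.DataFrame, tsv_path) -> None:
    out = pd.DataFrame({"SNP": weights["snp"], "EA": weights["ea"],
                        "WEIGHT": weights["weight"], "SOURCE": weights["source"]})
    out.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")


def load_phenotypes(tsv_path) -> pd.DataFrame:
    """Read a phenotype table (IID, STATUS[, RENAL, ONSET, SEX, POP])."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"IID": str, "POP": str},
                     na_values=["NA"])
    missing = [c for c in ("IID", "STATUS") if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table missing required columns: {missing}")
    if df["IID"].duplicated().any():
        raise ValidationError("duplicate IID in phenotype table")
    if not df["STATUS"].dropna().isin([0, 1]).all():
        raise ValidationError("STATUS must be 0/1")
    if "RENAL" in df.columns and not df["RENAL"].dropna().isin([0, 1]).all():
        raise ValidationError("RENAL must be 0/1/NA")
    if "ONSET" in df.columns and (df["ONSET"].dropna() <= 0).any():
        raise ValidationError("ONSET must be a positive age in years")
    return df


def write_phenotypes(pheno: pd.DataFrame, tsv_path) -> None:
    pheno.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")


def attach_phenotypes(dataset: GenotypeDataset, pheno: pd.DataFrame):
    """Join a phenotype table to the dataset samples by IID.

    Returns ``(joined, n_unmatched)`` where ``joined`` has one row per dataset
    sample in dataset order; phenotype rows with no matching sample are
    counted (and reported via a warning), never silently dropped.
    """
    joined = dataset.samples[["iid"]].merge(pheno, left_on="iid",
                                            right_on="IID", how="left")
    joined = joined.drop(columns=["IID"])
    n_unmatched = int((~pheno["IID"].isin(dataset.samples["iid"])).sum())
    if n_unmatched:
        warnings.warn(f"{n_unmatched} phenotype row(s) had no matching sample iid",
                      stacklevel=2)
    return joined, n_unmatched
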