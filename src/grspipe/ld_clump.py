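"""Pairwise LD and greedy clumping over a P-value / r^2 / window grid.

Clumping walks candidate index SNPs (association P below ``p1``) in ascending
P order; each still-unassigned SNP on the same chromosome within
``window_kb`` kilobases of the index whose squared dosage correlation with
the index reaches ``r2_max`` joins the index's clump and leaves candidacy, so
every SNP appears in at most one clump and the retained index set is
approximately LD-independent.  Any SNP may join a clump regardless of its own
P (the secondary threshold is fixed at 1.0).  P ties among candidates are
broken by (chromosome, position, variant id), making the result invariant to
input record order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geno_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ClumpSpec:
    """One point of the clumping-and-thresholding grid."""

    p1: float          # index-SNP P threshold (candidates have P < p1)
    r2_max: float      # pairwise r^2 at or above which a SNP joins the clump
    window_kb: float   # half-window around the index, in kb

    def __post_init__(self) -> None:
        if not 0 < self.p1 <= 1:
            raise ConfigError("p1 must lie in (0, 1]")
        if not 0 <= self.r2_max <= 1:
            raise ConfigError("r2_max must lie in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigError("window_kb must be > 0")


@dataclass
class ClumpResult:
    """Ordered clumps (index snp -> member snps) plus bookkeeping."""

    spec: ClumpSpec
    clumps: list                      # [(index_snp, [member_snp, ...]), ...]
    n_missing_from_dataset: int = 0
    index_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def retained(self) -> list:
        return [index for index, _ in self.clumps]

    def report_table(self) -> pd.DataFrame:
        """Clump report: INDEX_SNP, CHR, BP, P, N_MEMBERS, MEMBERS."""
        t = self.index_table.copy()
        t["N_MEMBERS"] = [len(m) for _, m in self.clumps]
        t["MEMBERS"] = [",".join(m) if m else "." for _, m in self.clumps]
        return t


def pairwise_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both; if either vector is constant
    on the shared support the value is undefined and NaN is returned (treated
    downstream as not-in-LD).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("dosage vectors must have equal length")
    # same computation as the vectorized block path, so threshold comparisons
    # at exact grid values (e.g. r^2 = 0.2) agree bit for bit
    return float(_r2_against(a, b[:, None])[0])


def _r2_against(g_index: np.ndarray, g_block: np.ndarray) -> np.ndarray:
    """r^2 of one dosage column against a block, pairwise-complete, vectorized."""
    ok_i = g_index != MISSING
    ok = ok_i[:, None] & (g_block != MISSING)
    n = ok.sum(axis=0).astype(float)
    gi = np.where(ok, g_index[:, None], 0.0)
    gb = np.where(ok, g_block, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = gi.sum(axis=0) / n
        mb = gb.sum(axis=0) / n
        sxy = (gi * gb).sum(axis=0) - n * mi * mb
        sxx = (gi * gi).sum(axis=0) - n * mi * mi
        syy = (gb * gb).sum(axis=0) - n * mb * mb
        r2 = np.where((sxx > 0) & (syy > 0) & (n >= 2),
                      (sxy * sxy) / (sxx * syy), np.nan)
    return r2


def greedy_clump(assoc: pd.DataFrame, dataset: GenotypeDataset,
                 spec: ClumpSpec) -> ClumpResult:
    """Greedy LD clumping of an association table against training genotypes."""
    var_idx = pd.Series(np.arange(dataset.n_variants),
                        index=dataset.variants["snp"])
    tested = assoc[np.isfinite(assoc["p"].to_numpy(dtype=float))]
    present = tested["snp"].isin(var_idx.index)
    n_missing = int((~present).sum())
    if n_missing:
        warnings.warn(f"{n_missing} association record(s) absent from the "
                      "dataset were excluded from clumping", stacklevel=2)
    work = tested[present].copy()
    work["_col"] = var_idx[work["snp"]].to_numpy()
    work = work.sort_values(["p", "chrom", "pos", "snp"],
                            kind="stable").reset_index(drop=True)

    window_bp = spec.window_kb * 1000.0
    chrom = work["chrom"].astype(str).to_numpy()
    pos = work["pos"].to_numpy(dtype=float)
    pvals = work["p"].to_numpy(dtype=float)
    cols = work["_col"].to_numpy()
    snps = work["snp"].to_numpy()

    assigned = np.zeros(len(work), dtype=bool)
    clumps = []
    index_rows = []
    for i in range(len(work)):
        if pvals[i] >= spec.p1:
            break               # sorted by P: no further candidates
        if assigned[i]:
            continue
        assigned[i] = True
        in_window = (~assigned) & (chrom == chrom[i]) \
            & (np.abs(pos - pos[i]) <= window_bp)
        members = []
        cand = np.flatnonzero(in_window)
        if cand.size:
            r2 = _r2_against(dataset.dosages[:, cols[i]],
                             dataset.dosages[:, cols[cand]])
            joins = cand[np.nan_to_num(r2, nan=-1.0) >= spec.r2_max]
            assigned[joins] = True
            members = [snps[j] for j in joins]
        clumps.append((snps[i], members))
        index_rows.append({"INDEX_SNP": snps[i], "CHR": chrom[i],
                           "BP": int(pos[i]), "P": pvals[i]})
    table = pd.DataFrame(index_rows, columns=["INDEX_SNP", "CHR", "BP", "P"])
    return ClumpResult(spec=spec, clumps=clumps,
                       n_missing_from_dataset=n_missing, index_table=table)


def ct_grid(assoc: pd.DataFrame, dataset: GenotypeDataset,
            p1_list, r2_list, kb_list) -> dict:
    """One ClumpResult per point of the Cartesian p1 x r2 x kb grid."""
    if not (len(p1_list) and len(r2_list) and len(kb_list)):
        raise ConfigError("grid lists must be non-empty")
    results = {}
    for p1, r2, kb in product(p1_list, r2_list, kb_list):
        spec = ClumpSpec(p1=p1, r2_max=r2, window_kb=kb)
        results[spec] = greedy_clump(assoc, dataset, spec)
    return results


#: The published clumping-and-thresholding sweep: 8 P thresholds x 2 r^2
#: thresholds x 2 window radii = 32 score configurations.
DEFAULT_P1_GRID = (0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 5e-8)
DEFAULT_R2_GRID = (0.2, 0.5)
DEFAULT_KB_GRID = (250.0, 1000.0)
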