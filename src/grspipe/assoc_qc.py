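"""GWAS stages: QC, principal components, per-SNP association, inflation, meta.

Association is computed for every variant against a binary outcome with one of
three tests:

``logistic_wald`` (default)
    Per-SNP logistic regression of the outcome on the allele1 dosage plus an
    intercept and optional covariates; Wald beta/SE/Z/P.  Fitting is a batched
    Newton-Raphson vectorized across SNPs, so a genome of tens of thousands of
    variants fits in seconds; results match statsmodels' per-SNP fits.
``allelic_chisq``
    2x2 allele-count table (2N alleles under HWE counting); Pearson chi-square
    P, with beta = ln(allelic OR) and Woolf SE.
``trend_1df``
    1-df Cochran-Armitage trend test (chi-square = N r^2 on the 0/1/2 coding);
    beta/SE as for the allelic test.

For the chi-square tests the reported ``z`` is ``beta/se`` (the Wald ratio on
the log OR) while ``p`` comes from the named statistic.  Monomorphic SNPs are
flagged and never tested; separation or non-convergence yields a flagged
record with missing beta, never a fabricated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import ComputationError, ConfigError
from .geno_io import ASSOC_COLUMNS, MISSING, GenotypeDataset

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))   # 0.4549364...


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Itemized variant-QC removals; removed + retained = input per category."""

    n_input: int
    n_retained: int
    removed_maf: int
    removed_info: int
    removed_region: int
    removed_chrom: int
    thresholds: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "removed_maf": self.removed_maf, "removed_info": self.removed_info,
                "removed_region": self.removed_region,
                "removed_chrom": self.removed_chrom,
                "thresholds": dict(self.thresholds)}


#: The MHC extended region excluded from clumping, as (chrom, start, end) bp.
MHC_EXTENDED_REGION = ("6", 24_000_000, 36_000_000)


def variant_qc(dataset: GenotypeDataset, maf_min: float = 0.0,
               info_min: float = 0.0, info=None,
               exclude_regions=(), exclude_chroms=()):
    """Filter variants by MAF, imputation INFO, regions and chromosomes.

    Thresholds are closed lower bounds (MAF/INFO >= threshold passes);
    regions are ``(chrom, start_bp, end_bp)`` inclusive.  Returns
    ``(filtered_dataset, QCReport)``; an empty result is allowed.
    """
    if not 0 <= maf_min <= 0.5:
        raise ConfigError("maf_min must lie in [0, 0.5]")
    if not 0 <= info_min <= 1:
        raise ConfigError("info_min must lie in [0, 1]")
    m = dataset.n_variants
    fail_maf = np.zeros(m, dtype=bool)
    if maf_min > 0 and m:
        maf = dataset.maf()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fail_maf = ~(maf >= maf_min)     # NaN (all-missing) also fails

    fail_info = np.zeros(m, dtype=bool)
    if info is None and "info" in dataset.variants.columns:
        info = dataset.variants["info"].to_numpy(dtype=float)
    if info_min > 0 and info is not None:
        info = np.asarray(info, dtype=float)
        fail_info = ~(info >= info_min)

    chrom = dataset.variants["chrom"].astype(str).to_numpy() if m else np.array([])
    pos = dataset.variants["pos"].to_numpy() if m else np.array([])
    fail_region = np.zeros(m, dtype=bool)
    for rchrom, start, end in exclude_regions:
        fail_region |= (chrom == str(rchrom)) & (pos >= start) & (pos <= end)
    fail_chrom = np.isin(chrom, [str(c) for c in exclude_chroms]) if m \
        else np.zeros(0, dtype=bool)

    keep = ~(fail_maf | fail_info | fail_region | fail_chrom)
    report = QCReport(
        n_input=m, n_retained=int(keep.sum()),
        removed_maf=int(fail_maf.sum()), removed_info=int(fail_info.sum()),
        removed_region=int(fail_region.sum()), removed_chrom=int(fail_chrom.sum()),
        thresholds={"maf_min": maf_min, "info_min": info_min,
                    "exclude_regions": list(map(tuple, exclude_regions)),
                    "exclude_chroms": list(exclude_chroms)},
    )
    return dataset.subset(variant_idx=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def relatedness_filter(dataset: GenotypeDataset, pihat_max: float = 0.125,
                       maf_min: float = 0.01):
    """Remove one member of each pair with PI_HAT above ``pihat_max``.

    PI_HAT = P(IBD=1)/2 + P(IBD=2) is estimated by the method of moments from
    observed identity-by-state counts against their expectations given the
    sample allele frequencies.  Within a flagged pair the member with higher
    genotype missingness is removed (ties: the later sample).  Returns
    ``(kept_dataset, pairs)`` where ``pairs`` lists every pair above the
    threshold and which member was removed.
    """
    n = dataset.n_samples
    if n < 2:
        raise ComputationError("relatedness filtering needs >= 2 samples")
    maf = dataset.maf()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        usable = (maf > maf_min) & ~np.any(dataset.dosages == MISSING, axis=0)
    if usable.sum() < 50:
        warnings.warn(f"only {int(usable.sum())} usable SNPs; "
                      "IBD estimates will be unstable", stacklevel=2)
    g = dataset.dosages[:, usable].astype(np.float32)
    p = g.mean(axis=0) / 2.0
    q = 1.0 - p
    m = g.shape[1]

    i0 = (g == 0).astype(np.float32)
    i1 = (g == 1).astype(np.float32)
    i2 = (g == 2).astype(np.float32)
    ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    ibs0 = i0 @ i2.T + i2 @ i0.T
    ibs1 = m - ibs2 - ibs0

    # Finite-sample expectations: the pair's alleles are a draw *without*
    # replacement from the observed pool of T = 2N alleles (X copies of
    # allele1, Y of allele2), which removes the small-sample bias of the
    # plug-in frequency formulas.
    t_all = 2.0 * n
    x_cnt = p * t_all
    y_cnt = q * t_all

    def _ff(a, k):      # falling factorial a (a-1) ... (a-k+1)
        out = np.ones_like(a)
        for i in range(k):
            out = out * (a - i)
        return out

    t4 = _ff(np.array([t_all]), 4)[0]
    t3 = t_all * (t_all - 1) * (t_all - 2)
    e0_z0 = float(np.sum(2 * _ff(x_cnt, 2) * _ff(y_cnt, 2)) / t4)
    e1_z0 = float(np.sum(4 * _ff(x_cnt, 3) * y_cnt
                         + 4 * x_cnt * _ff(y_cnt, 3)) / t4)
    e2_z0 = float(np.sum(_ff(x_cnt, 4) + _ff(y_cnt, 4)
                         + 4 * _ff(x_cnt, 2) * _ff(y_cnt, 2)) / t4)
    e1_z1 = float(np.sum(2 * _ff(x_cnt, 2) * y_cnt
                         + 2 * x_cnt * _ff(y_cnt, 2)) / t3)
    e2_z1 = float(np.sum(np.ones_like(x_cnt))) - e1_z1

    pz0 = ibs0 / e0_z0
    pz1 = (ibs1 - pz0 * e1_z0) / e1_z1
    pz2 = (ibs2 - pz0 * e2_z0 - pz1 * e2_z1) / m
    # sum signed components (clipping them separately would bias nulls up)
    pihat = np.clip(pz1 / 2.0 + pz2, 0.0, 1.0)

    miss_rate = np.mean(dataset.dosages == MISSING, axis=1)
    iu, ju = np.triu_indices(n, k=1)
    above = pihat[iu, ju] > pihat_max
    order = np.argsort(-pihat[iu, ju][above], kind="stable")
    flagged = list(zip(iu[above][order], ju[above][order]))

    removed: set = set()
    rows = []
    for a, b in flagged:
        a, b = int(a), int(b)
        if a in removed or b in removed:
            drop = None
        elif miss_rate[a] > miss_rate[b]:
            drop = a
        else:
            drop = b
        if drop is not None:
            removed.add(drop)
        rows.append({"iid_a": dataset.samples["iid"].iloc[a],
                     "iid_b": dataset.samples["iid"].iloc[b],
                     "pihat": float(pihat[a, b]),
                     "removed_iid": dataset.samples["iid"].iloc[drop]
                     if drop is not None else None})
    keep_idx = np.array([i for i in range(n) if i not in removed], dtype=int)
    pairs = pd.DataFrame(rows, columns=["iid_a", "iid_b", "pihat", "removed_iid"])
    return dataset.subset(sample_idx=keep_idx), pairs


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def compute_pcs(dataset: GenotypeDataset, k: int) -> pd.DataFrame:
    """Top-k principal-component coordinates of the samples.

    Dosages are mean-centered and scaled by sqrt(2 p (1-p)); missing calls are
    imputed to the mean.  Sign convention: the largest-magnitude variant
    loading of each component is positive, so results are deterministic.
    """
    n, m = dataset.n_samples, dataset.n_variants
    if k < 1 or k > min(n, m):
        raise ConfigError(f"k must lie in [1, min(n_samples, n_snps)] = "
                          f"[1, {min(n, m)}]")
    g = dataset.dosages.astype(float)
    g[dataset.dosages == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    z = (g[:, poly] - 2.0 * p[poly]) / scale[poly]
    z[np.isnan(z)] = 0.0
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    for comp in range(k):
        lead = np.argmax(np.abs(vt[comp]))
        if vt[comp, lead] < 0:
            vt[comp] = -vt[comp]
            u[:, comp] = -u[:, comp]
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)],
                        index=dataset.samples["iid"].to_numpy())


# ---------------------------------------------------------------------------
# Per-SNP association
# ---------------------------------------------------------------------------

VALID_TESTS = ("logistic_wald", "allelic_chisq", "trend_1df")


def snp_association(dataset: GenotypeDataset, outcome, covariates=None,
                    test: str = "logistic_wald") -> pd.DataFrame:
    """Associate every variant with a binary outcome.

    ``outcome`` is a 0/1 array over dataset samples (NaN rows are excluded);
    ``covariates`` (logistic only) is an (n, c) array/DataFrame without an
    intercept column.  Returns the canonical association table with effect
    allele = dataset allele1, plus a ``status`` column
    (``ok``/``monomorphic``/``nonconverged``).
    """
    if test not in VALID_TESTS:
        raise ConfigError(f"test must be one of {VALID_TESTS}")
    y_full = np.asarray(outcome, dtype=float)
    if y_full.shape[0] != dataset.n_samples:
        raise ConfigError("outcome length does not match dataset samples")
    sample_ok = ~np.isnan(y_full)
    y = y_full[sample_ok]
    if not np.isin(y, [0.0, 1.0]).all():
        raise ConfigError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ComputationError("outcome has a single class")

    g_raw = dataset.dosages[sample_ok]
    mask = g_raw != MISSING
    g = np.where(mask, g_raw, np.int8(0))    # int8: float views per chunk only
    n_used = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        eaf = np.where(n_used > 0,
                       g.sum(axis=0, dtype=np.int64) / (2 * n_used), np.nan)
    gmin = np.where(mask, g_raw, np.int8(3)).min(axis=0)
    gmax = np.where(mask, g_raw, np.int8(-3)).max(axis=0)
    mono = (gmin >= gmax) | (n_used == 0)

    m = dataset.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    status = np.full(m, "ok", dtype=object)
    status[mono] = "monomorphic"
    poly = np.flatnonzero(~mono)

    if test == "logistic_wald":
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)[sample_ok]
            if cov.ndim == 1:
                cov = cov[:, None]
            design = np.column_stack([np.ones(len(y)), cov])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise ComputationError("covariate matrix is rank-deficient")
        else:
            design = np.ones((len(y), 1))
        b, s_, ok = _batched_logistic(y, design, g[:, poly], mask[:, poly])
        beta[poly], se[poly] = b, s_
        with np.errstate(invalid="ignore"):
            z = b / s_
            pval[poly] = 2.0 * stats.norm.sf(np.abs(z))
        status[poly[~ok]] = "nonconverged"
        beta[poly[~ok]] = np.nan
        se[poly[~ok]] = np.nan
        pval[poly[~ok]] = np.nan
    else:
        if covariates is not None:
            raise ConfigError(f"covariates are only supported for logistic_wald")
        b, s_, p_ = _allele_table_tests(y, g[:, poly], mask[:, poly], test)
        beta[poly], se[poly], pval[poly] = b, s_, p_

    with np.errstate(invalid="ignore", divide="ignore"):
        zcol = beta / se
    out = pd.DataFrame({
        "snp": dataset.variants["snp"], "chrom": dataset.variants["chrom"],
        "pos": dataset.variants["pos"], "a1": dataset.variants["a1"],
        "a2": dataset.variants["a2"], "beta": beta, "se": se, "z": zcol,
        "p": np.clip(pval, np.nextafter(0, 1), 1.0),
        "n": n_used.astype(float), "info": np.nan, "eaf": eaf,
    })[ASSOC_COLUMNS + []]
    out["status"] = status
    return out


def _batched_logistic(y, design, g, mask, max_iter=30, tol=1e-6, beta_cap=15.0):
    """Newton-Raphson logistic fits vectorized across SNPs.

    ``design`` holds intercept+covariates shared by all SNPs; ``g`` the
    per-SNP dosage column (0 where masked out).  Returns (beta_g, se_g, ok).
    """
    n, c = design.shape
    m = g.shape[1]
    beta_g = np.full(m, np.nan)
    se_g = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    if m == 0:
        return beta_g, se_g, ok
    if c == 1:
        return _batched_logistic_2x2(y, g, mask, max_iter, tol, beta_cap)
    chunk = max(1, int(2e7 / max(n, 1)))
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        gb = g[:, lo:hi].astype(np.float64)
        mb = mask[:, lo:hi].astype(float)
        mm = hi - lo
        b = np.zeros((mm, c + 1))
        active = np.ones(mm, dtype=bool)
        singular = np.zeros(mm, dtype=bool)
        hess_final = np.empty((mm, c + 1, c + 1))

        def _newton_step(cols):
            gc_ = gb[:, cols]
            mc_ = mb[:, cols]
            eta = design @ b[cols, :c].T + gc_ * b[cols, c]
            mu = expit(eta)
            w = mu * (1.0 - mu) * mc_
            resid = (y[:, None] - mu) * mc_
            grad = np.empty((len(cols), c + 1))
            grad[:, :c] = (design.T @ resid).T
            grad[:, c] = (gc_ * resid).sum(axis=0)
            hess = np.empty((len(cols), c + 1, c + 1))
            hess[:, :c, :c] = np.einsum("nc,nm,nd->mcd", design, w, design,
                                        optimize=True)
            cross = np.einsum("nc,nm->mc", design, w * gc_, optimize=True)
            hess[:, :c, c] = cross
            hess[:, c, :c] = cross
            hess[:, c, c] = (w * gc_ * gc_).sum(axis=0)
            return grad, hess

        for _ in range(max_iter):
            cols = np.flatnonzero(active)
            if not cols.size:
                break
            grad, hess = _newton_step(cols)
            hess_final[cols] = hess
            delta = np.zeros_like(grad)
            try:
                delta = np.linalg.solve(hess, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                for k, i in enumerate(cols):
                    try:
                        delta[k] = np.linalg.solve(hess[k], grad[k])
                    except np.linalg.LinAlgError:
                        singular[i] = True
                        active[i] = False
                        delta[k] = 0.0
            delta = np.clip(delta, -4.0, 4.0)   # damp early overshoot
            b[cols] += delta
            done = np.max(np.abs(delta), axis=1) < tol
            active[cols[done]] = False
        still_active = active
        conv = ~still_active & ~singular & (np.abs(b[:, c]) < beta_cap)
        var = np.full(mm, np.nan)
        idx = np.flatnonzero(conv)
        if idx.size:
            # refresh the Hessian at the solution before inverting
            _, hess_idx = _newton_step(idx)
            inv = np.linalg.inv(hess_idx)
            var[idx] = inv[:, c, c]
        good = conv & (var > 0)
        beta_g[lo:hi] = np.where(good, b[:, c], np.nan)
        se_g[lo:hi] = np.where(good, np.sqrt(var), np.nan)
        ok[lo:hi] = good
    return beta_g, se_g, ok


def _batched_logistic_2x2(y, g, mask, max_iter, tol, beta_cap):
    """Intercept + dosage logistic fits with a closed-form 2x2 Newton solve.

    Processes SNPs in blocks so the float working set stays bounded
    regardless of panel size (dosages arrive as int8).
    """
    n, m = g.shape
    chunk = max(1, int(2.5e7 / max(n, 1)))
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        b, s_, o = _logistic_2x2_block(y, g[:, lo:hi].astype(np.float64),
                                       mask[:, lo:hi].astype(np.float64),
                                       max_iter, tol, beta_cap)
        beta[lo:hi], se[lo:hi], ok[lo:hi] = b, s_, o
    return beta, se, ok


def _logistic_2x2_block(y, g, mb_all, max_iter, tol, beta_cap):
    n, m = g.shape
    ybar = float(y.mean())
    b0 = np.full(m, np.log(ybar / (1.0 - ybar)))
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        cols = np.flatnonzero(active)
        if not cols.size:
            break
        gc_ = g[:, cols]
        mc_ = mb_all[:, cols]
        mu = expit(b0[cols] + gc_ * b1[cols])
        w = mu * (1.0 - mu) * mc_
        resid = (y[:, None] - mu) * mc_
        g0 = resid.sum(axis=0)
        g1 = (gc_ * resid).sum(axis=0)
        wg = w * gc_
        h00 = w.sum(axis=0)
        h01 = wg.sum(axis=0)
        h11 = (wg * gc_).sum(axis=0)
        det = h00 * h11 - h01 * h01
        bad = det <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = np.clip((h11 * g0 - h01 * g1) / det, -4.0, 4.0)
            d1 = np.clip((h00 * g1 - h01 * g0) / det, -4.0, 4.0)
        d0[bad] = 0.0
        d1[bad] = 0.0
        b0[cols] += d0
        b1[cols] += d1
        done = (np.maximum(np.abs(d0), np.abs(d1)) < tol) | bad
        active[cols[done]] = False
        if bad.any():
            b1[cols[bad]] = np.nan
    conv = ~active & np.isfinite(b1) & (np.abs(b1) < beta_cap)
    se = np.full(m, np.nan)
    beta = np.full(m, np.nan)
    idx = np.flatnonzero(conv)
    if idx.size:
        gc_ = g[:, idx]
        mc_ = mb_all[:, idx]
        mu = expit(b0[idx] + gc_ * b1[idx])
        w = mu * (1.0 - mu) * mc_
        wg = w * gc_
        h00 = w.sum(axis=0)
        h01 = wg.sum(axis=0)
        h11 = (wg * gc_).sum(axis=0)
        det = h00 * h11 - h01 * h01
        var = np.where(det > 0, h00 / det, np.nan)
        good = var > 0
        beta[idx[good]] = b1[idx][good]
        se[idx[good]] = np.sqrt(var[good])
    ok = np.isfinite(beta) & np.isfinite(se)
    return beta, se, ok


def _allele_table_tests(y, g, mask, test):
    """Allelic chi-square or Cochran-Armitage trend from 2x2 allele counts."""
    case = y == 1.0
    a_case = (g * mask)[case].sum(axis=0)                 # allele1 in cases
    n_case = mask[case].sum(axis=0)
    a_ctrl = (g * mask)[~case].sum(axis=0)
    n_ctrl = mask[~case].sum(axis=0)
    t_case = 2.0 * n_case
    t_ctrl = 2.0 * n_ctrl
    cells = np.stack([a_case, t_case - a_case, a_ctrl, t_ctrl - a_ctrl])
    zero = (cells <= 0).any(axis=0)
    adj = cells + np.where(zero, 0.5, 0.0)                # Haldane-Anscombe
    beta = np.log(adj[0] * adj[3] / (adj[1] * adj[2]))
    se = np.sqrt((1.0 / adj).sum(axis=0))

    if test == "allelic_chisq":
        total = cells.sum(axis=0)
        row1 = cells[0] + cells[1]
        row2 = cells[2] + cells[3]
        col1 = cells[0] + cells[2]
        col2 = cells[1] + cells[3]
        with np.errstate(invalid="ignore", divide="ignore"):
            expect = np.stack([row1 * col1, row1 * col2, row2 * col1, row2 * col2]) / total
            chi2 = np.where((expect > 0).all(axis=0),
                            ((cells - expect) ** 2 / expect).sum(axis=0), np.nan)
        pval = stats.chi2.sf(chi2, 1)
    else:   # trend_1df: chi2 = N * r^2 between 0/1/2 dosage and case status
        mb = mask.astype(float)
        n_used = mb.sum(axis=0)
        gm = (g * mb).sum(axis=0) / n_used
        ym = (y[:, None] * mb).sum(axis=0) / n_used
        gc = (g - gm) * mb
        yc = (y[:, None] - ym) * mb
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (gc * yc).sum(axis=0) / np.sqrt((gc ** 2).sum(axis=0)
                                                * (yc ** 2).sum(axis=0))
        chi2 = n_used * r ** 2
        pval = stats.chi2.sf(chi2, 1)
    return beta, se, pval


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------

@dataclass
class InflationResult:
    """Genomic inflation factor plus expected/observed QQ pairs."""

    lambda_gc: float
    n_tests: int
    qq: pd.DataFrame    # columns: expected, observed (-log10 P)


def genomic_inflation(assoc: pd.DataFrame) -> InflationResult:
    """lambda = median(Z^2) / 0.4549 (the median of chi-square with 1 df)."""
    z = assoc["z"].to_numpy(dtype=float)
    p = assoc["p"].to_numpy(dtype=float)
    tested = np.isfinite(z)
    if tested.sum() < 1:
        raise ComputationError("no tested SNPs for inflation estimate")
    lam = float(np.median(z[tested] ** 2) / _CHI2_MEDIAN_1DF)
    p_obs = np.sort(p[np.isfinite(p)])
    k = len(p_obs)
    expected = -np.log10((np.arange(1, k + 1) - 0.5) / k)
    observed = -np.log10(p_obs)
    qq = pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})
    return InflationResult(lambda_gc=lam, n_tests=int(tested.sum()), qq=qq)


# ---------------------------------------------------------------------------
# Fixed-effects meta-analysis
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return a2 == _complement(a1)


def harmonize_to(ref_a1, ref_a2, a1, a2, beta):
    """Align a (a1, a2, beta) record to reference alleles.

    Returns ``(beta, matched)``: sign-flips beta when effect/other are
    swapped, strand-flips when alleles only match after complementing, and
    reports no match (dropping strand-ambiguous mismatches) otherwise.
    """
    if (a1, a2) == (ref_a1, ref_a2):
        return beta, True
    if (a1, a2) == (ref_a2, ref_a1):
        return -beta, True
    if _is_ambiguous(a1, a2) or _is_ambiguous(ref_a1, ref_a2):
        return np.nan, False
    c1, c2 = _complement(a1), _complement(a2)
    if (c1, c2) == (ref_a1, ref_a2):
        return beta, True
    if (c1, c2) == (ref_a2, ref_a1):
        return -beta, True
    return np.nan, False


def meta_fixed_effects(*assoc_tables: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis of >= 1 tables.

    Effect alleles are harmonized to the first table carrying each SNP before
    combining; records whose alleles cannot be reconciled (including
    strand-ambiguous mismatches) are dropped.  SNPs present in a single table
    are carried through with ``single_study = True``.
    """
    if len(assoc_tables) == 0:
        raise ConfigError("at least one association table is required")
    if len(assoc_tables) == 1:
        out = assoc_tables[0].copy()
        out["single_study"] = True
        out["n_studies"] = 1
        return out

    records: dict = {}
    for table in assoc_tables:
        for row in table.itertuples(index=False):
            if not np.isfinite(row.beta):
                continue
            if row.snp not in records:
                records[row.snp] = {"ref": row, "betas": [row.beta],
                                    "ses": [row.se], "ns": [row.n]}
            else:
                entry = records[row.snp]
                ref = entry["ref"]
                b, matched = harmonize_to(ref.a1, ref.a2, row.a1, row.a2, row.beta)
                if matched:
                    entry["betas"].append(b)
                    entry["ses"].append(row.se)
                    entry["ns"].append(row.n)

    rows = []
    for snp, entry in records.items():
        ref = entry["ref"]
        betas = np.asarray(entry["betas"], dtype=float)
        ses = np.asarray(entry["ses"], dtype=float)
        k = len(betas)
        if k == 1:
            beta_meta, se_meta = betas[0], ses[0]
        else:
            w = 1.0 / ses ** 2
            beta_meta = float(np.sum(w * betas) / np.sum(w))
            se_meta = float(1.0 / np.sqrt(np.sum(w)))
        z = beta_meta / se_meta
        rows.append({"snp": snp, "chrom": ref.chrom, "pos": ref.pos,
                     "a1": ref.a1, "a2": ref.a2, "beta": beta_meta,
                     "se": se_meta, "z": z,
                     "p": max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)),
                     "n": float(np.nansum(entry["ns"])), "info": np.nan,
                     "eaf": np.nan, "single_study": k == 1, "n_studies": k})
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS + ["single_study", "n_studies"])
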