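"""Polarized binned-Z polygenicity test.

Target-study Z scores are re-signed ("polarized") so that each SNP's effect
allele is the risk allele of the discovery study (the allele with positive
discovery beta).  Under the null of no shared signal the polarized Z scores
have zero mean within any stratum of discovery P values; widespread weak true
associations shift the mean positive even in strata far from significance.
SNPs should be pre-thinned to an LD-clumped set so that within-bin Z scores
are approximately independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_qc import harmonize_to
from .errors import ConfigError

#: Discovery-P strata of one decile each; membership is left-open,
#: right-closed, so P = 1.0 falls in the top bin.
DEFAULT_BIN_EDGES = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


def polarize_z(discovery: pd.DataFrame, target: pd.DataFrame) -> pd.DataFrame:
    """Polarize target Z scores to the discovery risk allele.

    Returns a frame with columns ``snp``, ``z`` (polarized target Z) and
    ``p_discovery`` over the shared, harmonizable SNPs with a defined
    discovery risk allele (discovery beta != 0); the number of dropped SNPs
    is stored in ``.attrs['n_dropped']``.
    """
    disc = discovery.set_index("snp")
    targ = target.set_index("snp")
    shared = disc.index.intersection(targ.index)
    rows = []
    n_dropped = len(disc.index.union(targ.index)) - len(shared)
    for snp in shared:
        d = disc.loc[snp]
        t = targ.loc[snp]
        if not (np.isfinite(d["beta"]) and np.isfinite(t["beta"])) or d["beta"] == 0:
            n_dropped += 1
            continue
        beta_aligned, matched = harmonize_to(d["a1"], d["a2"], t["a1"], t["a2"],
                                             t["beta"])
        if not matched:
            n_dropped += 1
            continue
        z_aligned = beta_aligned / t["se"]
        rows.append({"snp": snp,
                     "z": float(np.sign(d["beta"]) * z_aligned),
                     "p_discovery": float(d["p"])})
    out = pd.DataFrame(rows, columns=["snp", "z", "p_discovery"])
    out.attrs["n_dropped"] = n_dropped
    return out


def binned_zero_mean_test(polarized: pd.DataFrame,
                          bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """One-sample t-test of mean(Z) = 0 within each discovery-P stratum.

    Bins are ``(lo, hi]``.  The P value is two-sided (a positive mean is the
    alternative of interest).  A bin with fewer than two SNPs, or with all Z
    equal, has undefined test fields; the degenerate all-equal-to-zero case
    is reported as p = 1.
    """
    edges = np.sort(np.asarray(bin_edges, dtype=float))
    if len(edges) < 2:
        raise ConfigError("need at least two bin edges")
    z = polarized["z"].to_numpy(dtype=float)
    p_disc = polarized["p_discovery"].to_numpy(dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (p_disc > lo) & (p_disc <= hi)
        zs = z[sel]
        n = int(sel.sum())
        mean = float(zs.mean()) if n else np.nan
        if n >= 2:
            sd = float(zs.std(ddof=1))
            if sd > 0:
                se = sd / np.sqrt(n)
                t = mean / se
                p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
            else:
                se, t = np.nan, np.nan
                p = 1.0 if mean == 0.0 else np.nan
        else:
            se = t = p = np.nan
        rows.append({"bin_lo": lo, "bin_hi": hi, "n_snps": n, "mean_z": mean,
                     "se_mean": se, "t": t, "p": p})
    return pd.DataFrame(rows)


def write_binned_z(table: pd.DataFrame, tsv_path) -> None:
    out = table.rename(columns={"bin_lo": "BIN_LO", "bin_hi": "BIN_HI",
                                "n_snps": "N_SNPS", "mean_z": "MEAN_Z",
                                "se_mean": "SE", "t": "T", "p": "P"})
    out.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
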