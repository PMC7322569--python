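"""Weight harmonization and per-sample genetic risk scores.

A GRS is ``score_i = sum_j w_j * g~_ij`` over the weight-table SNPs, where
``w_j`` is a per-allele log odds ratio and ``g~_ij`` the dosage of the effect
allele.  Before scoring, every weight is aligned to the target dataset:

* effect allele equals dataset allele1 -> dosage used as is;
* effect allele equals allele2 -> the dosage is reinterpreted as ``2 - g``
  (a flip flag; the weight itself is never negated);
* alleles match only after strand complementing -> strand-flipped, then
  aligned as above;
* strand-ambiguous variants (A/T, C/G) and irreconcilable mismatches are
  dropped, with an audit of kept/flipped/strand-flipped/dropped counts.

Missing dosages are imputed to twice the effect-allele frequency of the
scored dataset (``mean_dosage``, the default) or the SNP is omitted for that
sample (``omit``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import assoc_qc
from .assoc_qc import _complement, _is_ambiguous
from .errors import ComputationError, ConfigError
from .geno_io import MISSING, GenotypeDataset, ScoreVector
from .ld_clump import ClumpSpec, greedy_clump

MISSING_POLICIES = ("mean_dosage", "omit")

#: MHC tag SNPs for the major HLA risk haplotypes, by training population.
MHC_TAG_SNPS = {
    "EUR": ("rs2187668", "rs9267992"),
    "CHN": ("rs9271366", "rs9275328"),
}


def align_weights(weights: pd.DataFrame, dataset: GenotypeDataset):
    """Align a weight table to a dataset's variants and alleles.

    Returns ``(aligned, audit)``: ``aligned`` adds ``col`` (dataset column)
    and ``flip`` (score ``2 - g`` instead of ``g``) columns; ``audit`` counts
    kept / flipped / strand_flipped / dropped records.  An empty alignment is
    allowed (with a warning).
    """
    var = dataset.variants.set_index("snp")
    audit = {"kept": 0, "flipped": 0, "strand_flipped": 0,
             "dropped_absent": 0, "dropped_ambiguous": 0, "dropped_mismatch": 0}
    rows = []
    for w in weights.itertuples(index=False):
        if w.snp not in var.index:
            audit["dropped_absent"] += 1
            continue
        a1, a2 = var.at[w.snp, "a1"], var.at[w.snp, "a2"]
        if _is_ambiguous(a1, a2):
            audit["dropped_ambiguous"] += 1
            continue
        ea = w.ea
        strand_flipped = False
        if ea not in (a1, a2):
            ea = _complement(ea)
            strand_flipped = ea in (a1, a2)
            if not strand_flipped:
                audit["dropped_mismatch"] += 1
                continue
        flip = ea == a2
        audit["flipped" if flip else "kept"] += 1
        if strand_flipped:
            audit["strand_flipped"] += 1
        rows.append({"snp": w.snp, "ea": w.ea, "weight": w.weight,
                     "source": w.source, "col": int(var.index.get_loc(w.snp)),
                     "flip": flip})
    aligned = pd.DataFrame(rows, columns=["snp", "ea", "weight", "source",
                                          "col", "flip"])
    if aligned.empty and len(weights):
        warnings.warn("no weights could be aligned to the dataset", stacklevel=2)
    return aligned, audit


def score_samples(dataset: GenotypeDataset, aligned_weights: pd.DataFrame,
                  missing_policy: str = "mean_dosage",
                  n_snps_requested: int | None = None) -> ScoreVector:
    """Weighted risk score per sample from pre-aligned weights."""
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(f"missing_policy must be one of {MISSING_POLICIES}")
    if aligned_weights.empty:
        raise ComputationError("zero usable SNPs: cannot score samples")
    cols = aligned_weights["col"].to_numpy()
    flip = aligned_weights["flip"].to_numpy(dtype=bool)
    w = aligned_weights["weight"].to_numpy(dtype=float)

    g = dataset.dosages[:, cols].astype(float)
    miss = dataset.dosages[:, cols] == MISSING
    g[miss] = np.nan
    g = np.where(flip, 2.0 - g, g)      # NaN propagates through the flip
    if missing_policy == "mean_dosage":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fill = np.nanmean(g, axis=0)        # = 2 * effect-allele freq
        fill = np.nan_to_num(fill, nan=0.0)     # all-missing SNP contributes 0
        g = np.where(np.isnan(g), fill, g)
    else:
        g = np.nan_to_num(g, nan=0.0)
    scores = g @ w
    source = aligned_weights["source"].iloc[0] if len(aligned_weights) else "trained"
    return ScoreVector(
        scores=pd.Series(scores, index=dataset.samples["iid"].to_numpy(),
                         name="SCORE"),
        n_snps_requested=n_snps_requested if n_snps_requested is not None
        else len(aligned_weights),
        n_snps_used=len(aligned_weights),
        missing_policy=missing_policy,
        weight_source=str(source),
    )


def mhc_tag_weights(population: str, training_assoc: pd.DataFrame) -> pd.DataFrame:
    """Weight records for the two MHC tag SNPs of the training population.

    Weights (and effect alleles) come from the training association table;
    a tag absent from the table is omitted with a warning.
    """
    if population not in MHC_TAG_SNPS:
        raise ConfigError("population must be 'EUR' or 'CHN'")
    idx = training_assoc.set_index("snp")
    rows = []
    for snp in MHC_TAG_SNPS[population]:
        if snp not in idx.index or not np.isfinite(idx.at[snp, "beta"]):
            warnings.warn(f"MHC tag SNP {snp} absent from the training table; "
                          "omitted", stacklevel=2)
            continue
        rows.append({"snp": snp, "ea": idx.at[snp, "a1"],
                     "weight": float(idx.at[snp, "beta"]), "source": "mhc_tag"})
    return pd.DataFrame(rows, columns=["snp", "ea", "weight", "source"])


def restrict_overlap(weights: pd.DataFrame, dataset_a: GenotypeDataset,
                     dataset_b: GenotypeDataset):
    """Filter weights to variants present and alignable in both datasets."""
    aligned_a, _ = align_weights(weights, dataset_a)
    aligned_b, _ = align_weights(weights, dataset_b)
    shared = set(aligned_a["snp"]) & set(aligned_b["snp"])
    if not shared:
        raise ComputationError("no weight variants shared by both datasets")
    kept = weights[weights["snp"].isin(shared)].reset_index(drop=True)
    audit = {"requested": len(weights), "kept": len(kept),
             "dropped": len(weights) - len(kept)}
    return kept, audit


def weights_from_clump(assoc: pd.DataFrame, clump_result) -> pd.DataFrame:
    """Index-SNP training betas as a weight table (effect allele = a1)."""
    idx = assoc.set_index("snp")
    retained = clump_result.retained
    return pd.DataFrame({
        "snp": retained,
        "ea": [idx.at[s, "a1"] for s in retained],
        "weight": [float(idx.at[s, "beta"]) for s in retained],
        "source": "trained",
    }, columns=["snp", "ea", "weight", "source"])


def train_test_score(train_dataset: GenotypeDataset,
                     test_dataset: GenotypeDataset,
                     spec: ClumpSpec,
                     missing_policy: str = "mean_dosage",
                     outcome=None, covariates=None,
                     assoc: pd.DataFrame | None = None,
                     mhc_tags: str = "none") -> ScoreVector:
    """Full train->test scoring: GWAS, clump, weight, align, score.

    The clumping universe is the autosomes minus the MHC extended region.
    ``outcome`` defaults to the training .fam phenotype (2 = case); a
    precomputed training association table can be passed to avoid refitting
    when sweeping a grid.  ``mhc_tags`` in {'none', 'EUR', 'CHN'} appends the
    population's MHC tag-SNP weights (within-population scoring only).
    """
    if assoc is None:
        if outcome is None:
            outcome = (train_dataset.samples["phenotype"].to_numpy() == 2).astype(float)
        assoc = assoc_qc.snp_association(train_dataset, outcome,
                                         covariates=covariates)
    universe, _ = assoc_qc.variant_qc(
        train_dataset,
        exclude_regions=[assoc_qc.MHC_EXTENDED_REGION],
        exclude_chroms=["X", "23"])
    in_universe = assoc["snp"].isin(universe.variants["snp"])
    result = greedy_clump(assoc[in_universe], universe, spec)
    if not result.retained:
        raise ComputationError(
            f"no index SNPs at p1={spec.p1}: empty clump result")
    weights = weights_from_clump(assoc, result)
    if mhc_tags != "none":
        weights = pd.concat([weights, mhc_tag_weights(mhc_tags, assoc)],
                            ignore_index=True)
    n_requested = len(weights)
    aligned, _ = align_weights(weights, test_dataset)
    return score_samples(test_dataset, aligned, missing_policy,
                         n_snps_requested=n_requested)
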