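"""Experiment orchestration: simulate cohorts, GWAS -> clump -> score ->
evaluate for every training/testing pair, the polygenicity test, and the
severity/onset analyses, from a single config.

The config (a YAML-style mapping, see :class:`ExperimentConfig`) declares a
shared genome (SNP panel, LD, liability architecture), a set of cohorts with
roles (``discovery``, ``test``, ``cross_population``) and quota sizes, the
clumping grid, and scoring policies.  All randomness flows from the master
seed: the genome derives from it directly and each cohort receives a child
seed, so re-running the same config and seed reproduces every table.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import assoc_qc, evaluation, grs_engine, polygenic_test
from .errors import ConfigError, GrsPipeError
from .ld_clump import (DEFAULT_KB_GRID, DEFAULT_P1_GRID, DEFAULT_R2_GRID,
                       ClumpSpec, greedy_clump)
from .synthetic_cohort import SimConfig, simulate_case_control_cohort

_ROLES = ("discovery", "test", "cross_population")


@dataclass
class CohortSpec:
    role: str
    n_cases: int
    n_controls: int
    fst: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ConfigError(f"cohort role must be one of {_ROLES}")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; see ``from_yaml`` for the file form."""

    seed: int = 0
    genome: dict = field(default_factory=dict)       # SimConfig overrides
    cohorts: dict = field(default_factory=dict)      # name -> CohortSpec
    p1_list: tuple = DEFAULT_P1_GRID
    r2_list: tuple = DEFAULT_R2_GRID
    kb_list: tuple = DEFAULT_KB_GRID
    missing_policy: str = "mean_dosage"
    mhc_tags: str = "none"
    age_cutoff: float = 30.0
    severity_spec: tuple = (1e-5, 0.2, 250.0)        # (p1, r2, kb) for the severity GRS
    published_weights: str | None = None

    def __post_init__(self) -> None:
        if not self.cohorts:
            return
        roles = [c.role for c in self.cohorts.values()]
        if "discovery" not in roles:
            raise ConfigError("at least one discovery cohort is required")
        if not (len(self.p1_list) and len(self.r2_list) and len(self.kb_list)):
            raise ConfigError("grid lists must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohorts = {name: CohortSpec(**spec)
                   for name, spec in raw.get("cohorts", {}).items()}
        grid = raw.get("grid", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            genome=raw.get("genome", {}),
            cohorts=cohorts,
            p1_list=tuple(grid.get("p1", DEFAULT_P1_GRID)),
            r2_list=tuple(grid.get("r2", DEFAULT_R2_GRID)),
            kb_list=tuple(grid.get("kb", DEFAULT_KB_GRID)),
            missing_policy=raw.get("policies", {}).get("missing", "mean_dosage"),
            mhc_tags=raw.get("policies", {}).get("mhc_tags", "none"),
            age_cutoff=float(raw.get("policies", {}).get("age_cutoff", 30.0)),
            severity_spec=tuple(raw.get("policies", {}).get(
                "severity_spec", (1e-5, 0.2, 250.0))),
            published_weights=raw.get("published_weights"),
        )

    def config_hash(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "genome": self.genome,
            "cohorts": {k: vars(v) for k, v in sorted(self.cohorts.items())},
            "grid": [list(self.p1_list), list(self.r2_list), list(self.kb_list)],
            "policies": [self.missing_policy, self.mhc_tags, self.age_cutoff,
                         list(self.severity_spec)],
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_seed(master: int, index: int) -> int:
    state = np.random.SeedSequence((int(master), 777, index)).generate_state(1)
    return int(state[0] % (2 ** 31))


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns a report bundle of tables.

    Any stage failure is re-raised with the stage name attached; tables
    computed before the failure are preserved on the exception's ``partial``
    attribute.
    """
    bundle: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "timings": {}, "log": []}
    stage = "simulate"
    try:
        t0 = time.time()
        cohorts = {}
        for i, (name, spec) in enumerate(config.cohorts.items()):
            sim = SimConfig(seed=config.seed, fst=spec.fst, **config.genome)
            ds, truth = simulate_case_control_cohort(
                sim, spec.n_cases, spec.n_controls,
                cohort_seed=_cohort_seed(config.seed, i))
            cohorts[name] = {"spec": spec, "dataset": ds, "truth": truth}
            bundle["log"].append(
                f"simulated cohort {name}: {spec.n_cases} cases / "
                f"{spec.n_controls} controls, fst={spec.fst}")
        bundle["timings"][stage] = time.time() - t0

        stage = "gwas"
        t0 = time.time()
        lambdas = {}
        for name, c in cohorts.items():
            outcome = c["truth"].case.astype(float)
            c["assoc"] = assoc_qc.snp_association(c["dataset"], outcome)
            lambdas[name] = assoc_qc.genomic_inflation(c["assoc"]).lambda_gc
            bundle["log"].append(f"gwas {name}: lambda={lambdas[name]:.4f}")
        bundle["lambda_gc"] = lambdas
        bundle["timings"][stage] = time.time() - t0

        stage = "score_grid"
        t0 = time.time()
        bundle["auc_grid"] = _score_grid(config, cohorts)
        bundle["timings"][stage] = time.time() - t0

        stage = "polygenic_test"
        t0 = time.time()
        bundle["binned_z"] = _polygenicity(config, cohorts)
        bundle["timings"][stage] = time.time() - t0

        stage = "severity_onset"
        t0 = time.time()
        sev = _severity_onset(config, cohorts)
        bundle.update(sev)
        bundle["timings"][stage] = time.time() - t0
    except GrsPipeError as exc:
        exc.stage = stage
        exc.partial = bundle
        raise
    return bundle


def _pairs(config: ExperimentConfig):
    names = list(config.cohorts)
    eur = [n for n in names if config.cohorts[n].role in ("discovery", "test")]
    cross = [n for n in names if config.cohorts[n].role == "cross_population"]
    pairs = [(a, b, False) for a in eur for b in eur if a != b]
    disc = [n for n in names if config.cohorts[n].role == "discovery"]
    for c in cross:
        for d in disc:
            pairs.append((d, c, True))
            pairs.append((c, d, True))
    return pairs


def _score_grid(config: ExperimentConfig, cohorts: dict) -> pd.DataFrame:
    rows = []
    for train, test, is_cross in _pairs(config):
        tr, te = cohorts[train], cohorts[test]
        mhc = "none" if is_cross else config.mhc_tags
        for p1 in config.p1_list:
            for r2 in config.r2_list:
                for kb in config.kb_list:
                    spec = ClumpSpec(p1=p1, r2_max=r2, window_kb=kb)
                    try:
                        sv = grs_engine.train_test_score(
                            tr["dataset"], te["dataset"], spec,
                            missing_policy=config.missing_policy,
                            assoc=tr["assoc"], mhc_tags=mhc)
                    except GrsPipeError:
                        rows.append({"train": train, "test": test, "p1": p1,
                                     "r2": r2, "kb": kb, "n_snps": 0,
                                     "auc": np.nan, "ci_low": np.nan,
                                     "ci_high": np.nan})
                        continue
                    roc = evaluation.roc_auc(sv.scores.to_numpy(),
                                             te["truth"].case.astype(int))
                    rows.append({"train": train, "test": test, "p1": p1,
                                 "r2": r2, "kb": kb, "n_snps": sv.n_snps_used,
                                 "auc": roc.auc, "ci_low": roc.ci_low,
                                 "ci_high": roc.ci_high})
    return pd.DataFrame(rows)


def _polygenicity(config: ExperimentConfig, cohorts: dict) -> pd.DataFrame:
    disc_name = next(n for n, c in config.cohorts.items()
                     if c.role == "discovery")
    disc = cohorts[disc_name]
    frames = []
    thin_spec = ClumpSpec(p1=1.0, r2_max=0.1, window_kb=250.0)
    thinned = greedy_clump(disc["assoc"], disc["dataset"], thin_spec)
    keep = set(thinned.retained)
    disc_thin = disc["assoc"][disc["assoc"]["snp"].isin(keep)]
    for name, c in cohorts.items():
        if name == disc_name:
            continue
        pol = polygenic_test.polarize_z(disc_thin, c["assoc"])
        table = polygenic_test.binned_zero_mean_test(pol)
        table.insert(0, "target", name)
        table.insert(0, "discovery", disc_name)
        frames.append(table)
    return pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame()


def _severity_onset(config: ExperimentConfig, cohorts: dict) -> dict:
    disc_name = next(n for n, c in config.cohorts.items()
                     if c.role == "discovery")
    disc = cohorts[disc_name]
    p1, r2, kb = config.severity_spec
    spec = ClumpSpec(p1=p1, r2_max=r2, window_kb=kb)
    # fall back to the loosest grid threshold when nothing clears the
    # configured severity threshold (small panels / weak discovery GWAS)
    fallback = ClumpSpec(p1=max(config.p1_list), r2_max=r2, window_kb=kb)
    quintile_frames, glm_frames, anova_frames, level_rows = [], [], [], []
    for name, c in cohorts.items():
        truth = c["truth"]
        if truth.renal is None:
            continue
        try:
            sv = grs_engine.train_test_score(
                disc["dataset"], c["dataset"], spec,
                missing_policy=config.missing_policy, assoc=disc["assoc"])
        except GrsPipeError:
            try:
                sv = grs_engine.train_test_score(
                    disc["dataset"], c["dataset"], fallback,
                    missing_policy=config.missing_policy, assoc=disc["assoc"])
            except GrsPipeError:
                continue
        scores = sv.scores.to_numpy()
        case = truth.case
        renal = truth.renal
        onset = truth.onset

        level = np.where(case, np.where(renal == 1, 2, 1), 0)
        slope, p_trend = evaluation.ordinal_trend_test(scores, level)
        for lv, label in ((0, "control"), (1, "renal-"), (2, "renal+")):
            sel = level == lv
            level_rows.append({"cohort": name, "level": label,
                               "n": int(sel.sum()),
                               "mean_grs": float(scores[sel].mean()) if sel.any() else np.nan,
                               "sd_grs": float(scores[sel].std(ddof=1)) if sel.sum() > 1 else np.nan,
                               "trend_slope": slope, "trend_p": p_trend})

        cs = scores[case]
        cr = renal[case].astype(int)
        co = onset[case]
        qt = evaluation.quintile_or(cs, cr)
        qt.insert(0, "age_group", "all")
        qt.insert(0, "cohort", name)
        quintile_frames.append(qt)
        late = co > config.age_cutoff
        for label, sel in (("early", ~late), ("late", late)):
            if sel.sum() >= 10 and len(np.unique(cr[sel])) == 2:
                q = evaluation.quintile_or(cs[sel], cr[sel])
                q.insert(0, "age_group", label)
                q.insert(0, "cohort", name)
                quintile_frames.append(q)

        anova = evaluation.two_way_anova_grs(cs, late.astype(int), cr)
        anova.insert(0, "cohort", name)
        anova_frames.append(anova)

        glm_onset = evaluation.glm_association(
            co, pd.DataFrame({"grs": cs}), family="linear")
        glm_onset.insert(0, "model", "onset~grs")
        glm_renal = evaluation.glm_association(
            cr, pd.DataFrame({"grs": cs, "onset": co}), family="logistic")
        glm_renal.insert(0, "model", "renal~grs+onset")
        for gframe in (glm_onset, glm_renal):
            gframe.insert(0, "cohort", name)
            glm_frames.append(gframe)

    def _cat(frames):
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return {"quintile_or": _cat(quintile_frames),
            "score_by_level": pd.DataFrame(level_rows),
            "anova": _cat(anova_frames),
            "glm": _cat(glm_frames)}


def write_report(bundle: dict, out_dir) -> list:
    """Write the bundle as a JSON summary plus TSV tables; returns the paths."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary = {"config_hash": bundle.get("config_hash"),
               "seed": bundle.get("seed"),
               "lambda_gc": bundle.get("lambda_gc", {}),
               "timings": bundle.get("timings", {}),
               "log": bundle.get("log", [])}
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    written.append(spath)
    for key in ("auc_grid", "binned_z", "quintile_or", "score_by_level",
                "anova", "glm"):
        table = bundle.get(key)
        if table is None:
            continue
        path = out / f"{key}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
        written.append(path)
    return written
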