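"""End-to-end experiment driver and delimited-text I/O.

``run_experiment`` wires the stages together in the order the study design
requires: simulate (or load) → phenotype/quality selection → harmonize per
strategy → post-harmonization age/site-size selection → case/control
classification → site-distinguishability audit → permutation importance →
cross-strategy comparison.  The age-window selection deliberately runs
*after* the external harmonization fits, so the harmonizer estimates the
age trend on the widest available age range; the internal strategy refits
inside each fold of the final CV plan and is leakage-free by construction.

All randomness derives from a single master seed; every output is stamped
with the configuration hash and the seed so a run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_selection import (
    apply_age_and_site_selection,
    select_fqc,
    select_minsc,
    selection_report,
)
from .errors import ParameterError, SchemaError
from .evaluation import (
    make_cv_plan,
    run_asd_td,
    site_distinguishability,
)
from .feature_builder import FeatureMatrix
from .harmonization import (
    STRATEGY_NAMES,
    CovariateSpec,
    apply_model,
    fit_reference_model,
)
from .importance import compare_strategies, run_importance, top_fraction
from .synthetic_data import (
    PHENOTYPE_COLUMNS,
    SyntheticConfig,
    generate_cohort,
    generate_feature_matrix,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "read_tables",
    "write_tables",
    "read_phenotypes",
    "read_features",
    "write_features",
]

logger = logging.getLogger("combatcv")

_REQUIRED_PHENO = ["subject_id", "site", "diagnosis"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table (TSV/CSV), validating schema and ID uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _REQUIRED_PHENO if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing phenotype columns {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise SchemaError(
            f"{path}: duplicate subject IDs {dupes.tolist()[:5]} "
            f"(first at line {int(dupes.index[0]) + 2})"
        )
    return df


def read_features(path, kind: str = "structural") -> FeatureMatrix:
    """Read a feature matrix (first column = subject ID)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric feature columns {bad.tolist()[:5]}")
    return FeatureMatrix(df, kind=kind)


def read_tables(
    feature_path, phenotype_path, kind: str = "structural"
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Read and cross-validate a (phenotypes, features) pair."""
    pheno = read_phenotypes(phenotype_path)
    feats = read_features(feature_path, kind=kind)
    unknown = [s for s in feats.subject_ids if s not in set(pheno["subject_id"])]
    if unknown:
        raise SchemaError(
            f"feature matrix subjects missing from phenotypes: {unknown[:5]}"
        )
    return pheno, feats


def write_tables(phenotypes: pd.DataFrame, features: FeatureMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    write_features(features, outdir / f"features_{features.kind}.tsv")


def write_features(features: FeatureMatrix, path) -> None:
    path = Path(path)
    features.data.to_csv(path, sep="\t", index_label="subject_id")


@dataclass
class ExperimentConfig:
    """Everything a full experiment run needs, with desk-scale defaults."""

    # larger sites than the generator default so that the post-harmonization
    # age/site-size selection and the >=20-TD site audit retain every site
    synthetic: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(subjects_per_site=160)
    )
    feature_path: str | None = None     # real tables instead of simulation
    phenotype_path: str | None = None
    feature_kind: str = "structural"
    selection_variant: str = "fQC"      # minSC | fQC
    strategies: tuple[str, ...] = ("none", "external", "external45", "internal")
    cv_folds: int = 5
    cv_repetitions: int = 10
    seed: int = 0
    site_min_td: int = 20
    site_pcs: int = 20
    site_repetitions: int = 10
    importance_strategies: tuple[str, ...] = ("none", "external", "internal")
    importance_fraction: float = 0.30
    importance_shuffles: int = 5
    age_window: tuple[float, float] = (9.0, 20.0)
    min_site_n: int = 30
    output_dir: str = "results"

    def validate(self) -> None:
        for s in set(self.strategies) | set(self.importance_strategies):
            if s not in STRATEGY_NAMES:
                raise ParameterError(
                    f"unknown strategy {s!r}; expected one of {STRATEGY_NAMES}"
                )
        if self.selection_variant not in ("minSC", "fQC"):
            raise ParameterError(
                f"unknown selection variant {self.selection_variant!r}"
            )
        if self.feature_path is None:
            self.synthetic.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["strategies"] = list(self.strategies)
        d["importance_strategies"] = list(self.importance_strategies)
        d["age_window"] = list(self.age_window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        syn = SyntheticConfig(**d.pop("synthetic", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(synthetic=syn, **d)
        for name in ("strategies", "importance_strategies"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.age_window = tuple(cfg.age_window)
        return cfg


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_experiment(config: ExperimentConfig, write: bool = True) -> dict:
    """Run the full pipeline; returns (and optionally writes) a report bundle.

    The bundle holds per-strategy site-audit summaries (median / quartile
    pair AUCs), the case/control classification summary (mean ± SD AUC per
    strategy), importance tables, the cross-strategy agreement report, and
    reproducibility metadata (config hash, seed).
    """
    config.validate()
    t0 = _stage("inputs")
    spec = CovariateSpec()
    if config.feature_path is not None:
        phenotypes, features = read_tables(
            config.feature_path, config.phenotype_path, kind=config.feature_kind
        )
    else:
        phenotypes = generate_cohort(config.synthetic, seed=config.seed)
        features, _truth = generate_feature_matrix(
            phenotypes, config.synthetic, seed=config.seed,
            kind=config.feature_kind,
        )

    selector = select_minsc if config.selection_variant == "minSC" else select_fqc
    variant_ids = selector(phenotypes)
    if not variant_ids:
        raise SchemaError("selection removed every subject")
    age_ids = apply_age_and_site_selection(
        variant_ids, phenotypes,
        age_window=config.age_window, min_site_n=config.min_site_n,
    )
    if not age_ids:
        raise SchemaError(
            "age/site-size selection removed every subject; relax "
            "age_window/min_site_n or enlarge the cohort"
        )
    report = selection_report(
        phenotypes,
        {"all": phenotypes["subject_id"].tolist(),
         config.selection_variant: variant_ids,
         config.selection_variant + "as": age_ids},
    )
    logger.info("selection done in %.1fs", time.perf_counter() - t0)

    pheno_idx = phenotypes.set_index("subject_id")
    variant_features = features.subset(variant_ids)

    # CV plan on the final (post-age-selection) analysis set
    plan = make_cv_plan(
        pheno_idx.loc[age_ids, "diagnosis"],
        pheno_idx.loc[age_ids, "site"],
        k=config.cv_folds,
        repetitions=config.cv_repetitions,
        seed=config.seed,
    )

    def analysis_features(strategy: str) -> tuple[FeatureMatrix, str]:
        """Analysis-set features plus the strategy left for the CV loop.

        External variants harmonize on the wide-age variant set first, so
        the CV loop sees already-harmonized data (strategy 'none' slicing);
        'none' and 'internal' pass through, with internal refitting per fold
        on the training TD of the analysis set.
        """
        if strategy in ("none", "internal"):
            return features.subset(age_ids), strategy
        if strategy == "external":
            model = fit_reference_model(variant_features, phenotypes, spec=spec)
            H = apply_model(model, variant_features, phenotypes, spec=spec)
            return H.subset(age_ids), "none"
        raise ParameterError(f"strategy {strategy!r} not supported here")

    t0 = _stage("classification")
    classification = {}
    for strategy in config.strategies:
        if strategy == "external45":
            # per-repetition refits happen inside the strategy itself
            res = run_asd_td(
                features.subset(age_ids), phenotypes, "external45", plan,
                spec=spec, seed=config.seed + 11,
            )
        else:
            mat, inner = analysis_features(strategy)
            res = run_asd_td(mat, phenotypes, inner, plan, spec=spec)
            res.strategy = strategy
        classification[strategy] = res
    logger.info("classification done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("site audit")
    site_audit = {}
    for strategy in config.strategies:
        site_audit[strategy] = site_distinguishability(
            features.subset(age_ids), phenotypes, strategy, spec=spec,
            k=config.cv_folds, repetitions=config.site_repetitions,
            min_td=config.site_min_td, n_components=config.site_pcs,
            seed=config.seed + 23,
        )
    logger.info("site audit done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("importance")
    importance_tables = {}
    for strategy in config.importance_strategies:
        if strategy == "external45":
            importance_tables[strategy] = run_importance(
                features.subset(age_ids), phenotypes, "external45", plan,
                spec=spec, n_shuffles=config.importance_shuffles,
                seed=config.seed + 31,
            )
        else:
            mat, inner = analysis_features(strategy)
            table = run_importance(
                mat, phenotypes, inner, plan, spec=spec,
                n_shuffles=config.importance_shuffles, seed=config.seed + 31,
            )
            table.strategy = strategy
            importance_tables[strategy] = table
    reference = ("internal" if "internal" in importance_tables
                 else next(iter(importance_tables)))
    agreement = compare_strategies(
        importance_tables, reference, fraction=config.importance_fraction
    )
    logger.info("importance done in %.1fs", time.perf_counter() - t0)

    bundle = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "selection_report": report,
        "n_analysis_subjects": len(age_ids),
        "classification": {
            s: {"mean_auc": r.mean_auc, "sd_auc": r.sd_auc}
            for s, r in classification.items()
        },
        "site_audit": {s: r.summary() for s, r in site_audit.items()},
        "site_pair_aucs": {
            s: {f"{a}|{b}": v for (a, b), v in r.pair_means.items()}
            for s, r in site_audit.items()
        },
        "importance_agreement": {
            k: v for k, v in agreement.items() if k != "fold_correlations"
        },
        "_objects": {
            "classification": classification,
            "site_audit": site_audit,
            "importance": importance_tables,
            "agreement": agreement,
        },
    }
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {
            k: v for k, v in bundle.items()
            if k not in ("_objects", "selection_report")
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=2)
        report.to_csv(outdir / "selection_report.tsv", sep="\t", index=False)
        for s, table in importance_tables.items():
            table.as_frame().to_csv(
                outdir / f"importance_{s}.tsv", sep="\t"
            )
    return bundle
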