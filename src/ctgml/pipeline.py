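"""End-to-end pipeline: simulate -> features -> screen -> evaluate.

One :class:`PipelineConfig` drives every stage; a single global seed
deterministically derives per-stage seeds, and a manifest (config hash,
seed, package versions) is written with the run so any output file can be
regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (COLUMN_KINDS, GeneratorConfig, generate_cohort,
                     inject_bmi_missingness)
from .complexity import ComplexityConfig, ComplexityFeatures
from .modeling import (EvaluationSpec, LogisticOddsRatio, MixedNaiveBayes,
                       ResamplingSpec, evaluate_repeated)
from .screening import UnivariableScreen, candidate_features, impute_bmi
from .signals import write_signal_file

__all__ = ["PipelineConfig", "RECIPES", "run_pipeline",
           "write_cohort_csv", "read_cohort_csv"]

log = logging.getLogger("ctgml")

#: Model recipes: named predictor sets evaluated with both classifier
#: families.  "clinical+sisporto" is the multivariable clinical/CTG set;
#: the other two are the univariable non-linear index models.
RECIPES: dict[str, list[str]] = {
    "clinical+sisporto": ["maternal_age", "gestational_age", "male_fetus",
                          "prolonged_dec", "accelerations", "orange_alerts",
                          "mild_dec"],
    "cr2": ["CR2"],
    "mscsum": ["MSCsum"],
}

_CATEGORICAL_LEVELS = {
    "blood_group": {"A", "AB", "B", "O"},
    "rh": {"pos", "neg"},
    "pregnancy_type": {"spontaneous", "stimulation"},
    "fetal_presentation": {"cephalic", "non_cephalic"},
    "delivery_type": {"c_section", "vaginal", "vacuum"},
    "fetal_sex": {"male", "female"},
}


@dataclass
class PipelineConfig:
    """Configuration of a full reproducible run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    complexity: ComplexityConfig = field(default_factory=ComplexityConfig)
    evaluation: EvaluationSpec = field(default_factory=EvaluationSpec)
    resampling: ResamplingSpec = field(default_factory=ResamplingSpec)
    alpha: float = 0.2
    corr_threshold: float = 0.6
    n_bmi_missing: int = 47
    recipes: tuple[str, ...] = ("clinical+sisporto", "cr2", "mscsum")
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global seed, deterministically."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["group_params"] = {
            g: dataclasses.asdict(p)
            for g, p in self.generator.group_params.items()}
        return d


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort (or features) table written by this package.

    Empty cells become missing values; categorical levels are validated;
    duplicate subject ids and unknown columns are errors.
    """
    table = pd.read_csv(path, index_col="subject_id")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s) {dupes}")
    from .complexity import INDEX_NAMES
    known = set(COLUMN_KINDS) | {"outcome", "red_alerts"} | set(INDEX_NAMES)
    unknown = [c for c in table.columns if c not in known]
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {unknown}")
    for col, levels in _CATEGORICAL_LEVELS.items():
        if col in table.columns:
            bad = set(table[col].dropna().unique()) - levels
            if bad:
                raise ValueError(f"{path}: column {col!r} has invalid "
                                 f"level(s) {sorted(bad)}")
    return table


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d", name, n_in, n_out)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute simulate -> features -> impute -> screen -> evaluate.

    Writes all artifacts (signals, cohort and features CSVs, screen
    report, per-recipe evaluation summaries and per-repetition AUCs, a
    manifest and a log) into ``out_dir`` and returns the evaluation
    summaries keyed by ``(recipe, model_family)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> dict:
    gen_cfg = dataclasses.replace(config.generator,
                                  seed=config.stage_seed("simulate"))
    table, signals = generate_cohort(gen_cfg)
    _stage("simulate", 0, len(table))

    sig_dir = out_dir / "signals"
    sig_dir.mkdir(exist_ok=True)
    for sid, sig in signals.items():
        write_signal_file(sig, sig_dir / f"{sid}.txt")

    rng = np.random.default_rng(config.stage_seed("missingness"))
    table = inject_bmi_missingness(table, config.n_bmi_missing, rng)
    write_cohort_csv(table, out_dir / "cohort.csv")

    feats = ComplexityFeatures(
        m=config.complexity.m, r_fraction=config.complexity.r_fraction,
        n_scales=config.complexity.n_scales,
        compressor=config.complexity.compressor,
    ).fit().transform(signals.values())
    features = table.join(feats)
    write_cohort_csv(features, out_dir / "features.csv")
    _stage("features", len(table), len(features))

    features = impute_bmi(features)
    _stage("impute", len(features), len(features))

    y = features["outcome"].to_numpy()
    X = candidate_features(features)
    screen = UnivariableScreen(alpha=config.alpha,
                               corr_threshold=config.corr_threshold).fit(X, y)
    screen.report_.to_frame().to_csv(out_dir / "screen.csv")
    (out_dir / "screen_audit.json").write_text(json.dumps({
        "pruned": screen.report_.pruned, "selected": screen.selected_,
    }, indent=2))
    _stage("screen", X.shape[1], len(screen.selected_))

    summaries = {}
    rows = []
    for recipe in config.recipes:
        variables = RECIPES[recipe]
        for family, model in (("blr", LogisticOddsRatio()),
                              ("nb", MixedNaiveBayes())):
            summary = evaluate_repeated(
                X[variables], y, model, config.evaluation, config.resampling,
                seed=config.stage_seed(f"evaluate:{recipe}:{family}"),
                label=f"{recipe}/{family}")
            summaries[(recipe, family)] = summary
            rows.append({"recipe": recipe, "model": family,
                         "mean_auc": summary.mean_auc,
                         "ci_low": summary.ci_low,
                         "ci_high": summary.ci_high})
            pd.DataFrame({"auc": summary.aucs}).to_csv(
                out_dir / f"aucs_{recipe.replace('+', '_')}_{family}.csv",
                index_label="repetition")
            _stage(f"evaluate:{recipe}:{family}", len(y),
                   len(summary.aucs))
    pd.DataFrame(rows).to_csv(out_dir / "evaluation.csv", index=False)

    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"ctgml": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return summaries
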