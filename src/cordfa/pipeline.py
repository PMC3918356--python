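"""End-to-end orchestration: simulate/load → extract → expand → t-test →
select → classify → report.

A run is fully described by a :class:`RunConfig`; identical config + seed
gives an identical final report.  Every stage writes its output under the
run directory together with a ``manifest.json`` carrying the config, its
hash, the seed and the package version, so any stage can be re-executed
from its persisted inputs.

Entry modes
-----------
``synthetic``
    generate a per-slice base cohort from the calibrated generator;
``table``
    read a base (or already-expanded) feature CSV;
``image``
    read FA/mask image pairs (NIfTI-1 or ANALYZE), partition each ROI into
    quadrants and extract the base region means.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classify import kfold_cv, loocv, subject_aggregate
from .errors import ConfigError, DataError
from .features import EXPANDED_NAMES, expand_features, feature_ttests
from .io import load_fa_slice
from .roi_quadrants import Orientation, quadrant_labels, slices_to_table
from .selection import relieff_weights, rfs_rank, select_top
from .synthetic import CohortConfig, generate_feature_cohort
from .types import BASE_REGIONS, EvalReport, FeatureTable, SliceMeta

log = logging.getLogger("cordfa.pipeline")

SCHEMA_VERSION = 1


def _build(cls, raw: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**raw)


@dataclass
class SelectionConfig:
    method: str = "rfs"  # rfs | relieff | none
    n_features: int = 2
    k_neighbors: int = 7
    threshold: int = 3
    relieff_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("rfs", "relieff", "none"):
            raise ConfigError(f"unknown selection method {self.method!r}")


@dataclass
class ClassifierConfig:
    scheme: str = "kfold"  # kfold | loocv
    k: int = 5
    n_folds: int = 3
    subject_level: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "loocv"):
            raise ConfigError(f"unknown CV scheme {self.scheme!r}")


@dataclass
class RunConfig:
    """Complete description of one pipeline run."""

    mode: str = "synthetic"  # synthetic | table | image
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    input_table: str | None = None
    image_pairs: list = field(default_factory=list)
    center_method: str = "median"
    orientation: dict = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "table", "image"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if isinstance(self.selection, dict):
            self.selection = _build(SelectionConfig, self.selection, "selection")
        if isinstance(self.classifier, dict):
            self.classifier = _build(ClassifierConfig, self.classifier, "classifier")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema version {self.schema_version}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return _build(cls, dict(raw), "run config")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------- stages


def stage_acquire(config: RunConfig) -> FeatureTable:
    """Produce the base feature table for the configured entry mode."""
    if config.mode == "synthetic":
        raw = dict(config.cohort)
        if "class_means" in raw:
            raw["class_means"] = {
                k: tuple(v) for k, v in raw["class_means"].items()
            }
        raw.setdefault("seed", config.seed)
        cohort = _build(CohortConfig, raw, "cohort")
        table = generate_feature_cohort(cohort)
        log.info("simulate: %d slices from %d subjects", table.n_records,
                 cohort.n_patients + cohort.n_controls)
        return table
    if config.mode == "table":
        if not config.input_table:
            raise ConfigError("table mode requires input_table")
        table = FeatureTable.from_csv(config.input_table)
        log.info("load: %d records from %s", table.n_records, config.input_table)
        return table
    # image mode
    if not config.image_pairs:
        raise ConfigError("image mode requires image_pairs")
    orientation = _build(Orientation, dict(config.orientation), "orientation")
    slices, label_maps = [], []
    for pair in config.image_pairs:
        meta = SliceMeta(
            subject_id=str(pair.get("subject_id", "")),
            slice_id=int(pair.get("slice_id", 0)),
            class_label=int(pair["class"]),
        )
        fa = load_fa_slice(pair["fa"], pair["mask"], meta=meta)
        slices.append(fa)
        label_maps.append(
            quadrant_labels(
                fa.mask,
                orientation=orientation,
                center_method=config.center_method,
            )
        )
    log.info("extract: %d image slices", len(slices))
    return slices_to_table(slices, label_maps)


def stage_select(config: RunConfig, expanded: FeatureTable):
    """Rank features and pick the working subset; 'none' keeps all 15."""
    sel = config.selection
    if sel.method == "none":
        return None, list(expanded.feature_names)
    if sel.method == "rfs":
        ranking = rfs_rank(expanded, sel.k_neighbors, sel.threshold)
    else:
        ranking = relieff_weights(
            expanded, sel.k_neighbors, sel.relieff_iterations, seed=config.seed
        )
    chosen = select_top(ranking, sel.n_features)
    log.info("select: %s chose %s", sel.method, chosen)
    return ranking, chosen


def stage_classify(config: RunConfig, table: FeatureTable) -> EvalReport:
    clf = config.classifier
    if clf.subject_level:
        table = subject_aggregate(table)
    if clf.scheme == "loocv":
        return loocv(table, k=clf.k)
    return kfold_cv(table, n_folds=clf.n_folds, k=clf.k, seed=config.seed)


def run_pipeline(config: RunConfig, out_dir) -> EvalReport:
    """Execute all stages in order, persisting every intermediate.

    Writes under ``out_dir``: ``base.csv``, ``expanded.csv``,
    ``ttests.json``, ``ranking.csv``/``ranking.json`` (unless selection is
    disabled), ``report.json``, ``predictions.csv`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "acquire"
    try:
        base = stage_acquire(config)
        base.to_csv(out / "base.csv")

        stage = "expand"
        if base.feature_names == list(EXPANDED_NAMES):
            expanded = base  # table mode may hand us an expanded table
        else:
            expanded = expand_features(base)
        expanded.to_csv(out / "expanded.csv")

        stage = "ttest"
        ttests = feature_ttests(expanded)
        (out / "ttests.json").write_text(json.dumps(ttests.to_dict(), indent=2))

        stage = "select"
        ranking, chosen = stage_select(config, expanded)
        if ranking is not None:
            ranking.to_frame().to_csv(out / "ranking.csv", index=False)
            (out / "ranking.json").write_text(
                json.dumps(ranking.to_dict(), indent=2)
            )

        stage = "classify"
        report = stage_classify(config, expanded.subset(chosen))

        stage = "report"
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.predictions.to_csv(out / "predictions.csv", index=False)
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "config": config.to_dict(),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "cordfa_version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except (ConfigError, DataError) as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    log.info("report: %s", report.summary())
    return report
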