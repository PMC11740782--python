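"""Study orchestration: patient-exclusive splitting, the 16 training-data
combinations, classifier fan-out, and report generation.

Every combination concatenates the POCUS training images with zero or
more expanded views of the standard-ultrasound training cohort
(standard as-is, histogram-matched, equalized, or CycleGAN-translated);
ids 9-16 repeat ids 1-8 with random spatial augmentation during
training. All combinations are evaluated on the one held-out POCUS test
set. The sizes obey n_P, n_P + n_S, n_P + 2 n_S at any cohort scale.

A leakage audit records content hashes of every image used to fit
anything (pooled histograms, translators, classifiers) and asserts that
no test image, and no test patient, appears among them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentPolicy, policy_from_name
from .classifier import (CnnSpec, ScoreSet, TrainConfig, desk_cnn_spec, predict,
                         train_classifier)
from .cyclegan import CycleGANConfig, TranslatorPair, desk_cyclegan_config, train_regime, translate_cohort
from .evaluation import (RandomConvExtractor, balanced_accuracy, auc, binarize_malignant,
                         bootstrap_ci, constrained_youden, fid, roc_points,
                         sens_spec_at_threshold_ci, significance_matrix)
from .intensity_transforms import equalize, match_image_to_histogram, pooled_class_histogram
from .records import CLASSES, CohortManifest
from .synthetic_data import PhantomConfig, desk_config, generate_cohort

__all__ = ["CombinationSpec", "ExperimentConfig", "COMBINATIONS", "patient_split",
           "assemble_combination", "run_study", "report_tables", "StudyReport"]


@dataclass(frozen=True)
class CombinationSpec:
    id: int
    components: frozenset
    augmented: bool

    def label(self) -> str:
        names = {"pocus": "P", "standard": "US", "hist_match": "Hist. Match",
                 "hist_eq": "Hist. Eq.", "cyclegan1": "CycleGAN1", "cyclegan3": "CycleGAN3"}
        order = ["pocus", "standard", "hist_match", "hist_eq", "cyclegan1", "cyclegan3"]
        parts = [names[c] for c in order if c in self.components]
        if self.augmented:
            parts.append("Aug")
        return " + ".join(parts)


def _combo(i, comps, aug):
    return CombinationSpec(i, frozenset(comps), aug)


_BASE = [
    {"pocus"},
    {"pocus", "standard"},
    {"pocus", "hist_match"},
    {"pocus", "hist_eq"},
    {"pocus", "cyclegan1"},
    {"pocus", "cyclegan3"},
    {"pocus", "standard", "cyclegan1"},
    {"pocus", "standard", "cyclegan3"},
]

COMBINATIONS: dict[int, CombinationSpec] = {}
for _i, _c in enumerate(_BASE, start=1):
    COMBINATIONS[_i] = _combo(_i, _c, False)
    COMBINATIONS[_i + 8] = _combo(_i + 8, _c, True)


@dataclass
class ExperimentConfig:
    scale: str = "desk"                    # 'desk' or 'paper'
    n_patients_standard: int = 50
    n_patients_pocus: int = 140
    images_per_patient: tuple[int, int] = (1, 3)
    class_mix: dict = field(default_factory=lambda: {"normal": 0.57, "benign": 0.21,
                                                     "malignant": 0.22})
    test_fraction: float = 0.9
    combinations: tuple[int, ...] = tuple(range(1, 17))
    seed: int = 0
    alpha: float = 0.05
    bootstrap_B: int = 1000
    min_sensitivity: float = 0.90
    classifier_epochs: int | None = None   # None -> preset default
    translator_epochs: int | None = None

    def phantom_config(self) -> PhantomConfig:
        if self.scale == "desk":
            return desk_config(seed=self.seed, image_side=32)
        return PhantomConfig(seed=self.seed)

    def cnn_spec(self) -> CnnSpec:
        return desk_cnn_spec(32) if self.scale == "desk" else CnnSpec()

    def train_epochs(self) -> int:
        if self.classifier_epochs is not None:
            return self.classifier_epochs
        return 30 if self.scale == "desk" else 50

    def cyclegan_config(self, seed: int) -> CycleGANConfig:
        epochs = self.translator_epochs
        if self.scale == "desk":
            return desk_cyclegan_config(seed=seed, **({} if epochs is None else {"epochs": epochs}))
        return CycleGANConfig(seed=seed, **({} if epochs is None else {"epochs": epochs}))


# ---------------------------------------------------------------------------
# splitting


def patient_split(manifest: CohortManifest, test_fraction: float,
                  seed: int) -> CohortManifest:
    """Assign whole patients to train/test, targeting a test image fraction.

    Patients are shuffled and greedily moved to the test side until the
    realized test image fraction reaches the request.
    """
    patients = manifest.patient_ids()
    if len(patients) < 2:
        raise ValueError("patient split requires at least 2 patients")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    counts = {p: 0 for p in patients}
    for r in manifest:
        counts[r.patient_id] += 1
    total = len(manifest)
    rng = np.random.default_rng(seed)
    order = list(patients)
    rng.shuffle(order)
    split = {}
    in_test = 0
    for p in order:
        if in_test / total < test_fraction:
            split[p] = "test"
            in_test += counts[p]
        else:
            split[p] = "train"
    if all(s == "test" for s in split.values()):
        split[order[-1]] = "train"
    return CohortManifest(list(manifest.records), split=split)


# ---------------------------------------------------------------------------
# combination assembly


def assemble_combination(spec: CombinationSpec, pocus_train: CohortManifest,
                         expanded: dict[str, CohortManifest]) -> CohortManifest:
    """Concatenate the requested record sets for one training combination.

    ``expanded`` maps component name ('standard', 'hist_match', 'hist_eq',
    'cyclegan1', 'cyclegan3') to the corresponding expansion of the
    standard training cohort. Augmentation is a training-time flag and
    does not change the assembled size.
    """
    parts = [pocus_train]
    for comp in sorted(spec.components - {"pocus"}):
        if comp not in expanded:
            raise ValueError(f"combination {spec.id} needs component {comp!r} "
                             "which has not been built (train translators first?)")
        parts.append(expanded[comp])
    return parts[0].merged_with(*parts[1:])


def _equalize_cohort(manifest: CohortManifest) -> CohortManifest:
    return CohortManifest([r.with_pixels(equalize(r.pixels), provenance="hist_eq")
                           for r in manifest], split=manifest.split)


def _match_cohort(manifest: CohortManifest, histograms: dict) -> CohortManifest:
    recs = [r.with_pixels(match_image_to_histogram(r.pixels, histograms[r.class_label]),
                          provenance="hist_match") for r in manifest]
    return CohortManifest(recs, split=manifest.split)


# ---------------------------------------------------------------------------
# the study


@dataclass
class StudyReport:
    config: dict
    metrics: dict                  # combination id -> metric dict
    significance: dict             # ids, stars, raw/adjusted p matrices
    fid_table: dict                # data source -> FID to pocus train
    histories: dict                # combination id -> loss history
    leakage_audit: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(asdict(self)), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyReport":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def _hashes(*manifests: CohortManifest) -> set[str]:
    return {r.content_hash() for m in manifests for r in m}


def run_study(config: ExperimentConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full study on freshly generated synthetic cohorts.

    Generates the two-domain cohorts, splits the POCUS cohort by
    patient, builds every expansion the requested combinations need,
    trains one classifier per combination, and evaluates all of them on
    the common POCUS test set. When ``out_dir`` is given, per-combination
    score CSVs are cached there and reused on rerun.
    """
    for cid in config.combinations:
        if cid not in COMBINATIONS:
            raise ValueError(f"unknown combination id {cid}")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    phantom = config.phantom_config()

    standard = generate_cohort(config.n_patients_standard, config.images_per_patient,
                               config.class_mix, "standard", phantom, seed=seeds[0],
                               patient_prefix="std")
    pocus = generate_cohort(config.n_patients_pocus, config.images_per_patient,
                            config.class_mix, "pocus", phantom, seed=seeds[1],
                            patient_prefix="poc")
    pocus = patient_split(pocus, config.test_fraction, seed=seeds[2])
    pocus_train = pocus.subset("train")
    pocus_test = pocus.subset("test")

    fit_hashes: set[str] = set()
    needed = set().union(*(COMBINATIONS[c].components for c in config.combinations))
    expanded: dict[str, CohortManifest] = {}
    histograms = None
    if "standard" in needed:
        expanded["standard"] = standard
    if "hist_match" in needed:
        histograms = {c: pooled_class_histogram(pocus_train, c) for c in CLASSES}
        fit_hashes |= _hashes(pocus_train)
        expanded["hist_match"] = _match_cohort(standard, histograms)
    if "hist_eq" in needed:
        expanded["hist_eq"] = _equalize_cohort(standard)

    fid_table = {}
    translator_histories = {}
    regimes = [r for r in ("cyclegan1", "cyclegan3") if r in needed]
    if regimes:
        gan_pool = standard.merged_with(pocus_train)
        fit_hashes |= _hashes(standard, pocus_train)
        extractor = RandomConvExtractor(seed=seeds[3])
        fid_table["standard"] = fid(standard, pocus_train, extractor)
        for k, regime in enumerate(regimes):
            translators = train_regime(gan_pool, config.cyclegan_config(seeds[4] + k), regime)
            expanded[regime] = translate_cohort(standard, translators, regime_tag=regime)
            fid_table[regime] = fid(expanded[regime], pocus_train, extractor)
            translator_histories[regime] = {
                c: pair.history for c, pair in translators.items()
            } if regime == "cyclegan3" else {"all": translators["normal"].history}

    metrics: dict[int, dict] = {}
    histories: dict[int, list] = {}
    score_sets: dict[int, ScoreSet] = {}
    spec = config.cnn_spec()
    for cid in config.combinations:
        cspec = COMBINATIONS[cid]
        cache = out_dir / f"scores_combination_{cid:02d}.csv" if out_dir is not None else None
        test_set = pocus_test if "hist_eq" not in cspec.components else _equalize_cohort(pocus_test)
        if cache is not None and cache.exists():
            score_sets[cid] = ScoreSet.from_csv(cache, combination_id=cid)
            histories[cid] = []
        else:
            train_manifest = assemble_combination(cspec, pocus_train, expanded)
            fit_hashes |= _hashes(train_manifest)
            policy = policy_from_name("spatial") if cspec.augmented else None
            tconf = TrainConfig(epochs=config.train_epochs(),
                                learning_rate=1e-3 if config.scale == "desk" else 1e-4,
                                batch_size=8 if config.scale == "desk" else 32,
                                lr_decay=config.scale == "desk",
                                seed=seeds[5] + cid, augment_policy=policy)
            model, history = train_classifier(train_manifest, tconf, spec)
            histories[cid] = history
            score_sets[cid] = predict(model, test_set, spec, combination_id=cid)
            if cache is not None:
                score_sets[cid].to_csv(cache)
        metrics[cid] = evaluate_score_set(score_sets[cid], config, seed=seeds[6] + cid)
        metrics[cid]["label"] = cspec.label()
        metrics[cid]["n_train"] = len(assemble_combination(cspec, pocus_train, expanded))

    sig = None
    if len(score_sets) >= 2:
        sm = significance_matrix({c: score_sets[c] for c in config.combinations},
                                 alpha=config.alpha)
        sig = {"ids": sm.ids, "stars": sm.stars, "raw_p": sm.raw_p,
               "adjusted_p": sm.adjusted_p, "alpha": config.alpha}

    test_hashes = _hashes(pocus_test)
    test_patients = set(pocus_test.patient_ids())
    train_patients = set(pocus_train.patient_ids())
    audit = {
        "n_fit_images": len(fit_hashes),
        "n_test_images": len(test_hashes),
        "test_hash_overlap": len(fit_hashes & test_hashes),
        "patient_overlap": sorted(test_patients & train_patients),
        "passed": not (fit_hashes & test_hashes) and not (test_patients & train_patients),
    }

    report = StudyReport(config=_jsonable(asdict(config)), metrics=metrics,
                         significance=sig, fid_table=fid_table,
                         histories={"classifier": histories,
                                    "translator": translator_histories},
                         leakage_audit=audit)
    if out_dir is not None:
        report.to_json(out_dir / "report.json")
        report_tables(report, out_dir)
    return report


def run_augment_study(config: ExperimentConfig) -> dict:
    """Compare the three augmentation policies on the POCUS+standard data.

    Trains one classifier per policy (spatial, brightness/noise, both) on
    the combined POCUS + standard training cohort, evaluates on the
    POCUS test set, and reports AUCs with pairwise DeLong p-values.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    phantom = config.phantom_config()
    standard = generate_cohort(config.n_patients_standard, config.images_per_patient,
                               config.class_mix, "standard", phantom, seed=seeds[0],
                               patient_prefix="std")
    pocus = patient_split(
        generate_cohort(config.n_patients_pocus, config.images_per_patient,
                        config.class_mix, "pocus", phantom, seed=seeds[1],
                        patient_prefix="poc"),
        config.test_fraction, seed=seeds[2])
    train_manifest = pocus.subset("train").merged_with(standard)
    test = pocus.subset("test")
    spec = config.cnn_spec()
    score_sets = {}
    for k, policy_name in enumerate(("spatial", "brightness_noise", "both")):
        tconf = TrainConfig(epochs=config.train_epochs(),
                            learning_rate=1e-3 if config.scale == "desk" else 1e-4,
                            batch_size=8 if config.scale == "desk" else 32,
                            lr_decay=config.scale == "desk", seed=seeds[3] + k,
                            augment_policy=policy_from_name(policy_name))
        model, _ = train_classifier(train_manifest, tconf, spec)
        score_sets[policy_name] = predict(model, test, spec)
    sm = significance_matrix(score_sets, alpha=config.alpha)
    return {"aucs": sm.aucs, "stars": sm.stars, "ids": sm.ids,
            "adjusted_p": sm.adjusted_p.tolist()}


def evaluate_score_set(score_set: ScoreSet, config: ExperimentConfig,
                       seed: int = 0) -> dict:
    """Balanced accuracy, AUC, constrained operating point, and their CIs."""
    scores, labels = binarize_malignant(score_set)
    roc = roc_points(scores, labels)
    op = constrained_youden(roc, config.min_sensitivity)
    auc_value = auc(scores, labels)
    acc = balanced_accuracy(score_set)
    B = config.bootstrap_B
    auc_ci = bootstrap_ci(score_set,
                          lambda ss: auc(*binarize_malignant(ss)), B=B, seed=seed)
    acc_ci = bootstrap_ci(score_set, balanced_accuracy, B=B, seed=seed + 1)
    ss_ci = sens_spec_at_threshold_ci(score_set, op.threshold, B=B, seed=seed + 2)
    return {
        "acc": acc, "acc_ci": acc_ci,
        "auc": auc_value, "auc_ci": auc_ci,
        "threshold": op.threshold, "youden_j": op.J,
        "sens": op.sensitivity, "sens_ci": ss_ci["sensitivity"],
        "spec": op.specificity, "spec_ci": ss_ci["specificity"],
    }


def report_tables(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Render the accuracy/AUC, sensitivity/specificity and star-matrix tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_acc, rows_ss = [], []
    for cid, m in report.metrics.items():
        rows_acc.append({"combination": cid, "acc": m["acc"],
                         "acc_ci_lo": m["acc_ci"][0], "acc_ci_hi": m["acc_ci"][1],
                         "auc": m["auc"], "auc_ci_lo": m["auc_ci"][0],
                         "auc_ci_hi": m["auc_ci"][1]})
        rows_ss.append({"combination": cid, "sens": m["sens"],
                        "sens_ci_lo": m["sens_ci"][0], "sens_ci_hi": m["sens_ci"][1],
                        "spec": m["spec"], "spec_ci_lo": m["spec_ci"][0],
                        "spec_ci_hi": m["spec_ci"][1]})
    paths = {}
    paths["metrics"] = out_dir / "table_acc_auc.csv"
    pd.DataFrame(rows_acc).to_csv(paths["metrics"], index=False)
    paths["sens_spec"] = out_dir / "table_sens_spec.csv"
    pd.DataFrame(rows_ss).to_csv(paths["sens_spec"], index=False)
    if report.significance is not None:
        ids = report.significance["ids"]
        df = pd.DataFrame(report.significance["stars"], index=ids, columns=ids)
        paths["significance"] = out_dir / "table_significance.csv"
        df.to_csv(paths["significance"])
    return paths
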