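"""End-to-end orchestration: simulate -> preprocess -> fuse -> classify.

``run_pipeline`` drives the whole workflow from a single RunConfig and
returns (and optionally writes) every stage artifact plus a manifest of
output files with SHA-256 checksums; a rerun with the same config
reproduces identical checksums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .chemistry import annotate_peak, load_marker_table
from .classification import (
    ClassifierConfig,
    evaluate_test,
    repeated_grouped_cv,
    train_forest,
)
from .constants import BLOCK_ORDER
from .fusion_stats import (
    BlockSet,
    cluster_heatmap,
    low_level_fuse,
    mid_level_fuse,
    pca_scores,
    select_informative,
)
from .preprocessing import pareto_scale, preprocess_block
from .spectra_io import file_checksum, write_feature_matrix, write_peak_csv
from .synthetic_data import SyntheticConfig, generate_cohort, split_train_test

logger = logging.getLogger("insectprint")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_test: int = 8
    split_seed: int = 42
    ppm_isotope: float = 10.0
    ppm_align: float = 5.0
    missing_threshold: float = 0.75
    n_features: int = 18
    n_pls_components: int = 5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    out_dir: str | None = None

    _KNOWN = {
        "synthetic",
        "n_test",
        "split_seed",
        "ppm_isotope",
        "ppm_align",
        "missing_threshold",
        "n_features",
        "n_pls_components",
        "classifier",
        "out_dir",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            data["synthetic"] = SyntheticConfig(**data["synthetic"])
        if "classifier" in data and isinstance(data["classifier"], dict):
            data["classifier"] = ClassifierConfig(**data["classifier"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    samples: list
    blocks: BlockSet
    selected: list
    fused_train: object
    fused_test: object
    cv_report: object
    test_report: object
    annotations: dict
    species_mean: object
    manifest: dict


def build_blockset(
    spectra,
    train_ids: set[str],
    ppm_isotope: float = 10.0,
    ppm_align: float = 5.0,
    missing_threshold: float = 0.75,
) -> BlockSet:
    """Per-block preprocessing with training-derived Pareto parameters.

    Alignment, missingness filtering and imputation are unsupervised and
    run over all rows jointly; Pareto means/sds are learned on training
    rows only and applied unchanged to held-out rows.
    """
    blocks = {}
    for b in BLOCK_ORDER:
        block_spectra = [s for s in spectra if s.block == b]
        matrix = preprocess_block(
            block_spectra, ppm_isotope, ppm_align, missing_threshold
        )
        _, params = pareto_scale(matrix.rows_for(train_ids))
        scaled, _ = pareto_scale(matrix, params)
        blocks[b] = scaled
        logger.info(
            "block %s: %d spectra -> %d rows x %d bins",
            b, len(block_spectra), *scaled.values.shape,
        )
    return BlockSet(blocks)


def pipeline_cv(
    blocks: BlockSet,
    labels_by_sample: dict[str, str],
    train_ids: set[str],
    n_features: int = 18,
    n_pls_components: int = 5,
    classifier: ClassifierConfig | None = None,
) -> "object":
    """Leakage-free cross-validation of the whole selection+classification chain.

    Unlike :func:`insectprint.classification.repeated_grouped_cv` — which
    mirrors the reference protocol of selecting the informative ions once
    on the full training set before cross-validating the classifier —
    this variant re-runs the per-block PLS-DA/VIP selection inside every
    training fold, so no held-out replicate ever influences which ions
    the fold's classifier sees. This is the appropriate instrument for
    negative controls: supervised selection performed outside the folds
    biases no-signal accuracy upward.
    """
    import numpy as np
    from collections import Counter
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedGroupKFold

    from .classification import majority_vote, metrics_from_confusion

    cfg = classifier or ClassifierConfig()
    train_blocks = blocks.rows_for(train_ids)
    index = train_blocks.row_index
    sids = index.get_level_values("sample_id")
    y_rows = np.array([labels_by_sample[s] for s in sids])
    sample_ids = list(dict.fromkeys(sids))

    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(cfg.seed).spawn(cfg.cv_repeats)
    ]
    calls_per_sample: dict[str, list[str]] = {s: [] for s in sample_ids}
    repeat_acc = []
    for rep_seed in seeds:
        splitter = StratifiedGroupKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=rep_seed
        )
        repeat_calls: dict[str, str] = {}
        for tr_idx, va_idx in splitter.split(np.zeros(len(y_rows)), y_rows, groups=sids):
            fold_train_sids = set(sids[tr_idx])
            fold_val_sids = set(sids[va_idx])
            fold_blocks = train_blocks.rows_for(fold_train_sids)
            fold_labels = [
                labels_by_sample[s]
                for s in fold_blocks.row_index.get_level_values("sample_id")
            ]
            selected = select_informative(
                fold_blocks, fold_labels, total=n_features,
                n_components=n_pls_components,
            )
            fused = mid_level_fuse(train_blocks, selected)
            ftr = fused.rows_for(fold_train_sids)
            fva = fused.rows_for(fold_val_sids)
            model = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                max_features=cfg.max_features,
                random_state=rep_seed,
            ).fit(
                ftr.values.to_numpy(float),
                [labels_by_sample[s] for s in ftr.values.index.get_level_values("sample_id")],
            )
            repeat_calls.update(majority_vote(model, fva))
        correct = sum(repeat_calls[s] == labels_by_sample[s] for s in sample_ids)
        repeat_acc.append(correct / len(sample_ids))
        for s in sample_ids:
            calls_per_sample[s].append(repeat_calls[s])

    classes = sorted({labels_by_sample[s] for s in sample_ids})
    cidx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for s in sample_ids:
        modal = Counter(calls_per_sample[s]).most_common()
        top = modal[0][1]
        call = sorted(c for c, n in modal if n == top)[0]
        M[cidx[labels_by_sample[s]], cidx[call]] += 1
    report = metrics_from_confusion(M, classes)
    report.cv_repeat_accuracies = repeat_acc
    return report


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    cfg = config or RunConfig()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _manifest_params(cfg), "files": {}}

    samples, spectra = generate_cohort(cfg.synthetic)
    samples = split_train_test(samples, n_test=cfg.n_test, seed=cfg.split_seed)
    labels = {s.sample_id: s.species for s in samples}
    train_ids = {s.sample_id for s in samples if s.role == "train"}
    test_ids = {s.sample_id for s in samples if s.role == "test"}
    logger.info("cohort: %d samples (%d train / %d test), %d spectra",
                len(samples), len(train_ids), len(test_ids), len(spectra))
    if out:
        write_peak_csv(out / "cohort.csv", samples, spectra)

    blocks = build_blockset(
        spectra, train_ids, cfg.ppm_isotope, cfg.ppm_align, cfg.missing_threshold
    )
    if out:
        for b in BLOCK_ORDER:
            write_feature_matrix(blocks[b], out / f"matrix_{b}.tsv")

    # exploratory low-level fusion + PCA (recorded, not used downstream)
    fused_low = low_level_fuse(blocks)
    _, explained = pca_scores(fused_low, n_components=2)

    train_blocks = blocks.rows_for(train_ids)
    train_labels = [
        labels[sid] for sid in train_blocks.row_index.get_level_values("sample_id")
    ]
    selected = select_informative(
        train_blocks, train_labels, total=cfg.n_features,
        n_components=cfg.n_pls_components,
    )
    logger.info("selected %d informative ions: %s",
                len(selected), [f.label for f in selected])

    fused = mid_level_fuse(blocks, selected)
    fused_train = fused.rows_for(train_ids)
    fused_test = fused.rows_for(test_ids)

    cv_report = repeated_grouped_cv(fused_train, labels, cfg.classifier)
    model = train_forest(fused_train, labels, cfg.classifier)
    test_report = evaluate_test(model, fused_test, labels, train_sample_ids=train_ids)
    logger.info("CV: %d/%d training samples correct; test: %d/%d",
                cv_report.n_correct, cv_report.n_total,
                test_report.n_correct, test_report.n_total)

    table = load_marker_table()
    annotations = {}
    for feat in selected:
        polarity = "pos" if feat.block.endswith("pos") else "neg"
        hits = annotate_peak(feat.bin_mz, polarity, tol_ppm=5.0, table=table)
        annotations[feat.label] = [
            {"name": rec.name, "species": rec.species, "ppm_error": err}
            for rec, err in hits
        ]

    train_species = sorted(set(train_labels))
    row_link, col_link, species_mean = cluster_heatmap(
        fused_train,
        [labels[sid] for sid in fused_train.values.index.get_level_values("sample_id")],
    )
    assert set(species_mean.columns) == set(train_species)

    if out:
        species_mean.to_csv(out / "heatmap_species_mean.tsv", sep="\t")
        _write_linkage(row_link, out / "heatmap_row_linkage.txt")
        _write_linkage(col_link, out / "heatmap_col_linkage.txt")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "pca_explained_variance": [float(v) for v in explained],
                    "selected_features": [
                        {"label": f.label, "vip": f.vip, "rank": f.rank}
                        for f in selected
                    ],
                    "cv": cv_report.to_dict(),
                    "test": test_report.to_dict(),
                    "annotations": annotations,
                },
                fh,
                indent=2,
            )
        for path in sorted(out.iterdir()):
            if path.is_file():
                manifest["files"][path.name] = file_checksum(path)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineResult(
        samples=samples,
        blocks=blocks,
        selected=selected,
        fused_train=fused_train,
        fused_test=fused_test,
        cv_report=cv_report,
        test_report=test_report,
        annotations=annotations,
        species_mean=species_mean,
        manifest=manifest,
    )


def _manifest_params(cfg: RunConfig) -> dict:
    params = asdict(cfg)
    synth = params["synthetic"]
    if synth.get("marker_table") is not None:
        synth["marker_table"] = f"<{len(synth['marker_table'])} custom records>"
    return params


def _write_linkage(Z, path) -> None:
    """Text linkage format: one merge per line (left, right, height, size)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("left\tright\theight\tsize\n")
        for left, right, height, size in Z:
            fh.write(f"{int(left)}\t{int(right)}\t{height:.10g}\t{int(size)}\n")
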