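"""End-to-end phantom experiments used throughout the package.

Two standard study conditions are defined once here so tests, examples and
the reproduction script all run the same experiments:

* the **separable** cohort — lesion speckle markedly coarser than the
  surrounding texture (correlation lengths 4 vs 1.5 pixels), where both
  the texture-feature classifiers and the CNN should separate the classes
  well; and
* the **null** cohort — identical texture parameters inside and outside
  the lesion polygon, where any classifier should hover at chance.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .features import extract_feature_table
from .io_via import HCC, PAR
from .patches import Patch, SplitSpec, generate_patches, split_dataset
from .phantoms import PhantomSpec, TextureParams, generate_cohort

__all__ = [
    "separable_spec",
    "null_spec",
    "cohort_patches",
    "balanced_patch_dataset",
    "cohort_feature_table",
    "run_separable_experiment",
    "run_null_experiment",
]


def separable_spec() -> PhantomSpec:
    """Phantom spec with clearly distinct lesion and background speckle."""
    return PhantomSpec(
        image_size=(400, 400),
        inside_texture=TextureParams(correlation_length=4.0, mean_brightness=140.0, heterogeneity=0.2),
        outside_texture=TextureParams(correlation_length=1.5, mean_brightness=110.0, heterogeneity=0.2),
    )


def null_spec() -> PhantomSpec:
    """Phantom spec with identical inside/outside texture parameters."""
    params = TextureParams(correlation_length=2.0, mean_brightness=120.0, heterogeneity=0.2)
    return PhantomSpec(image_size=(400, 400), inside_texture=params, outside_texture=params)


def cohort_patches(
    spec: PhantomSpec,
    n_patients: int,
    images_per_patient: int,
    seed: int,
) -> list[Patch]:
    """Generate a cohort and extract every patch from every frame."""
    images = generate_cohort(n_patients, images_per_patient, spec, seed=seed)
    out: list[Patch] = []
    for image in images:
        out.extend(generate_patches(image))
    return out


def balanced_patch_dataset(
    patches: list[Patch],
    max_total: int | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Patch], list[Patch]]:
    """Patient-grouped train/validation split with per-class balancing.

    PAR windows outnumber HCC windows on phantom lesions (the boundary is
    long relative to the interior), so the majority class is subsampled to
    parity per patient before splitting; ``max_total`` optionally caps the
    dataset size. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[Patch]] = {}
    for p in patches:
        by_patient.setdefault(p.patient_id, []).append(p)

    balanced: list[Patch] = []
    for pid in sorted(by_patient):
        group = by_patient[pid]
        hcc = [p for p in group if p.label == HCC]
        par = [p for p in group if p.label == PAR]
        n = min(len(hcc), len(par))
        for cls in (hcc, par):
            idx = rng.permutation(len(cls))[:n]
            balanced.extend(cls[i] for i in sorted(idx))
    if max_total is not None and len(balanced) > max_total:
        idx = sorted(rng.permutation(len(balanced))[:max_total])
        balanced = [balanced[i] for i in idx]

    train, _, val = split_dataset(
        balanced,
        SplitSpec(
            train_fraction=1.0 - val_fraction,
            validation_fraction=0.0,
            test_fraction=val_fraction,
            group_by_patient=True,
            seed=seed,
        ),
    )
    return train, val


def cohort_feature_table(patches: list[Patch], **kwargs) -> tuple[pd.DataFrame, np.ndarray]:
    """47-feature table and label vector for a patch list."""
    df = extract_feature_table(patches, **kwargs)
    y = df.pop("label").to_numpy()
    df.pop("patient_id")
    return df, y


def run_separable_experiment(
    seed: int,
    n_patients: int = 20,
    images_per_patient: int = 5,
    max_total: int = 2000,
    nf: int = 16,
    epochs: int = 10,
) -> dict[str, float]:
    """End-to-end separability study on the coarse-vs-fine phantom cohort.

    Trains the scaled multi-resolution network (NF1 = NF2 = NF3 = ``nf``,
    SGD lr 1e-4, momentum 0.1, batch 64) on a patient-grouped 80/20 split
    of ~``max_total`` balanced patches, and a 100-tree random forest on the
    47 texture features of the same patches. Returns validation AUCs and
    accuracies for both routes.
    """
    from .classical import evaluate_model, fit, make_spec
    from .evaluation import roc_auc
    from .nn import CNNConfig, TrainConfig, build_model, patches_to_arrays, predict_proba, train

    patches = cohort_patches(separable_spec(), n_patients, images_per_patient, seed)
    train_p, val_p = balanced_patch_dataset(patches, max_total=max_total, seed=seed)

    model = build_model(CNNConfig(nf1=nf, nf2=nf, nf3=nf), seed=seed)
    tc = TrainConfig(epochs=epochs, batch_size=64, learning_rate=1e-4, momentum=0.1, seed=seed)
    model, history = train(model, train_p, val_p, tc)
    xv, yv = patches_to_arrays(val_p)
    labels = [HCC if v else PAR for v in yv]
    _, cnn_auc = roc_auc(labels, predict_proba(model, xv)[:, 1])

    X_train, y_train = cohort_feature_table(train_p)
    X_val, y_val = cohort_feature_table(val_p)
    rf = fit(make_spec("random_forest", seed=seed), X_train, y_train)
    rf_report = evaluate_model(rf, X_val, y_val)

    return {
        "cnn_val_auc": float(cnn_auc),
        "cnn_val_accuracy": float(history["best_val_accuracy"]),
        "rf_auc": float(rf_report.auc),
        "rf_accuracy": float(rf_report.accuracy),
        "n_train": len(train_p),
        "n_val": len(val_p),
    }


def run_null_experiment(
    seed: int,
    n_patients: int = 12,
    images_per_patient: int = 3,
    methods: tuple[str, ...] = ("svm_linear", "mlp", "random_forest", "adaboost_trees"),
    include_cnn: bool = True,
) -> dict[str, float]:
    """Chance-level control: identical textures inside and outside.

    Every classifier is trained and evaluated exactly like in the
    separable study; with no real class signal the test AUCs should hover
    at 0.5. The classical methods run at full scale on a stratified 50/50
    split (large test sets keep the chance-AUC spread narrow); the network
    runs in a reduced configuration (NF = 8, 2 epochs) since an epoch-long
    fit cannot move a null task away from chance anyway.
    """
    from .classical import make_spec, run_comparison
    from .evaluation import roc_auc
    from .nn import CNNConfig, TrainConfig, build_model, patches_to_arrays, predict_proba, train

    patches = cohort_patches(null_spec(), n_patients, images_per_patient, seed)
    X, y = cohort_feature_table(patches)
    report = run_comparison(
        X, y, [make_spec(m, seed=seed) for m in methods], test_fraction=0.5, seed=seed
    )
    aucs = {row["method"]: float(row["auc"]) for _, row in report.iterrows()}

    if include_cnn:
        train_p, val_p = balanced_patch_dataset(patches, val_fraction=0.5, seed=seed)
        model = build_model(CNNConfig(nf1=8, nf2=8, nf3=8), seed=seed)
        tc = TrainConfig(epochs=2, batch_size=64, learning_rate=1e-4, momentum=0.1, seed=seed)
        model, _ = train(model, train_p, val_p, tc)
        xv, yv = patches_to_arrays(val_p)
        labels = [HCC if v else PAR for v in yv]
        _, cnn_auc = roc_auc(labels, predict_proba(model, xv)[:, 1])
        aucs["cnn"] = float(cnn_auc)
    return aucs
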