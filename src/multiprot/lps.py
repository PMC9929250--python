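"""Linear-predictor-score (LPS) Bayes classifier for two molecular subtypes.

Each feature (by default the activities of two TFs) is z-scored on the
training cohort; the feature weight is its two-sample t-statistic between
the classes; a sample's LPS is the weighted sum of its z-scores. The LPS
distribution within each class is modelled as a Gaussian, and a new sample
is assigned by Bayes' rule with uniform priors; posteriors below the
certainty cutoff (default 0.75) leave the sample unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError


@dataclass
class LPSModel:
    classes: tuple
    weights: pd.Series                 # feature -> t-statistic weight
    feature_means: pd.Series           # training z-score parameters
    feature_sds: pd.Series
    class_means: dict                  # class -> Gaussian mean of LPS
    class_sds: dict                    # class -> Gaussian sd of LPS (MLE)
    priors: dict
    cutoff: float = 0.75
    training_lps: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    training_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def fit_lps(
    activity: pd.DataFrame,
    labels: pd.Series,
    features: list[str] | None = None,
    cutoff: float = 0.75,
) -> LPSModel:
    """Fit the predictor from a feature × sample frame and a two-class
    sample labeling. Class priors are uniform (the predictor is meant for
    external cohorts of unknown composition).
    """
    if not 0.5 < cutoff <= 1.0:
        raise ValidationError("certainty cutoff must lie in (0.5, 1]")
    features = list(features) if features is not None else list(activity.index)
    missing = [f for f in features if f not in activity.index]
    if missing:
        raise ValidationError(f"feature(s) absent from activity matrix: {missing}")
    common = [s for s in activity.columns if s in labels.index]
    labels = labels.loc[common]
    classes = tuple(sorted(labels.unique()))
    if len(classes) != 2:
        raise ValidationError(f"exactly two classes required, got {classes}")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValidationError("each class needs >= 3 samples")
    X = activity.loc[features, common].astype(float)
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    if (sd <= 0).any():
        raise ValidationError("zero variance feature in training data")
    Z = X.sub(mu, axis=0).div(sd, axis=0)
    c1, c2 = classes
    z1 = Z.loc[:, labels == c1]
    z2 = Z.loc[:, labels == c2]
    tstats = pd.Series(
        stats.ttest_ind(z1, z2, axis=1, equal_var=True).statistic, index=features
    )
    lps = Z.mul(tstats, axis=0).sum(axis=0)
    class_means, class_sds = {}, {}
    for cls in classes:
        vals = lps[labels == cls]
        class_means[cls] = float(vals.mean())
        sd_cls = float(vals.std(ddof=0))  # Gaussian MLE
        if sd_cls == 0:
            raise ValidationError(f"zero within-class LPS variance for class {cls!r}")
        class_sds[cls] = sd_cls
    return LPSModel(
        classes=classes,
        weights=tstats,
        feature_means=mu,
        feature_sds=sd,
        class_means=class_means,
        class_sds=class_sds,
        priors={c1: 0.5, c2: 0.5},
        cutoff=cutoff,
        training_lps=lps,
        training_labels=labels,
    )


def lps_posterior(model: LPSModel, lps_value: float) -> dict:
    """Posterior class probabilities for one LPS value under Bayes' rule."""
    dens = {
        cls: model.priors[cls]
        * stats.norm.pdf(lps_value, model.class_means[cls], model.class_sds[cls])
        for cls in model.classes
    }
    total = sum(dens.values())
    if total == 0:  # far tails; fall back to the nearer class in sd units
        dists = {
            cls: abs(lps_value - model.class_means[cls]) / model.class_sds[cls]
            for cls in model.classes
        }
        nearest = min(dists, key=dists.get)
        return {cls: 1.0 if cls == nearest else 0.0 for cls in model.classes}
    return {cls: d / total for cls, d in dens.items()}


def classify(
    model: LPSModel,
    z_values: pd.Series,
    strict: bool = False,
) -> dict:
    """Classify one sample given its standardized feature values.

    ``z_values`` must already be z-scores on the scale the caller chose
    (for an external cohort, that cohort's own standardization). Missing
    features are an error — no imputation happens at classification time.
    Returns posterior probabilities, the LPS, and the call (a class or
    ``unclassified`` below the certainty cutoff; ``strict`` forces the
    argmax class regardless of cutoff).
    """
    feats = list(model.weights.index)
    if z_values.reindex(feats).isna().any():
        missing = [f for f in feats if f not in z_values.index or pd.isna(z_values[f])]
        raise ValidationError(f"missing feature value(s): {missing}")
    lps_value = float((z_values.reindex(feats) * model.weights).sum())
    post = lps_posterior(model, lps_value)
    best = max(post, key=post.get)
    if strict or post[best] >= model.cutoff:
        call = best
    else:
        call = "unclassified"
    return {"lps": lps_value, "posterior": post, "call": call}


def classify_cohort(
    model: LPSModel,
    activity: pd.DataFrame,
    strict: bool = False,
    standardize: str = "cohort",
) -> pd.DataFrame:
    """Classify every sample of a feature × sample frame.

    ``standardize='cohort'`` z-scores each feature with the new cohort's own
    mean/sd (the convention for validating on an external cohort);
    ``'training'`` reuses the training parameters.
    """
    feats = list(model.weights.index)
    X = activity.loc[feats].astype(float)
    if standardize == "cohort":
        Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
    elif standardize == "training":
        Z = X.sub(model.feature_means, axis=0).div(model.feature_sds, axis=0)
    else:
        raise ValidationError("standardize must be 'cohort' or 'training'")
    rows = []
    for sample in Z.columns:
        res = classify(model, Z[sample], strict=strict)
        post = res["posterior"]
        rows.append(
            (sample, res["lps"], post[model.classes[0]], post[model.classes[1]], res["call"])
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "lps", f"posterior_{model.classes[0]}",
                 f"posterior_{model.classes[1]}", "call"],
    ).set_index("sample_id")
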