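"""End-to-end model-selection workflows.

Reproduces the selection ledger of the origin-discrimination study design:

* a normalization x scaling grid (standardized-area vs total-area;
  unit-variance vs Pareto) scored by autofit + permutation validity,
* a VIP cutoff sweep refitting the model on the retained variables,
* the binary Korea-vs-China OPLS-DA preset and the three one-vs-rest
  Chinese-region PLS-DA models with LOO-CV confusion reports,
* per-metabolite Welch comparisons of group levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classify import (
    ClassCoding,
    ConfusionMetrics,
    CrossValResult,
    classify_and_score,
    loo_cv,
    one_vs_rest_codings,
    permutation_test,
    roc_auc,
)
from .cohort import default_design, simulate_spectra
from .library import build_metabolite_library
from .pls import NipalsPLS, OPLS, autofit, fit_statistics, vip
from .preprocess import (
    BinnedMatrix,
    ColumnScaler,
    aggregate_metabolite_features,
    bin_spectra,
    normalize,
)

__all__ = [
    "ModelSelectionRow",
    "VipSweepRow",
    "grid_search_preprocessing",
    "vip_cutoff_sweep",
    "one_vs_rest_models",
    "compare_group_levels",
    "PRESETS",
    "run_preset",
]


@dataclass
class ModelSelectionRow:
    """One cell of the normalization x scaling selection grid."""

    normalization: str
    scaling: str
    signature: str
    r2y: float
    q2y: float
    r2y_intercept: float
    q2y_intercept: float
    valid: bool
    selected: bool = False

    def as_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "scaling": self.scaling,
            "components": self.signature,
            "R2Y": self.r2y,
            "Q2Y": self.q2y,
            "R2Y_intercept": self.r2y_intercept,
            "Q2Y_intercept": self.q2y_intercept,
            "valid": self.valid,
            "selected": self.selected,
        }


def _n_components_total(signature: str) -> int:
    if "+" in signature:
        a, b = signature.split("+")
        return int(a) + int(b)
    return int(signature)


def grid_search_preprocessing(
    binned: BinnedMatrix,
    labels,
    *,
    family: str = "opls",
    Y=None,
    normalizations=("standardized_area", "total_area"),
    scalings=("uv", "pareto"),
    max_components: int = 10,
    n_permutations: int = 100,
    seed: int = 0,
    aggregate=None,
    cv: int = 7,
) -> list[ModelSelectionRow]:
    """Score every normalization x scaling cell and mark the chosen one.

    Each cell is normalized, scaled, autofit (component count by greedy Q2Y),
    scored by stratified-CV fit statistics and a permutation test. The
    selected row is the one with the highest Q2Y among cells passing the
    validity bounds (R2Y intercept < 0.40, Q2Y intercept < 0.05); ties break
    by R2Y, then by fewer components. If no cell is valid, none is selected
    and a warning is issued.

    Parameters
    ----------
    binned : BinnedMatrix
        Raw (unnormalized) binned matrix.
    labels : array-like
        Class labels (used for stratification and, if ``Y`` is None, to
        build the response).
    Y : array-like, optional
        Response; defaults to a 0/1 code for two classes or a one-vs-rest
        indicator matrix for more.
    aggregate : MetaboliteLibrary, optional
        If given, bins are aggregated into per-metabolite features after
        normalization and before scaling.
    """
    labels = np.asarray(labels)
    if Y is None:
        classes = list(dict.fromkeys(labels))
        if len(classes) == 2:
            Y = (labels == classes[0]).astype(float)
        else:
            Y = np.column_stack([(labels == c).astype(float) for c in classes])
    rows: list[ModelSelectionRow] = []
    for norm in normalizations:
        nm = normalize(binned, norm)
        feats = (
            aggregate_metabolite_features(nm, aggregate).values
            if aggregate is not None
            else nm.values.values
        )
        for scal in scalings:
            scaler = ColumnScaler(method=scal)
            af = autofit(
                feats,
                Y,
                family=family,
                max_components=max_components,
                cv=cv,
                scaler=scaler,
                stratify=labels,
                random_state=seed,
            )
            perm = permutation_test(
                feats,
                Y,
                af.model,
                n_permutations=n_permutations,
                seed=seed,
                cv=cv,
                scaler=scaler,
                stratify=labels,
            )
            rows.append(
                ModelSelectionRow(
                    normalization=norm,
                    scaling=scal,
                    signature=af.signature,
                    r2y=af.statistics.r2y,
                    q2y=af.statistics.q2y,
                    r2y_intercept=perm.r2y_intercept,
                    q2y_intercept=perm.q2y_intercept,
                    valid=perm.valid,
                )
            )
    # a cell is selectable only if the permutation intercepts pass AND the
    # model has positive cross-validated predictability (Q2Y <= 0 means the
    # intercept line is flat at a useless model, which the bounds alone
    # cannot exclude)
    valid_rows = [r for r in rows if r.valid and r.q2y > 0]
    if not valid_rows:
        warnings.warn("no grid cell passed the permutation validity bounds")
    else:
        best = max(
            valid_rows,
            key=lambda r: (r.q2y, r.r2y, -_n_components_total(r.signature)),
        )
        best.selected = True
    return rows


@dataclass
class VipSweepRow:
    """One VIP cutoff evaluated against the base model's variable ranking."""

    cutoff: float
    n_variables: int
    signature: str = ""
    r2y: float = float("nan")
    q2y: float = float("nan")
    r2y_intercept: float = float("nan")
    q2y_intercept: float = float("nan")
    feasible: bool = True
    variables: tuple[int, ...] = field(default_factory=tuple)


def vip_cutoff_sweep(
    X,
    Y,
    *,
    family: str = "opls",
    cutoffs=(0.0, 0.5, 1.0, 1.5, 2.0),
    scaling: str = "uv",
    max_components: int = 10,
    n_permutations: int | None = None,
    seed: int = 0,
    stratify=None,
    cv: int = 7,
) -> list[VipSweepRow]:
    """Refit the model on VIP-thresholded variable subsets.

    VIP scores come from the full-data base model (autofit on all
    variables) and are *not* recomputed after each refit; the cutoff-0 row
    is the base model itself. Cutoffs retaining fewer than two variables
    are flagged infeasible.
    """
    X = np.asarray(X, dtype=float)
    scaler = ColumnScaler(method=scaling)
    kwargs = dict(
        family=family,
        max_components=max_components,
        cv=cv,
        scaler=scaler,
        stratify=stratify,
        random_state=seed,
    )
    base = autofit(X, Y, **kwargs)
    base_scaler = ColumnScaler(method=scaling).fit(X)
    base_model = type(base.model)(**base.model.get_params()).fit(
        base_scaler.transform(X), Y
    )
    scores = vip(base_model)
    rows: list[VipSweepRow] = []
    for cut in cutoffs:
        keep = np.nonzero(scores >= cut)[0]
        if len(keep) < 2:
            rows.append(
                VipSweepRow(cutoff=cut, n_variables=len(keep), feasible=False)
            )
            continue
        af = autofit(X[:, keep], Y, **kwargs)
        row = VipSweepRow(
            cutoff=cut,
            n_variables=len(keep),
            signature=af.signature,
            r2y=af.statistics.r2y,
            q2y=af.statistics.q2y,
            variables=tuple(int(i) for i in keep),
        )
        if n_permutations:
            perm = permutation_test(
                X[:, keep],
                Y,
                af.model,
                n_permutations=n_permutations,
                seed=seed,
                cv=cv,
                scaler=scaler,
                stratify=stratify,
            )
            row.r2y_intercept = perm.r2y_intercept
            row.q2y_intercept = perm.q2y_intercept
        rows.append(row)
    return rows


def one_vs_rest_models(
    X,
    labels,
    *,
    model_factory=None,
    family: str = "pls",
    max_components: int = 6,
    scaling: str = "uv",
    variables=None,
    sample_ids=None,
    seed: int = 0,
) -> list[tuple[ClassCoding, CrossValResult, ConfusionMetrics]]:
    """Three case-vs-rest LOO-CV models for a three-class design.

    Each class in turn is the case (coded 1) against the pooled other two
    (coded 0). By default each binary model's component count is chosen by
    autofit on its own full-data response (then frozen inside the LOO
    folds); pass ``model_factory`` to impose one configured model on all
    three comparisons. Every model is scored by LOO-CV confusion metrics,
    yielding a three-row sensitivity/specificity/accuracy report.
    """
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) != 3:
        raise ValueError(f"expected exactly 3 classes, got {len(classes)}")
    Xa = np.asarray(X, dtype=float)
    Xsel = Xa[:, np.asarray(variables, dtype=int)] if variables is not None else Xa
    out = []
    for coding in one_vs_rest_codings(classes):
        if model_factory is None:
            af = autofit(
                Xsel,
                coding.encode(labels),
                family=family,
                max_components=max_components,
                scaler=ColumnScaler(method=scaling),
                stratify=labels,
                random_state=seed,
            )
            model = af.model
        else:
            model = model_factory()
        res = loo_cv(
            Xa,
            labels,
            coding,
            model,
            scaling=scaling,
            variables=variables,
            sample_ids=sample_ids,
        )
        out.append((coding, res, classify_and_score(res)))
    return out


def one_vs_rest_report(results) -> pd.DataFrame:
    """Tabulate one-vs-rest results as a classification-performance table."""
    return pd.DataFrame(
        [
            {
                "class": coding.name,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "accuracy": cm.accuracy,
            }
            for coding, _res, cm in results
        ]
    )


def compare_group_levels(
    features: pd.DataFrame,
    labels,
    *,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-metabolite two-group comparison by Welch's t-test.

    Reports the ratio of group means (first group over second), the
    direction of the difference, the two-sided p-value and a significance
    flag at ``alpha``. Multiplicity correction is off by default
    ("holm" or "bonferroni" to enable). Metabolites with zero variance in
    both groups get p = 1 and a degenerate flag.
    """
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("compare_group_levels requires exactly 2 groups")
    a, b = (features.loc[labels == g] for g in groups)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 samples")
    rows = []
    for m in features.columns:
        xa, xb = a[m].values, b[m].values
        degenerate = xa.std(ddof=1) < 1e-15 and xb.std(ddof=1) < 1e-15
        if degenerate:
            p = 1.0
        else:
            p = float(sstats.ttest_ind(xa, xb, equal_var=False).pvalue)
        ratio = float(xa.mean() / xb.mean()) if xb.mean() != 0 else float("inf")
        rows.append(
            {
                "metabolite": m,
                "mean_ratio": ratio,
                "higher_in": groups[0] if ratio > 1 else groups[1],
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("metabolite")
    p = table["p_value"].values.copy()
    if correction == "bonferroni":
        p = np.minimum(p * len(p), 1.0)
    elif correction == "holm":
        order = np.argsort(p)
        stepped = np.maximum.accumulate(
            np.minimum((len(p) - np.arange(len(p))) * p[order], 1.0)
        )
        p_adj = np.empty_like(p)
        p_adj[order] = stepped
        p = p_adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    table["p_adjusted"] = p
    table["significant"] = (p < alpha) & ~table["degenerate"]
    return table


def korea_china_tables(seed: int):
    """Simulate the default cohort and return (features, bin matrix, labels).

    Features are the total-area-normalized, metabolite-aggregated table the
    two-class origin model consumes.
    """
    design = default_design()
    library = build_metabolite_library()
    spectra = simulate_spectra(design, seed)
    binned = bin_spectra(spectra)
    normed = normalize(binned, "total_area")
    feats = aggregate_metabolite_features(normed, library)
    return feats, binned, binned.metadata["country"].values


def validity_simulation(seed: int, *, n_permutations: int = 100, n_orthogonal: int = 2):
    """Permutation-validation of the two-class model on a simulated cohort.

    Default cohort, total-area normalization, unit-variance scaling,
    OPLS-DA with 1 predictive + ``n_orthogonal`` orthogonal components,
    ``n_permutations`` label permutations. Returns the
    :class:`~soynmr.classify.PermutationResult` whose R2Y/Q2Y intercepts are
    checked against the 0.40 / 0.05 validity bounds.
    """
    feats, _binned, labels = korea_china_tables(seed)
    y = (labels == "Korea").astype(float)
    return permutation_test(
        feats.values,
        y,
        OPLS(n_orthogonal=n_orthogonal),
        n_permutations=n_permutations,
        seed=seed,
        scaler=ColumnScaler(method="uv"),
        stratify=labels,
    )


def korea_china_loo_accuracy(seed: int, *, n_orthogonal: int = 2) -> float:
    """End-to-end LOO-CV accuracy (%) of the two-class origin model."""
    feats, _binned, labels = korea_china_tables(seed)
    coding = ClassCoding(class_names=("Korea", "China"), case_class="Korea")
    res = loo_cv(
        feats.values,
        labels,
        coding,
        OPLS(n_orthogonal=n_orthogonal),
        scaling="uv",
        sample_ids=list(feats.index),
    )
    return classify_and_score(res).accuracy


def marker_retention(seed: int, *, cutoff: float = 1.0, n_orthogonal: int = 2) -> int:
    """How many of the nine planted country markers pass the VIP cutoff."""
    from .cohort import KOREA_CHINA_MARKERS

    feats, _binned, labels = korea_china_tables(seed)
    y = (labels == "Korea").astype(float)
    Xs = ColumnScaler(method="uv").fit(feats.values).transform(feats.values)
    scores = vip(OPLS(n_orthogonal=n_orthogonal).fit(Xs, y))
    by_name = dict(zip(feats.columns, scores))
    return sum(1 for m in KOREA_CHINA_MARKERS if by_name[m] >= cutoff)


#: Named preset configurations for the two headline analyses. The two-class
#: model uses total-area normalization + UV scaling + OPLS-DA with no VIP
#: cutoff; the Chinese-region model uses standardized-area normalization +
#: UV scaling + PLS-DA with a VIP cutoff of 1.0.
PRESETS = {
    "korea_china": {
        "labels": "country",
        "family": "opls",
        "normalization": "total_area",
        "scaling": "uv",
        "vip_cutoff": None,
        "features": "metabolites",
    },
    "china_regions": {
        "labels": "region_class",
        "subset_country": "China",
        "family": "pls",
        "normalization": "standardized_area",
        "scaling": "uv",
        "vip_cutoff": 1.0,
        # bin-level features: unsupervised 0.04-ppm bin sums cannot untangle
        # the sugar envelope the way per-compound deconvolution does, so the
        # three-region models select discriminating bins directly
        "features": "bins",
    },
}


def run_preset(
    name: str,
    seed: int,
    *,
    n_permutations: int = 100,
    max_components: int = 6,
    design=None,
) -> dict:
    """Simulate the default cohort and run one preset analysis end to end.

    Returns a dict with the binned matrix, metabolite features, grid ledger,
    the LOO-CV result(s), confusion metrics, ROC AUC(s) and the permutation
    diagnostics of the preset model. Deterministic given ``seed``.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    design = design or default_design()
    library = build_metabolite_library()
    spectra = simulate_spectra(design, seed)
    binned = bin_spectra(spectra)
    meta = binned.metadata
    if "subset_country" in cfg:
        keep = (meta["country"] == cfg["subset_country"]).values
        binned = BinnedMatrix(
            values=binned.values.loc[keep],
            bin_edges=binned.bin_edges,
            normalization=binned.normalization,
            reference_areas=binned.reference_areas[keep],
            metadata=meta.loc[keep].reset_index(drop=True),
            scheme=binned.scheme,
        )
        meta = binned.metadata
    labels = meta[cfg["labels"]].values
    normed = normalize(binned, cfg["normalization"])
    feats = aggregate_metabolite_features(normed, library)
    # model-form selection and permutation diagnostics run on the compact
    # metabolite table; classification may run at bin resolution (presets)
    X = feats.values
    if cfg.get("features") == "bins":
        cls_table = normed.values
    else:
        cls_table = feats
    X_cls = cls_table.values

    grid = grid_search_preprocessing(
        binned,
        labels,
        family=cfg["family"],
        max_components=max_components,
        n_permutations=n_permutations,
        seed=seed,
        aggregate=library,
    )

    classes = list(dict.fromkeys(labels))
    if len(classes) == 2:
        Y = (labels == classes[0]).astype(float)
    else:
        Y = np.column_stack([(labels == c).astype(float) for c in classes])
    scaler = ColumnScaler(method=cfg["scaling"])
    af = autofit(
        X,
        Y,
        family=cfg["family"],
        max_components=max_components,
        cv=7,
        scaler=scaler,
        stratify=labels,
        random_state=seed,
    )
    variables = None
    sweep = None
    if cfg["vip_cutoff"] is not None:
        sweep = vip_cutoff_sweep(
            X_cls,
            Y,
            family=cfg["family"],
            cutoffs=(0.0, 0.5, cfg["vip_cutoff"], 1.5),
            scaling=cfg["scaling"],
            max_components=max_components,
            seed=seed,
            stratify=labels,
        )
        chosen = next(r for r in sweep if r.cutoff == cfg["vip_cutoff"])
        if chosen.feasible:
            variables = list(chosen.variables)

    perm = permutation_test(
        X,
        Y,
        af.model,
        n_permutations=n_permutations,
        seed=seed,
        scaler=scaler,
        stratify=labels,
    )

    sample_ids = list(cls_table.index)
    if len(classes) == 2:
        coding = ClassCoding(class_names=tuple(classes), case_class=classes[0])
        res = loo_cv(
            X_cls,
            labels,
            coding,
            af.model,
            scaling=cfg["scaling"],
            variables=variables,
            sample_ids=sample_ids,
        )
        models = [(coding, res, classify_and_score(res))]
    else:
        models = one_vs_rest_models(
            X_cls,
            labels,
            family=cfg["family"],
            max_components=max_components,
            scaling=cfg["scaling"],
            variables=variables,
            sample_ids=sample_ids,
            seed=seed,
        )
    aucs = {
        coding.name: roc_auc(res.ypredcv.values, res.true_case.values)
        for coding, res, _cm in models
    }
    return {
        "preset": name,
        "seed": seed,
        "binned": binned,
        "features": feats,
        "grid": grid,
        "autofit": af,
        "vip_sweep": sweep,
        "selected_variables": variables,
        "permutation": perm,
        "models": models,
        "report": one_vs_rest_report(models)
        if len(classes) != 2
        else pd.DataFrame(
            [
                {
                    "class": models[0][0].name,
                    "sensitivity": models[0][2].sensitivity,
                    "specificity": models[0][2].specificity,
                    "accuracy": models[0][2].accuracy,
                }
            ]
        ),
        "auc": aucs,
    }
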