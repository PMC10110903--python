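"""Final prognosticators and the end-to-end pipeline.

Phase 1 trains the segmentation U-Net (no outcome information enters);
Phase 2 extracts each patient's bottleneck latent vector, clusters features
into medoids, retains outcome-associated medoid features with the LASSO and
fits an unpenalized logistic model per endpoint on the 2-year binary
outcome; Phase 3 predicts 2-year event probabilities for the reserved test
patients, dichotomizes them at 50% into low/high-risk groups, and compares
the groups with the censored survival statistics (Kaplan-Meier, log-rank,
Cox hazard ratio, Harrell's c).

All supervised state — standardization constants, medoids, the LASSO
penalty, and logistic weights — is computed on the non-test patients only;
patients censored before two years without an event carry no 2-year label
and are excluded from supervised fitting (they still receive predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import deep_features, segnet, survival_stats
from .deep_features import FeaturePanel, lasso_select, select_k_silhouette
from .phantoms import PhantomConfig, PhantomPatient, generate_cohort
from .survival_stats import SurvivalRecord

ENDPOINTS = ("os", "dss", "lpfs")


@dataclass
class CVPlan:
    n_total: int
    test_ids: list
    folds: list            # list of (train_ids, val_ids)
    n_folds: int
    seed: int


@dataclass
class RiskPrediction:
    patient_id: str
    endpoint: str
    probability: float
    risk_group: str        # "low" | "high"
    cutoff: float = 0.5


@dataclass
class LogisticModel:
    coefficients: np.ndarray
    intercept: float
    feature_ids: np.ndarray
    separation_flagged: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coefficients):
            raise ValueError("feature count mismatch with training")
        return 1.0 / (1.0 + np.exp(-(X @ self.coefficients + self.intercept)))


def make_cv_plan(patient_ids, labels, n_folds: int = 6,
                 test_fraction: float = 0.2, seed: int = 0) -> CVPlan:
    """Seeded, outcome-stratified test split + CV folds on the remainder.

    Patients with missing labels can appear in the test set but never in a
    training/validation fold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = list(patient_ids)
    labels = list(labels)
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(ids)))
    # stratified test draw: sample proportionally within label strata
    strata: dict = {}
    for i, lab in enumerate(labels):
        strata.setdefault(lab if lab is not None else "__missing__", []).append(i)
    test_idx: list[int] = []
    for key in sorted(strata, key=str):
        members = strata[key]
        take = int(round(n_test * len(members) / len(ids)))
        test_idx.extend(rng.permutation(members)[:take].tolist())
    test_idx = sorted(test_idx)[:n_test]
    test_set = set(test_idx)
    cv_idx = [i for i in range(len(ids)) if i not in test_set
              and labels[i] is not None]
    y = np.asarray([labels[i] for i in cv_idx], dtype=int)
    if len(cv_idx) < n_folds:
        raise ValueError("not enough labeled patients for the folds")
    folds = []
    if min(np.bincount(y)) >= n_folds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(cv_idx)), y)
    else:
        warnings.warn("fold count exceeds a class count; "
                      "falling back to unstratified folds")
        from sklearn.model_selection import KFold
        splits = KFold(n_splits=n_folds, shuffle=True,
                       random_state=seed).split(np.zeros(len(cv_idx)))
    for tr, va in splits:
        folds.append(([ids[cv_idx[i]] for i in tr],
                      [ids[cv_idx[i]] for i in va]))
    return CVPlan(n_total=len(ids), test_ids=[ids[i] for i in test_idx],
                  folds=folds, n_folds=n_folds, seed=seed)


def fit_prognosticator(X: np.ndarray, y: np.ndarray,
                       feature_ids=None) -> LogisticModel:
    """Unpenalized logistic MLE by Newton-Raphson (gradient norm < 1e-8).

    Perfect or quasi-perfect separation (diverging coefficients or a
    singular step) is flagged and the fit falls back to a light L2 penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    ids = np.arange(X.shape[1]) if feature_ids is None \
        else np.asarray(feature_ids)
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    separated = False
    for _ in range(200):
        eta = np.clip(Xd @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (y - mu)
        if np.linalg.norm(grad) < 1e-8:
            break
        w = np.maximum(mu * (1 - mu), 1e-12)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta += step
        if p and np.max(np.abs(beta[1:])) > 30:
            separated = True
            break
    else:
        separated = separated or np.linalg.norm(grad) >= 1e-8
    if separated:
        warnings.warn("perfect separation detected; L2-stabilized fit used")
        coef, b0 = deep_features._newton_logistic(X, y, ridge=1.0)
        return LogisticModel(coefficients=coef, intercept=b0,
                             feature_ids=ids, separation_flagged=True)
    return LogisticModel(coefficients=beta[1:], intercept=float(beta[0]),
                         feature_ids=ids)


def predict_and_dichotomize(model: LogisticModel, X: np.ndarray,
                            patient_ids, endpoint: str = "os",
                            cutoff: float = 0.5) -> list[RiskPrediction]:
    """Probabilities and 50%-cutoff risk groups; p == cutoff -> high risk."""
    probs = model.predict_proba(X)
    return [RiskPrediction(patient_id=pid, endpoint=endpoint,
                           probability=float(p),
                           risk_group="high" if p >= cutoff else "low",
                           cutoff=cutoff)
            for pid, p in zip(patient_ids, probs)]


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class DesepConfig:
    """Knobs of phases 1-3 at desk scale."""

    net: segnet.UNetConfig = field(
        default_factory=lambda: segnet.UNetConfig.preset("desk"))
    n_seg_train: int = 20              # phase-1 training volumes
    k_grid: tuple[int, ...] = (4, 8, 16, 24)
    lambda_grid: tuple[float, ...] = tuple(np.geomspace(1e-3, 3.0, 10))
    max_pam_features: int = 4096
    n_folds: int = 6
    test_fraction: float = 0.25
    cutoff: float = 0.5
    seed: int = 0


@dataclass
class EndpointReport:
    endpoint: str
    predictions: list
    harrells_c: float | None
    hr: float | None
    hr_ci: tuple | None
    logrank_chi2: float | None
    logrank_p: float | None
    n_test: int = 0
    n_high: int = 0
    retained_features: int = 0
    hr_monotone_flagged: bool = False


def _two_year_label(p: PhantomPatient, endpoint: str):
    return getattr(p, f"two_year_{endpoint}")


def extract_panel(model: segnet.SegNetModel,
                  patients: list[PhantomPatient]) -> FeaturePanel:
    latents = [segnet.extract_latent(model, p.baseline_volume)
               for p in patients]
    return FeaturePanel.from_latents(np.asarray(latents))


def run_desep(cohort, config: DesepConfig | None = None,
              endpoints=ENDPOINTS, seg_model: segnet.SegNetModel | None = None,
              ) -> dict:
    """Run phases 1-3 on a phantom cohort (list of patients or directory).

    Returns a report dict with per-endpoint predictions and survival
    comparisons; fully reproducible given the config seed. A pre-trained
    segmentation model may be supplied (it must not have seen the cohort's
    test patients), in which case phase 1 is skipped.
    """
    from .phantoms import load_cohort

    cfg = config or DesepConfig()
    if isinstance(cohort, (str, )) or hasattr(cohort, "joinpath"):
        patients, _ = load_cohort(cohort)
    else:
        patients = list(cohort)
    ids = [p.patient_id for p in patients]
    by_id = {p.patient_id: p for p in patients}
    labels_os = [_two_year_label(p, "os") for p in patients]
    plan = make_cv_plan(ids, labels_os, n_folds=cfg.n_folds,
                        test_fraction=cfg.test_fraction, seed=cfg.seed)
    test_set = set(plan.test_ids)
    cv_ids = [i for i in ids if i not in test_set]

    # Phase 1 — segmentation training on non-test patients only
    if seg_model is None:
        seg_train = [by_id[i] for i in cv_ids[:cfg.n_seg_train]]
        seg_model = segnet.build_model(cfg.net)
        segnet.train(seg_model,
                     [(p.baseline_volume, p.baseline_mask) for p in seg_train],
                     cfg.net)

    # Phase 2 — latent panel; all constants fitted on non-test patients
    cv_patients = [by_id[i] for i in cv_ids]
    panel = extract_panel(seg_model, cv_patients)
    panel.fit_standardization()
    k_star, sil_scores = select_k_silhouette(
        panel, cfg.k_grid, seed=cfg.seed, max_features=cfg.max_pam_features)
    medoids = deep_features.cluster_features(
        panel, k_star, seed=cfg.seed, max_features=cfg.max_pam_features)
    z_cv = panel.zscored()[:, medoids.medoid_columns]

    test_patients = [by_id[i] for i in plan.test_ids]
    if test_patients:
        test_panel = extract_panel(seg_model, test_patients)
        z_test = panel.zscored(test_panel.matrix)[:, medoids.medoid_columns]
    else:
        z_test = np.zeros((0, len(medoids.medoid_columns)))

    report = {"config_seed": cfg.seed, "k_selected": int(k_star),
              "silhouette_scores": {int(k): float(v)
                                    for k, v in sil_scores.items()},
              "cv_plan": plan, "endpoints": {}}

    for ep in endpoints:
        labels = [_two_year_label(p, ep) for p in cv_patients]
        keep = [i for i, lab in enumerate(labels) if lab is not None]
        y = np.asarray([labels[i] for i in keep], dtype=float)
        X = z_cv[keep]
        if np.unique(y).size < 2:
            warnings.warn(f"endpoint {ep}: single-class labels; skipped")
            continue
        sel = lasso_select(X, y, lambda_grid=cfg.lambda_grid,
                           cv_folds=cfg.n_folds, seed=cfg.seed)
        if len(sel.retained_columns) == 0:
            X_fit = np.zeros((len(y), 0))
            model = LogisticModel(
                coefficients=np.zeros(0),
                intercept=float(np.log(y.mean() / (1 - y.mean()))),
                feature_ids=np.zeros(0, dtype=int))
            X_pred = np.zeros((len(test_patients), 0))
        else:
            X_fit = X[:, sel.retained_columns]
            model = fit_prognosticator(
                X_fit, y, feature_ids=medoids.medoid_feature_ids[
                    sel.retained_columns])
            X_pred = z_test[:, sel.retained_columns]
        preds = predict_and_dichotomize(model, X_pred, plan.test_ids,
                                        endpoint=ep, cutoff=cfg.cutoff)
        records = [SurvivalRecord(time=getattr(by_id[pr.patient_id], f"{ep}_time"),
                                  event=getattr(by_id[pr.patient_id], f"{ep}_event"),
                                  group_or_score=pr.probability)
                   for pr in preds]
        c = None
        try:
            c = survival_stats.harrells_c(records)
        except ValueError:
            pass
        hi = [r for r, pr in zip(records, preds) if pr.risk_group == "high"]
        lo = [r for r, pr in zip(records, preds) if pr.risk_group == "low"]
        hr = ci = chi2 = pval = None
        monotone = False
        if hi and lo:
            chi2, pval = survival_stats.logrank(lo, hi)
            grp = [SurvivalRecord(r.time, r.event, 1.0 if pr.risk_group == "high"
                                  else 0.0) for r, pr in zip(records, preds)]
            try:
                cox = survival_stats.cox_hr_binary(grp)
                hr, ci = cox.hr, (cox.ci_low, cox.ci_high)
                monotone = cox.monotone_likelihood
            except ValueError:
                pass
        report["endpoints"][ep] = EndpointReport(
            endpoint=ep, predictions=preds, harrells_c=c, hr=hr, hr_ci=ci,
            logrank_chi2=chi2, logrank_p=pval, n_test=len(preds),
            n_high=len(hi), retained_features=len(sel.retained_columns),
            hr_monotone_flagged=monotone)
    report["seg_model"] = seg_model
    return report
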