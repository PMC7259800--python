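"""Weighted multiparametric mutation score (WMMS): least-squares weight training.

The unit-weighted MMS treats all parameters as equally informative.  Here the
parameter weights are trained against the clinical outcome score by ordinary
least squares: the design matrix has one parameter vector per training unit
(unique mutation for homozygous cohorts, patient for compound-heterozygous
cohorts, plus zero-COS healthy controls) and the response is the COS.
The fitted coefficients replace the unit weights, and the WMMS of a mutation
or genotype is the dot product of its parameter vector with the trained
weights — the intercept is fitted for the regression but excluded from
reported scores, so an all-zero vector always scores 0.

Organised in the statsmodels idiom: build a :class:`WmmsModel` from data,
call :meth:`WmmsModel.fit`, and read estimates and diagnostics off the
returned :class:`WmmsResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import features as _features
from .errors import ContractError, ValidationError
from .features import ALL_PARAMETERS, FeatureConfig, unit_signs

PROVENANCES = ("unweighted", "homozygous_trained", "heterozygous_trained", "trained")


@dataclass
class WeightSet:
    """Trained or unit parameter weights, with provenance and fit quality."""

    weights: pd.Series
    intercept: float = 0.0
    provenance: str = "unweighted"
    fit_r2: float | None = None

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "unweighted":
            expected = unit_signs().reindex(self.weights.index)
            if not np.allclose(self.weights, expected) or self.intercept != 0:
                raise ValidationError(
                    "unweighted provenance requires unit signs and zero intercept"
                )
            if self.fit_r2 is not None:
                raise ValidationError("unweighted weights carry no fit R²")

    def to_json(self, path):
        payload = {
            "weights": {k: float(v) for k, v in self.weights.items()},
            "intercept": float(self.intercept),
            "provenance": self.provenance,
            "fit_r2": None if self.fit_r2 is None else float(self.fit_r2),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "WeightSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=pd.Series(payload["weights"]),
            intercept=payload["intercept"],
            provenance=payload["provenance"],
            fit_r2=payload["fit_r2"],
        )


def unit_weightset() -> WeightSet:
    """The untrained weight set: +1 per parameter, −1 for cons_substitution."""
    return WeightSet(weights=unit_signs(), intercept=0.0, provenance="unweighted")


def wmms_score(v: pd.Series, w: WeightSet) -> float:
    """WMMS of a parameter vector: Σ weight·value, intercept excluded.

    The weight set may cover a subset of the vector's keys (a printed weight
    table may omit parameters that never fire), but any parameter the vector
    actually triggers must have a weight.
    """
    missing = v.index.difference(w.weights.index)
    if len(missing) and (v[missing] != 0).any():
        raise ContractError(
            f"vector triggers parameters with no weight: {sorted(missing)}"
        )
    shared = v.index.intersection(w.weights.index)
    return float((v[shared] * w.weights[shared]).sum())


class WmmsModel:
    """OLS model of COS on mutation parameter vectors.

    Parameters
    ----------
    exog : DataFrame
        One parameter vector per row; columns are parameter keys.
    endog : array-like
        Clinical outcome score per row, each in [0, 12].
    labels : sequence, optional
        Row labels (mutation names or patient ids).
    provenance : str
        Recorded on the results ("homozygous_trained", ...).
    """

    def __init__(self, exog: pd.DataFrame, endog, labels=None, provenance="trained"):
        exog = pd.DataFrame(exog).astype(float)
        endog = np.asarray(endog, dtype=float)
        if exog.shape[0] != endog.shape[0]:
            raise ContractError("exog and endog row counts differ")
        if exog.shape[0] < 2:
            raise ContractError("need at least 2 training rows")
        if ((endog < 0) | (endog > _cohort.MAX_COS)).any():
            raise ValidationError("response values must lie in [0, 12]")
        if labels is None:
            labels = list(exog.index)
        self.exog = exog.reset_index(drop=True)
        self.endog = endog
        self.labels = list(labels)
        self.provenance = provenance

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_homozygous_cohort(
        cls,
        records,
        annotations: dict,
        controls: pd.DataFrame | None = None,
        cfg: FeatureConfig | None = None,
    ) -> "WmmsModel":
        """Design with one row per unique homozygous mutation (COS averaged
        across carriers) plus optional zero-COS control vectors."""
        mean_cos = _cohort.aggregate_homozygous_cos(records)
        rows, ys, labels = [], [], []
        for mut, cos in mean_cos.items():
            if mut not in annotations:
                raise ValidationError(f"no annotation for mutation {mut}")
            rows.append(_features.derive_parameter_vector(annotations[mut], cfg))
            ys.append(cos)
            labels.append(mut)
        X = pd.DataFrame(rows)
        if controls is not None:
            X = pd.concat([X, controls.reindex(columns=X.columns, fill_value=0.0)])
            ys.extend([0.0] * len(controls))
            labels.extend(list(controls.index))
        return cls(X, ys, labels=labels, provenance="homozygous_trained")

    @classmethod
    def from_heterozygous_cohort(
        cls,
        records,
        annotations: dict,
        controls: pd.DataFrame | None = None,
        cfg: FeatureConfig | None = None,
    ) -> "WmmsModel":
        """Design with one composite (0.5-per-allele) row per patient plus
        optional zero-COS control vectors."""
        rows, ys, labels = [], [], []
        for r in records:
            cos = _cohort.compute_cos(r)
            if cos is None:
                continue
            a1 = _allele_spec(r.allele1, r.allele1_class, annotations)
            a2 = _allele_spec(r.allele2, r.allele2_class, annotations)
            rows.append(_features.combine_heterozygous(a1, a2, cfg))
            ys.append(cos)
            labels.append(r.patient_id)
        X = pd.DataFrame(rows)
        if controls is not None:
            X = pd.concat([X, controls.reindex(columns=X.columns, fill_value=0.0)])
            ys.extend([0.0] * len(controls))
            labels.extend(list(controls.index))
        return cls(X, ys, labels=labels, provenance="heterozygous_trained")

    # ------------------------------------------------------------------ #

    def fit(self, fit_intercept: bool = True) -> "WmmsResults":
        """Ordinary least squares; minimum-norm solution if rank deficient.

        Columns that are identically zero in the design cannot be estimated:
        their weight is pinned to 0 and they are recorded on the results.
        """
        X = self.exog
        y = self.endog
        active = [c for c in X.columns if (X[c] != 0).any()]
        pinned = [c for c in X.columns if c not in active]
        A = X[active].to_numpy()
        if fit_intercept:
            xm, ym = A.mean(axis=0), y.mean()
            coef, _, rank, _ = np.linalg.lstsq(A - xm, y - ym, rcond=None)
            intercept = float(ym - xm @ coef)
        else:
            coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            intercept = 0.0
        weights = pd.Series(0.0, index=X.columns)
        weights[active] = coef
        fitted = A @ coef + intercept
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return WmmsResults(
            model=self,
            weights=weights,
            intercept=intercept,
            rsquared=r2,
            fitted=fitted,
            pinned_zero=pinned,
            rank_deficient=rank < len(active),
            fit_intercept=fit_intercept,
        )


def _allele_spec(name, allele_class, annotations):
    if allele_class == "missense":
        if name not in annotations:
            raise ValidationError(f"no annotation for missense allele {name}")
        return _features.AlleleSpec(name, "missense", annotations[name])
    return _features.AlleleSpec(name, allele_class)


class WmmsResults:
    """Trained weights, fit diagnostics and scoring methods."""

    def __init__(
        self,
        model: WmmsModel,
        weights: pd.Series,
        intercept: float,
        rsquared: float,
        fitted: np.ndarray,
        pinned_zero: list,
        rank_deficient: bool,
        fit_intercept: bool,
    ):
        self.model = model
        self.weights = weights
        self.intercept = intercept
        self.rsquared = rsquared
        self.fittedvalues = fitted
        self.pinned_zero = pinned_zero
        self.rank_deficient = rank_deficient
        self.fit_intercept = fit_intercept

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def sse(self) -> float:
        return float((self.resid**2).sum())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Regression prediction (intercept included) for new vectors."""
        X = pd.DataFrame(X).reindex(columns=self.weights.index, fill_value=0.0)
        return X.to_numpy() @ self.weights.to_numpy() + self.intercept

    def score_vector(self, v: pd.Series) -> float:
        """WMMS of one parameter vector (intercept excluded)."""
        return wmms_score(v, self.to_weightset())

    def to_weightset(self) -> WeightSet:
        return WeightSet(
            weights=self.weights.copy(),
            intercept=self.intercept,
            provenance=self.model.provenance,
            fit_r2=self.rsquared,
        )

    def summary(self) -> str:
        lines = [
            "WMMS ordinary least squares",
            f"  provenance:     {self.model.provenance}",
            f"  n rows:         {len(self.model.endog)}",
            f"  R-squared:      {self.rsquared:.4f}",
            f"  intercept:      {self.intercept:.4f} (excluded from WMMS)",
            f"  rank deficient: {self.rank_deficient}",
        ]
        if self.pinned_zero:
            lines.append(f"  pinned to zero: {', '.join(self.pinned_zero)}")
        lines.append("  " + "-" * 38)
        lines.append(f"  {'parameter':<20}{'weight':>10}")
        for k, v in self.weights.items():
            lines.append(f"  {k:<20}{v:>10.3f}")
        return "\n".join(lines)


def train_weights(
    exog: pd.DataFrame,
    endog,
    fit_intercept: bool = True,
    provenance: str = "trained",
) -> WeightSet:
    """Functional wrapper: fit OLS weights on a prepared design matrix."""
    return WmmsModel(exog, endog, provenance=provenance).fit(fit_intercept).to_weightset()


def severity_cutpoint(scores, classes) -> float:
    """Midpoint of the attenuated and severe class mean WMMS."""
    s = pd.Series(np.asarray(scores, dtype=float))
    c = pd.Series(list(classes))
    means = s.groupby(c.values).mean()
    for needed in ("attenuated", "severe"):
        if needed not in means.index:
            raise ValidationError(f"no {needed} patients to place a cutpoint")
    return float((means["attenuated"] + means["severe"]) / 2)


def predict_cohort(
    records,
    annotations: dict,
    w: WeightSet,
    cfg: FeatureConfig | None = None,
    cutpoint: float | None = None,
) -> pd.DataFrame:
    """Score every eligible patient with a weight set.

    Returns one row per patient with the composite WMMS, the per-allele WMMS
    (each allele's vector scored alone at full weight), the observed COS,
    and — if a cutpoint is given — the predicted severity class.  Patients
    with a missense allele lacking an annotation are skipped with a reason
    recorded in the ``skipped`` attribute of the returned frame.
    """
    rows, skipped = [], []
    for r in records:
        try:
            a1 = _allele_spec(r.allele1, r.allele1_class, annotations)
            a2 = _allele_spec(r.allele2, r.allele2_class, annotations)
        except ValidationError as err:
            skipped.append((r.patient_id, str(err)))
            continue
        if r.zygosity == "homozygous":
            composite = _features.allele_vector(a1, cfg)
        else:
            composite = _features.combine_heterozygous(a1, a2, cfg)
        row = {
            "patient_id": r.patient_id,
            "cos": _cohort.compute_cos(r),
            "wmms": wmms_score(composite, w),
            "allele1_wmms": wmms_score(_features.allele_vector(a1, cfg), w),
            "allele2_wmms": wmms_score(_features.allele_vector(a2, cfg), w),
        }
        if cutpoint is not None:
            row["predicted_class"] = "severe" if row["wmms"] > cutpoint else "attenuated"
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out
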