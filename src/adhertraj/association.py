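"""Exposure-trajectory association models.

Baseline exposures (tumour, treatment, comorbidity and prior-medication
factors) are related to modal trajectory-group assignment via multinomial
logistic regression, one model per exposure with its own adjustment set,
using the high-adherence group as the outcome reference.  Missing stage /
tumour size / nodal status are multiply imputed by chained equations and
aggregated by averaging the ordinal codes across imputations and rounding
to the nearest category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

MISSABLE = {
    "stage": ["I", "II", "III"],
    "tumor_size": ["<2cm", "2-5cm", ">5cm"],
    "positive_nodes": ["none", "one", "two_plus"],
}

#: default predictors used in the imputation conditionals
IMPUTE_PREDICTORS = ["age_at_diagnosis", "chemotherapy", "grade", "her2", "cci"]


@dataclass
class ExposureModelSpec:
    """One exposure model: which covariate, its reference level, and the
    DAG-derived adjustment set."""

    exposure: str
    adjustment_set: list[str] = field(default_factory=list)
    exposure_reference: str | None = None  # None -> largest cohort level
    outcome_reference: int = 1             # trajectory group of high adherers

    def __post_init__(self):
        if self.exposure in self.adjustment_set:
            raise ValueError("exposure cannot appear in its own adjustment set")

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "adjustment_set": list(self.adjustment_set),
            "exposure_reference": self.exposure_reference,
            "outcome_reference": self.outcome_reference,
        }


def default_specs() -> list[ExposureModelSpec]:
    """One model per exposure, mirroring per-exposure DAG adjustment sets.

    The exact footnote-to-exposure mapping in the source figures is partly
    ambiguous; this default records our working assumption and is meant to
    be edited as configuration.
    """
    med_adj = ["age_group", "cci", "income", "cohabitation", "education"]
    specs = [
        ExposureModelSpec("age_group", []),
        ExposureModelSpec("stage", ["age_group"]),
        ExposureModelSpec("tumor_size", ["age_group"]),
        ExposureModelSpec("positive_nodes", ["age_group"]),
        ExposureModelSpec("grade", ["age_group"]),
        ExposureModelSpec("her2", ["age_group"]),
        ExposureModelSpec("chemotherapy", ["age_group", "cci", "stage"]),
        ExposureModelSpec("surgery_rt", ["age_group", "cci", "stage", "cohabitation"]),
        ExposureModelSpec("cci", ["age_group", "education"]),
        ExposureModelSpec("prior_med_any", med_adj, exposure_reference="no"),
    ]
    from adhertraj.simulate import MEDICATION_CLASSES

    for cls in MEDICATION_CLASSES:
        specs.append(
            ExposureModelSpec(f"prior_med_{cls}", med_adj, exposure_reference="no")
        )
    return specs


# ---------------------------------------------------------------------------
# covariate encoding
# ---------------------------------------------------------------------------

def _as_categorical(patients: pd.DataFrame, name: str) -> pd.Series:
    """Analysis-scale categorical view of a covariate column."""
    if name == "cci":
        return pd.Series(
            np.where(patients["cci"].to_numpy() >= 1, "1+", "0"),
            index=patients.index, name="cci",
        )
    if name.startswith("prior_med"):
        return pd.Series(
            np.where(patients[name].to_numpy() == 1, "yes", "no"),
            index=patients.index, name=name,
        )
    return patients[name].astype(str)


def _dummies(series: pd.Series, reference: str | None) -> tuple[pd.DataFrame, str]:
    counts = series.value_counts()
    if reference is None:
        reference = counts.idxmax()
    if reference not in counts.index:
        raise ValueError(f"reference level {reference!r} absent from {series.name!r}")
    levels = [lv for lv in counts.index if lv != reference]
    out = pd.DataFrame(
        {f"{series.name}[{lv}]": (series == lv).astype(float) for lv in levels},
        index=series.index,
    )
    return out, reference


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def _impute_design(df: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [df["age_at_diagnosis"].to_numpy(dtype=float)]
    for name in ["chemotherapy", "grade", "her2", "cci"]:
        cat = _as_categorical(df, name)
        d, _ = _dummies(cat, None)
        cols.append(d.to_numpy(dtype=float))
    for other in MISSABLE:
        if other == exclude:
            continue
        codes = pd.Categorical(df[other], categories=MISSABLE[other]).codes
        cols.append(codes.astype(float)[:, None])
    X = np.column_stack([np.asarray(c).reshape(len(df), -1) for c in cols])
    return sm.add_constant(X, has_constant="add")


def _fit_conditional(X_obs, codes_obs, n_levels):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes_obs, X_obs)
        try:
            return model.fit(disp=False, maxiter=100)
        except Exception:
            return None


def impute_missing(
    patients: pd.DataFrame, m: int = 50, seed: int = 0, n_cycles: int = 10
) -> pd.DataFrame:
    """Multiply impute stage / tumour size / nodal status, then aggregate.

    Chained equations: each missable field is imputed from a multinomial
    logit on available patient and tumour characteristics plus the current
    draws of the other missable fields; draws are refreshed over
    ``n_cycles`` Gibbs cycles per imputation.  The ``m`` completed datasets
    are aggregated by averaging each field's ordinal code across
    imputations and rounding to the nearest category.
    """
    non_designated = [
        c for c in patients.columns
        if c not in MISSABLE and patients[c].isna().any()
    ]
    if non_designated:
        raise ValueError(f"missingness outside designated fields: {non_designated}")

    miss_masks = {f: patients[f].isna().to_numpy() for f in MISSABLE}
    if not any(mask.any() for mask in miss_masks.values()):
        return patients.copy()

    rng = np.random.default_rng(seed)
    sums = {f: np.zeros(int(mask.sum())) for f, mask in miss_masks.items()}

    for _ in range(m):
        work = patients.copy()
        # initialize missing draws from the observed marginal
        for f, levels in MISSABLE.items():
            mask = miss_masks[f]
            if not mask.any():
                continue
            obs = work.loc[~mask, f]
            probs = obs.value_counts(normalize=True).reindex(levels).fillna(0.0)
            work.loc[mask, f] = rng.choice(levels, size=mask.sum(), p=probs / probs.sum())
        for cycle in range(n_cycles):
            for f, levels in MISSABLE.items():
                mask = miss_masks[f]
                if not mask.any():
                    continue
                X = _impute_design(work, exclude=f)
                codes = pd.Categorical(work[f], categories=levels).codes
                res = _fit_conditional(X[~mask], codes[~mask], len(levels))
                if res is None:
                    continue  # keep marginal draws for this cycle
                probs = res.predict(X[mask])
                probs = np.asarray(probs)
                u = rng.random(len(probs))
                draw = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                present = sorted(np.unique(codes[~mask]))
                work.loc[mask, f] = [levels[present[d]] for d in draw]
        for f, levels in MISSABLE.items():
            mask = miss_masks[f]
            if mask.any():
                sums[f] += pd.Categorical(work.loc[mask, f], categories=levels).codes

    out = patients.copy()
    for f, levels in MISSABLE.items():
        mask = miss_masks[f]
        if mask.any():
            mean_code = np.rint(sums[f] / m).astype(int)
            out.loc[mask, f] = [levels[c] for c in mean_code]
    return out


# ---------------------------------------------------------------------------
# multinomial models
# ---------------------------------------------------------------------------

def fit_multinomial(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ExposureModelSpec,
) -> pd.DataFrame:
    """Fit one exposure's multinomial logit and tabulate ORs with 95% CIs.

    Returns an OR table with one row per (exposure level, outcome group)
    including OR = 1 reference rows; metadata in ``df.attrs``.
    """
    df = patients.merge(assignments[["patient_id", "assigned_group"]], on="patient_id")
    if len(df) < len(assignments):
        raise ValueError("assignments cover patients missing from the covariate table")

    exp_cat = _as_categorical(df, spec.exposure)
    exp_dum, exp_ref = _dummies(exp_cat, spec.exposure_reference)

    # drop exposure levels with an empty cell against any outcome group
    tab = pd.crosstab(exp_cat, df["assigned_group"])
    bad = tab.index[(tab == 0).any(axis=1)].tolist()
    dropped = [lv for lv in bad if lv != exp_ref]
    if dropped:
        warnings.warn(f"dropping exposure level(s) with empty cells: {dropped}")
        keep = ~exp_cat.isin(dropped)
        df, exp_cat = df[keep], exp_cat[keep]
        exp_dum = exp_dum.loc[keep, [c for c in exp_dum if not any(f'[{lv}]' in c for lv in dropped)]]

    X_parts = [exp_dum]
    for adj in spec.adjustment_set:
        d, _ = _dummies(_as_categorical(df, adj), None)
        X_parts.append(d)
    X = sm.add_constant(pd.concat(X_parts, axis=1).to_numpy(dtype=float), has_constant="add")

    groups = np.sort(df["assigned_group"].unique())
    if spec.outcome_reference not in groups:
        raise ValueError("outcome reference group absent from assignments")
    if len(groups) < 2:
        warnings.warn("only one outcome group present; nothing to contrast")
        table = pd.DataFrame(
            columns=["exposure", "level", "outcome_group", "OR", "ci_low", "ci_high", "n_level"]
        )
        table.attrs.update({"spec": spec.to_dict(), "n": len(df), "converged": True,
                            "exposure_reference": exp_ref})
        return table
    nonref = [g for g in groups if g != spec.outcome_reference]
    code_map = {spec.outcome_reference: 0, **{g: i + 1 for i, g in enumerate(nonref)}}
    endog = df["assigned_group"].map(code_map).to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(endog, X).fit(disp=False, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", True))

    params = np.asarray(res.params)   # (n_coef, n_outcomes-1)
    bses = np.asarray(res.bse)
    z = norm.ppf(0.975)
    rows = []
    level_counts = exp_cat.value_counts()
    for g in groups:
        if g == spec.outcome_reference:
            continue
        col = code_map[g] - 1
        rows.append((spec.exposure, exp_ref, int(g), 1.0, np.nan, np.nan,
                     int(level_counts.get(exp_ref, 0))))
        for k, name in enumerate(exp_dum.columns):
            lv = name[name.index("[") + 1 : -1]
            coef, se = params[k + 1, col], bses[k + 1, col]
            rows.append((spec.exposure, lv, int(g), float(np.exp(coef)),
                         float(np.exp(coef - z * se)), float(np.exp(coef + z * se)),
                         int(level_counts.get(lv, 0))))
    table = pd.DataFrame(
        rows, columns=["exposure", "level", "outcome_group", "OR", "ci_low", "ci_high", "n_level"]
    )
    table.attrs["spec"] = spec.to_dict()
    table.attrs["n"] = len(df)
    table.attrs["converged"] = converged
    table.attrs["exposure_reference"] = exp_ref
    if not converged:
        warnings.warn(f"multinomial fit for {spec.exposure} did not converge")
    return table


def run_association_suite(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    specs: list[ExposureModelSpec] | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit one multinomial model per exposure spec; keyed by exposure name."""
    if specs is None:
        specs = default_specs()
    if not specs:
        raise ValueError("specs must be non-empty")
    out = {}
    for spec in specs:
        out[spec.exposure] = fit_multinomial(assignments, patients, spec)
    return out


def combined_or_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-exposure OR tables into one long frame (forest-plot data)."""
    return pd.concat(tables.values(), ignore_index=True)
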