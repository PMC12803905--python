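"""Random-intercept multilevel models of windowed reaction time.

Trials are aggregated into 15 windows of 2 blocks (6 test trials) per
subject.  Per window the pipeline computes the mean correct-trial RT, the
occurrence rates of late EI and late IE transitions (fraction of the
window's trials whose EI / IE transition fell in the second half of the
trial), the mean accuracy, and the mean RRI velocity.  All variables are
z-scored over every subject-window (grand normalisation); predictors are
then centred on each subject's own mean, so the fixed slopes are purely
within-subject, while RT keeps its between-subject variation for the random
intercept to absorb.

Two models share the machinery and differ only in the respiratory
predictor:

* Model 1:  RT ~ EIt-2nd rate + RRI velocity + accuracy, random intercept
  per subject;
* Model 2:  RT ~ IEt-2nd rate + RRI velocity + accuracy, random intercept
  per subject.

Estimation is REML via ``statsmodels`` MixedLM; slopes are fixed across
subjects by design.  Fixed-effect p-values use the large-sample normal
approximation (the df method is recorded in the fit diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

N_WINDOW_BLOCKS = 2

MODEL_PREDICTORS = {
    1: ("eit2nd_rate", "delta_rri", "accuracy"),
    2: ("iet2nd_rate", "delta_rri", "accuracy"),
}


@dataclass
class ModelFit:
    """Fixed effects, variance components and diagnostics of one model."""

    model_id: int
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    intercept: float
    intercept_se: float
    random_intercept_var: float
    residual_var: float
    converged: bool
    df_method: str
    n_obs: int
    n_subjects: int
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "coefficients": self.coef,
            "standard_errors": self.se,
            "p_values": self.p,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "random_intercept_variance": self.random_intercept_var,
            "residual_variance": self.residual_var,
            "converged": self.converged,
            "df_method": self.df_method,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "notes": self.notes,
        }


def aggregate_windows(trials: pd.DataFrame, correct_only_rt: bool = True) -> pd.DataFrame:
    """Collapse trials into per-subject windows of 2 consecutive blocks.

    Windows are blocks (1,2), (3,4), ... — 15 windows for the standard 30
    blocks.  Mean RT uses correct trials (the correct-trial RT focus;
    ``correct_only_rt=False`` switches to all trials); accuracy and the
    late-transition rates use all trials in the window; mean RRI velocity
    uses trials with a valid value.  Windows with no correct trial get a
    missing mean RT.
    """
    df = trials.copy()
    df["window"] = (df["block"].astype(int) - 1) // N_WINDOW_BLOCKS + 1
    rows = []
    for (subject, window), g in df.groupby(["subject", "window"], sort=True):
        rt_pool = g.loc[g["correct"], "rt_s"] if correct_only_rt else g["rt_s"]
        rows.append(
            dict(
                subject=subject,
                window=int(window),
                mean_rt=float(rt_pool.mean()) if len(rt_pool) else np.nan,
                eit2nd_rate=float((g["eit_half"] == "2nd").mean()),
                iet2nd_rate=float((g["iet_half"] == "2nd").mean()),
                accuracy=float(g["correct"].mean()),
                delta_rri=float(g["delta_rri"].mean()),
                n_trials=int(len(g)),
                n_correct=int(g["correct"].sum()),
            )
        )
    return pd.DataFrame(rows)


VARIABLES = ("mean_rt", "eit2nd_rate", "iet2nd_rate", "accuracy", "delta_rri")


def normalize_and_center(
    aggregates: pd.DataFrame, center_rt: bool = False
) -> pd.DataFrame:
    """Grand-normalise all variables, then within-subject centre the predictors.

    Every variable is z-scored over all subject-windows.  Predictors are
    additionally centred on each subject's own mean (per-subject mean 0), so
    slopes reflect within-subject covariation.  RT is grand-normalised but
    by default not subject-centred — the random intercept absorbs subject
    means; ``center_rt=True`` reproduces the fully-centred variant.

    Raises ``ValueError`` naming any zero-variance variable.
    """
    if aggregates["subject"].nunique() < 2:
        raise ValueError("need at least two subjects")
    df = aggregates.copy()
    for var in VARIABLES:
        x = df[var].astype(float)
        sd = x.std(ddof=0)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
            raise ValueError(f"zero-variance variable: {var}")
        df[var + "_norm"] = (x - x.mean()) / sd
    for var in VARIABLES:
        if var == "mean_rt" and not center_rt:
            df[var + "_c"] = df[var + "_norm"]
            continue
        df[var + "_c"] = df[var + "_norm"] - df.groupby("subject")[var + "_norm"].transform("mean")
    return df


def fit_random_intercept(prepared: pd.DataFrame, model_id: int) -> ModelFit:
    """REML fit of the random-intercept model on a prepared window table.

    ``prepared`` must carry the ``*_c`` columns from
    :func:`normalize_and_center` (or equivalently scaled data).  Rows with a
    missing response or predictor are dropped (windows without correct
    trials).
    """
    if model_id not in MODEL_PREDICTORS:
        raise ValueError("model_id must be 1 or 2")
    preds = MODEL_PREDICTORS[model_id]
    cols = ["mean_rt_c"] + [p + "_c" for p in preds]
    df = prepared.dropna(subset=cols)
    y = df["mean_rt_c"].to_numpy()
    X = sm.add_constant(df[[p + "_c" for p in preds]].to_numpy())
    groups = df["subject"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups)
    fit = None
    last_err: Exception | None = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            with np.errstate(all="ignore"):
                fit = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError as err:  # singular step along the path
            last_err = err
    if fit is None:
        raise RuntimeError(f"mixed-model fit failed to converge: {last_err}")
    names = ["intercept"] + list(preds)
    fe = dict(zip(names, fit.fe_params))
    se = dict(zip(names, fit.bse_fe))
    pv = dict(zip(names, fit.pvalues[: len(names)]))
    # cov_re is already on the response scale in statsmodels
    cov_re = np.asarray(fit.cov_re)
    re_var = float(cov_re[0, 0]) if cov_re.size else 0.0
    notes = ""
    if re_var < 1e-8:
        notes = "singular random-intercept variance (kept)"
    return ModelFit(
        model_id=model_id,
        coef={k: float(fe[k]) for k in preds},
        se={k: float(se[k]) for k in preds},
        p={k: float(pv[k]) for k in preds},
        intercept=float(fe["intercept"]),
        intercept_se=float(se["intercept"]),
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        converged=bool(fit.converged),
        df_method="normal-approximation",
        n_obs=int(len(df)),
        n_subjects=int(df["subject"].nunique()),
        notes=notes,
    )


def fit_models(prepared: pd.DataFrame) -> dict[int, ModelFit]:
    """Fit Model 1 and Model 2 on the same prepared table."""
    return {m: fit_random_intercept(prepared, m) for m in (1, 2)}


# ---------------------------------------------------------------------------
# aggregate-level simulation (parameter recovery / calibration)


def simulate_aggregate_cohort(
    rng: np.random.Generator,
    coefs: tuple[float, float, float] = (0.21, 0.145, -0.118),
    n_subjects: int = 36,
    n_windows: int = 15,
    intercept_sd: float = 0.5,
    resid_sd: float = 0.78,
    model_id: int = 1,
) -> pd.DataFrame:
    """Simulate a window-level cohort directly on the normalised scale.

    Predictors are standard normal (already grand-normalised and
    subject-centred in expectation); the response is
    ``u_j + X @ coefs + e`` with Gaussian random intercepts and residuals.
    Used for parameter-recovery and type-I-error studies of
    :func:`fit_random_intercept` without re-running the signal pipeline.
    """
    preds = MODEL_PREDICTORS[model_id]
    n = n_subjects * n_windows
    subject = np.repeat(np.arange(1, n_subjects + 1), n_windows)
    X = rng.normal(size=(n, 3))
    u = rng.normal(0.0, intercept_sd, size=n_subjects)
    y = u[subject - 1] + X @ np.asarray(coefs) + rng.normal(0.0, resid_sd, size=n)
    df = pd.DataFrame(
        {
            "subject": subject,
            "window": np.tile(np.arange(1, n_windows + 1), n_subjects),
            "mean_rt_c": y,
        }
    )
    for j, p in enumerate(preds):
        df[p + "_c"] = X[:, j]
    return df


def tables_markdown(fits: dict[int, ModelFit]) -> str:
    """Human-readable coefficient tables for both models."""
    label = {
        "eit2nd_rate": "EIt-2nd rate",
        "iet2nd_rate": "IEt-2nd rate",
        "delta_rri": "RRI velocity",
        "accuracy": "Accuracy",
    }
    lines = []
    for mid in sorted(fits):
        f = fits[mid]
        lines.append(f"## Model {mid} (random intercept, REML; n={f.n_obs} windows, "
                     f"{f.n_subjects} subjects)")
        lines.append("")
        lines.append("| predictor | coefficient (SE) | p-value |")
        lines.append("|---|---|---|")
        for k in f.coef:
            lines.append(
                f"| {label.get(k, k)} | {f.coef[k]:.3f} ({f.se[k]:.4f}) | {f.p[k]:.3g} |"
            )
        lines.append("")
        lines.append(
            f"random-intercept variance {f.random_intercept_var:.4f}, "
            f"residual variance {f.residual_var:.4f}, "
            f"converged={f.converged}, df method {f.df_method}"
        )
        lines.append("")
    return "\n".join(lines)
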