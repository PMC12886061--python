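"""Mixed-effects tests of the registration-method effect on variability.

The benchmark's statistical design: for each organ and metric, a linear
mixed-effects model with registration method (DIR vs RIR) as the fixed
effect and crossed random intercepts for patient and centre, fitted by
restricted maximum likelihood; the method effect is tested two-sided at
the 5% level with a Wald test (standard reporting for a single fixed
effect — recorded in output metadata).  No multiple-testing correction is
applied across organs or metrics.

Because a model on raw constraint values would test dose *level* rather
than *variation*, dose variability enters through explicit dispersion
responses: (a) each centre's absolute deviation of D_0.3cm^3 from the
patient-wise median (per method), the default; (b) the per-patient DVH
band IQR area, one value per patient and method, tested with a patient
random intercept only.  Both are emitted for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_model import DIR, RIR

ALPHA = 0.05


@dataclass
class ModelResult:
    """One fitted mixed model for one response."""

    response: str
    estimate: float       # DIR minus RIR fixed effect
    std_error: float
    p_value: float        # two-sided Wald
    var_patient: float
    var_centre: float | None
    var_residual: float
    converged: bool
    singular: bool
    n_obs: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= ALPHA)


def _as_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    required = {"case_id", "centre_id", "method", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records lack required columns: {sorted(missing)}")
    return df


def fit_method_effect(records, response: str = "value",
                      include_centre: bool = True) -> ModelResult:
    """Fit the method effect with random intercepts for patient (and centre).

    ``records`` is long-format with columns case_id, centre_id, method and
    ``value``; the fixed effect is an indicator coded 1 for DIR and 0 for
    RIR.  With ``include_centre=False`` only the patient intercept is used
    (appropriate when the response is already one value per patient and
    method, e.g. a DVH band area).
    """
    df = _as_frame(records).dropna(subset=["value"])
    for col in ("case_id", "centre_id", "method"):
        if df[col].nunique() < 2 and not (col == "centre_id" and not include_centre):
            raise ValueError(f"need >= 2 levels of {col} to fit the model")
    df = df.reset_index(drop=True)
    df["is_dir"] = (df["method"] == DIR).astype(float)
    vc = {"patient": "0 + C(case_id)"}
    if include_centre:
        vc["centre"] = "0 + C(centre_id)"
    # crossed random intercepts: a single all-encompassing group with one
    # variance component per factor
    groups = np.ones(len(df))
    data = df.rename(columns={"value": "_y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("_y ~ is_dir", data=data,
                                        groups=groups, re_formula="0",
                                        vc_formula=vc)
        result = model.fit(reml=True, method=["lbfgs", "bfgs"])
    converged = bool(getattr(result, "converged", True))
    vcomp = dict(zip(model.exog_vc.names, np.asarray(result.vcomp, dtype=float)))
    var_resid = float(result.scale)
    singular = any(v < 1e-8 * max(var_resid, 1e-12) for v in vcomp.values())
    return ModelResult(
        response=response,
        estimate=float(result.params["is_dir"]),
        std_error=float(result.bse["is_dir"]),
        p_value=float(result.pvalues["is_dir"]),
        var_patient=float(vcomp.get("patient", np.nan)),
        var_centre=float(vcomp["centre"]) if "centre" in vcomp else None,
        var_residual=var_resid,
        converged=converged,
        singular=singular,
        n_obs=int(len(df)),
    )


# ---------------------------------------------------------------------------
# dispersion responses
# ---------------------------------------------------------------------------


def dispersion_response(records, statistic: str = "constraint_absdev") -> pd.DataFrame:
    """Build the variability response the mixed model is fitted on.

    ``constraint_absdev``: per-centre absolute deviation of the constraint
    dose from the patient-wise median within each method (one row per
    centre).  ``band_iqr_area``: passthrough for responses that are already
    one value per patient and method.
    """
    df = _as_frame(records)
    if statistic == "constraint_absdev":
        med = df.groupby(["case_id", "method"])["value"].transform("median")
        out = df.copy()
        out["value"] = (df["value"] - med).abs()
        return out
    if statistic == "band_iqr_area":
        return df.copy()
    raise ValueError(f"unknown dispersion statistic {statistic!r}")


def paired_plot_table(records, value_col: str = "value") -> pd.DataFrame:
    """Wide per-patient table of paired RIR/DIR values and their difference.

    Patients missing one method get a flagged row with NaN difference.
    """
    df = _as_frame(records.rename(columns={value_col: "value"})
                   if value_col != "value" else records)
    agg = df.groupby(["case_id", "method"])["value"].mean().unstack("method")
    for m in (RIR, DIR):
        if m not in agg.columns:
            agg[m] = np.nan
    out = agg[[RIR, DIR]].reset_index()
    out.columns = ["case_id", "RIR", "DIR"]
    out["difference"] = out["DIR"] - out["RIR"]
    out["complete_pair"] = out[["RIR", "DIR"]].notna().all(axis=1)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo generator for calibration studies
# ---------------------------------------------------------------------------


def simulate_method_effect_records(n_patients: int = 7, n_centres: int = 6,
                                   delta: float = 0.0, sd_patient: float = 1.0,
                                   sd_centre: float = 0.5, sd_residual: float = 1.0,
                                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gaussian records with known variance components and method effect.

    One observation per (patient, centre, method):
    ``y = delta * 1[DIR] + u_patient + v_centre + e``.  Used to calibrate
    the mixed model's estimator bias and type-I error.
    """
    rng = rng or np.random.default_rng()
    u = rng.normal(0.0, sd_patient, size=n_patients)
    v = rng.normal(0.0, sd_centre, size=n_centres)
    rows = []
    for p in range(n_patients):
        for c in range(n_centres):
            for method in (RIR, DIR):
                y = (delta * (method == DIR) + u[p] + v[c]
                     + rng.normal(0.0, sd_residual))
                rows.append({"case_id": f"case_{p + 1}", "centre_id": f"centre_{c + 1:02d}",
                             "method": method, "value": y})
    return pd.DataFrame(rows)


def models_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
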