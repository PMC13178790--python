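"""Linear mixed model for eGFR over time.

The population trajectory is quadratic in time,

    eGFR_ij = (β0 + b0_i) + (β1 + b1_i) t_ij + β2 t_ij² + ε_ij,

with subject-specific random intercepts and linear time trends
(b0_i, b1_i) ~ N(0, G) (unstructured 2×2 G), ε_ij ~ N(0, σ²), fitted by
REML by default. Time is years since each subject's first eGFR record.
The quadratic term is a fixed effect only, and the model is deliberately
unadjusted: between-group differences in progression are read off the
subject-level predicted trajectories downstream, not modelled as covariates
here. Per-subject coefficients combine the fixed effects with the empirical
best linear unbiased predictions (BLUPs) of the random effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed; carries the optimizer message."""


@dataclass
class TrajectoryFit:
    beta0: float  # fixed intercept, mL/min/1.73 m²
    beta1: float  # fixed linear slope, per year
    beta2: float  # fixed quadratic term, per year²
    random_effects: Mapping[str, tuple[float, float]]  # subject -> (b0_i, b1_i)
    G: np.ndarray  # 2x2 random-effect covariance
    sigma2: float  # residual variance
    scheme: str = ""
    converged: bool = True
    singular: bool = False
    convergence_info: dict = field(default_factory=dict)

    def subject_coeffs(self, subject_id: str) -> tuple[float, float, float]:
        """(a, b, c) of the subject's predicted curve a + b t + c t²."""
        b0, b1 = self.random_effects[subject_id]
        return (self.beta0 + b0, self.beta1 + b1, self.beta2)

    def to_dict(self) -> dict:
        return {
            "beta": [self.beta0, self.beta1, self.beta2],
            "G": np.asarray(self.G).tolist(),
            "sigma2": self.sigma2,
            "scheme": self.scheme,
            "converged": self.converged,
            "singular": self.singular,
            "n_subjects": len(self.random_effects),
        }


def fit_trajectory_lmm(
    long_table: pd.DataFrame,
    scheme: str = "",
    reml: bool = True,
) -> TrajectoryFit:
    """Fit the random-intercept/random-slope quadratic eGFR model.

    ``long_table`` needs columns ``subject_id``, ``time`` (years) and
    ``egfr``. At least two subjects are required — random effects are
    unidentifiable from a single cluster. Non-convergence raises
    :class:`ConvergenceError`; a singular random-effect covariance is
    returned with ``singular=True`` and a warning rather than discarded.
    """
    df = long_table[["subject_id", "time", "egfr"]].dropna().copy()
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError(
            f"random effects need >= 2 subjects, got {n_subjects}"
        )
    df = df.sort_values(["subject_id", "time"], kind="mergesort")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            "egfr ~ time + I(time**2)", df, groups=df["subject_id"],
            re_formula="~time",
        )
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise ConvergenceError(str(exc)) from exc
    singular = any("singular" in str(w.message).lower() for w in caught)
    if not res.converged:
        raise ConvergenceError(
            f"mixed model did not converge: {res.mle_retvals if hasattr(res, 'mle_retvals') else 'no trace'}"
        )

    fe = res.fe_params
    G = np.asarray(res.cov_re)
    if singular:
        warnings.warn("random-effect covariance is singular; fit returned with flag")
    re = {
        sid: (float(vals.iloc[0]), float(vals.iloc[1]))
        for sid, vals in res.random_effects.items()
    }
    return TrajectoryFit(
        beta0=float(fe.iloc[0]),
        beta1=float(fe.iloc[1]),
        beta2=float(fe.iloc[2]),
        random_effects=re,
        G=G,
        sigma2=float(res.scale),
        scheme=scheme,
        converged=bool(res.converged),
        singular=singular,
        convergence_info={"method": "lbfgs+powell", "reml": reml},
    )


def predict_subject_egfr(fit: TrajectoryFit, subject_id: str, t: float) -> float:
    """Predicted eGFR for one subject at time ``t`` (years from their origin)."""
    if subject_id not in fit.random_effects:
        raise KeyError(f"subject {subject_id!r} not in fit")
    a, b, c = fit.subject_coeffs(subject_id)
    return a + b * t + c * t * t
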