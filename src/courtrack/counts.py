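"""Negative-binomial count models for behavior tables.

:class:`BehaviorCountModel` fits the standard behavioral-count
regression — a negative-binomial (NB2, log link) model of a count
response on female receptivity status, male social treatment, their
interaction, and the body-size-difference and glide-frequency
covariates — and returns a :class:`CountModelResults` carrying
coefficients, incidence-rate ratios (IRRs), Wald statistics and 95%
intervals.  An optional intercept-only zero-inflation term is available
for responses with excess zeros (chasing time).

This is the within-package fitting surface used for calibration and
power checks of the synthetic count generator; estimation is delegated
to statsmodels.  Random intercepts (batch, rearing tank) are part of
the data-generating process but are not estimated here — the fixed
marginal model is what the calibration checks exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.discrete_model import NegativeBinomial

from .errors import ParameterError

TERMS = {
    "intercept": "Intercept",
    "treatment": "treatment_mixed_sex",
    "status": "status_receptive",
    "interaction": "treatment_x_status",
    "body_size": "body_size_diff_cm",
    "glides": "glide_count",
}


def _design_matrix(data: pd.DataFrame, covariates: bool) -> pd.DataFrame:
    """Treatment-coded design with male_only / non_receptive reference."""
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    X["treatment_mixed_sex"] = (data["treatment"] == "mixed_sex").astype(float)
    X["status_receptive"] = (data["female_status"] == "receptive").astype(float)
    X["treatment_x_status"] = X["treatment_mixed_sex"] * X["status_receptive"]
    if covariates:
        X["body_size_diff_cm"] = data["body_size_diff_cm"].astype(float)
        X["glide_count"] = data["glide_count"].astype(float)
    return X


class BehaviorCountModel:
    """NB2 count regression of one behavior response.

    Parameters
    ----------
    data
        BehaviorRecord table (one row per assay) with at least
        ``treatment``, ``female_status`` and the response column, plus
        ``body_size_diff_cm`` and ``glide_count`` unless
        ``covariates=False``.
    response
        Column to model (e.g. ``"sneaks"``, ``"displays"``,
        ``"total_behavior"``, ``"chase_frames"``).
    zero_inflated
        Add an intercept-only zero-inflation component.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        covariates: bool = True,
        zero_inflated: bool = False,
    ):
        if response not in data.columns:
            raise ParameterError(f"response column {response!r} not in data")
        y = data[response].to_numpy()
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ParameterError(f"{response!r} must hold non-negative counts")
        self.data = data
        self.response = response
        self.zero_inflated = zero_inflated
        self.endog = np.round(y).astype(int)
        self.exog = _design_matrix(data, covariates)

    @classmethod
    def from_records(cls, records, response: str, **kwargs) -> "BehaviorCountModel":
        import dataclasses

        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        return cls(pd.DataFrame(rows), response, **kwargs)

    def fit(self, maxiter: int = 500) -> "CountModelResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.zero_inflated:
                model = ZeroInflatedNegativeBinomialP(
                    self.endog, self.exog, exog_infl=np.ones((len(self.endog), 1)), p=2
                )
                res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
            else:
                model = NegativeBinomial(self.endog, self.exog, loglike_method="nb2")
                res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
                if not res.mle_retvals.get("converged", False):
                    res = model.fit(method="nm", maxiter=5 * maxiter, disp=0)
        return CountModelResults(self, res)


@dataclass(frozen=True)
class CoefRow:
    term: str
    coef: float
    se: float
    irr: float
    irr_low: float
    irr_high: float
    z: float
    p: float


class CountModelResults:
    """Fitted count model: link-scale coefficients, IRRs with 95%
    Wald intervals, z statistics and p-values.

    ``irr`` is always ``exp(coef)``; intervals exponentiate the
    link-scale Wald interval.  Wald tests and intervals use a
    t(n - p) reference (p = mean-model parameters) rather than the
    normal — the usual finite-sample correction; with ~100 assays the
    plain z reference is noticeably anticonservative.  ``converged``
    flags optimizer success — a non-converged fit is returned flagged,
    never silently refit with a different structure.
    """

    def __init__(self, model: BehaviorCountModel, sm_results):
        self.model = model
        self._res = sm_results
        self.converged = bool(sm_results.mle_retvals.get("converged", True))
        self.df_resid = int(len(model.endog) - model.exog.shape[1])

    def _pnames(self) -> list[str]:
        if hasattr(self._res.params, "index"):
            return [str(n) for n in self._res.params.index]
        return [str(n) for n in self._res.model.exog_names]

    def _row(self, name: str) -> CoefRow:
        # in ZI fits the count-component parameters appear as the bare
        # design names; the inflation intercept is 'inflate_const'
        pnames = self._pnames()
        try:
            i = pnames.index(name)
        except ValueError:
            raise ParameterError(f"no parameter {name!r}; have {pnames}")
        coef = float(np.asarray(self._res.params)[i])
        se = float(np.asarray(self._res.bse)[i])
        z = coef / se if se > 0 else np.nan
        from scipy import stats as _st

        p = 2 * _st.t.sf(abs(z), self.df_resid) if np.isfinite(z) else np.nan
        crit = _st.t.ppf(0.975, self.df_resid)
        lo, hi = coef - crit * se, coef + crit * se
        return CoefRow(
            term=name,
            coef=coef,
            se=se,
            irr=float(np.exp(coef)),
            irr_low=float(np.exp(lo)),
            irr_high=float(np.exp(hi)),
            z=float(z),
            p=float(p),
        )

    def coef(self, term: str) -> CoefRow:
        """Coefficient row by friendly name (``treatment``, ``status``,
        ``interaction``, ``body_size``, ``glides``, ``intercept``) or by
        raw design-column name."""
        return self._row(TERMS.get(term, term))

    @property
    def alpha(self) -> float:
        """Estimated NB2 dispersion parameter alpha (variance =
        mu + alpha * mu^2)."""
        pnames = self._pnames()
        if "alpha" in pnames:
            return float(np.asarray(self._res.params)[pnames.index("alpha")])
        return float(np.asarray(self._res.params)[-1])

    def wald_test(self, term: str) -> tuple[float, float]:
        """Wald z test of one coefficient against zero: (z, p)."""
        row = self.coef(term)
        return row.z, row.p

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pnames = self._pnames()
        for friendly, name in TERMS.items():
            if name not in pnames:
                continue
            r = self._row(name)
            rows.append({
                "term": friendly, "coef": r.coef, "se": r.se, "irr": r.irr,
                "irr_low": r.irr_low, "irr_high": r.irr_high, "z": r.z, "p": r.p,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            f"Negative-binomial count model: {self.model.response}"
            + (" (zero-inflated)" if self.model.zero_inflated else "")
            + f"\n  n = {len(self.model.endog)}, converged = {self.converged}\n"
        )
        df = self.to_frame()
        body = df.to_string(
            index=False,
            formatters={c: (lambda v: f"{v:8.3f}") for c in df.columns if c != "term"},
        )
        return head + body

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CountModelResults {self.model.response!r} converged={self.converged}>"


def fit_latency_cox(
    data: pd.DataFrame, covariates: bool = True, interaction: bool = True
):
    """Cox proportional-hazards fit of latency to first sexual behavior
    (Efron ties), with treatment, status and optionally their
    interaction and the two covariates; censoring from the ``censored``
    flag.

    Uses lifelines; returns the fitted ``CoxPHFitter``.  This is a
    fixed-effects analogue of the mixed-effects survival analysis (no
    frailty terms).
    """
    from lifelines import CoxPHFitter

    X = _design_matrix(data, covariates=covariates).drop(columns=["Intercept"])
    X = X.copy()
    if not interaction:
        X = X.drop(columns=["treatment_x_status"])
    X["latency_s"] = data["latency_s"].astype(float)
    X["observed"] = (~data["censored"].astype(bool)).astype(int)
    cph = CoxPHFitter()
    cph.fit(X, duration_col="latency_s", event_col="observed")
    return cph
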