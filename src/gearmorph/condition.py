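"""Body-condition and caudal-fin metrics with AIC model selection.

The scaled mass index (SMI) standardizes each fish's mass to the cohort
mean standard length L0 along the allometric mass-length axis:

    SMI_i = M_i * (L0 / L_i) ** b_SMA

where b_SMA is the standardized-major-axis slope of ln(mass) on
ln(length).  Caudal aspect ratio is fin height squared over fin area, a
correlate of sustained swimming capacity.  Both (and raw caudal area)
are modelled with ordinary least squares over vulnerability, sex, gear
and stated interactions; the reported model minimizes AIC over the
marginality-respecting sub-models of the full model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .tps_io import CovariateTable

__all__ = [
    "SMIResult",
    "ModelSelectionResult",
    "sma_slope",
    "scaled_mass_index",
    "caudal_aspect_ratio",
    "fit_condition_models",
    "DEFAULT_TERMS",
]

#: Full-model terms per response, as used in the condition analyses.
DEFAULT_TERMS: dict[str, list[str]] = {
    "smi": ["vulnerability", "sex", "gear", "vulnerability:sex", "vulnerability:gear"],
    "caudal_area": [
        "standard_length",
        "vulnerability",
        "sex",
        "gear",
        "vulnerability:sex",
        "vulnerability:gear",
    ],
    "caudal_aspect_ratio": [
        "standard_length",
        "vulnerability",
        "sex",
        "gear",
        "vulnerability:sex",
        "vulnerability:gear",
    ],
}


@dataclass
class SMIResult:
    """SMA slope, reference length and per-fish scaled mass index (g)."""

    b_sma: float
    l0: float
    smi: pd.Series  # indexed by fish id


@dataclass
class ModelSelectionResult:
    """AIC table over the candidate set plus the selected model's fit."""

    response: str
    candidates: pd.DataFrame  # columns: formula, n_terms, aic
    selected_formula: str
    coefficients: pd.DataFrame  # estimate, se, t, p per term
    df_resid: int
    aic: float


def sma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized major axis slope: sign(corr(x, y)) * sd(y) / sd(x)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d vectors")
    if len(x) < 3:
        raise ValueError("SMA regression needs at least 3 points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: SMA slope undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    return float(sign * sy / sx)


def scaled_mass_index(covariates: CovariateTable | pd.DataFrame) -> SMIResult:
    """Scaled mass index per fish from mass (g) and standard length (mm).

    All fish of the table enter the SMA fit on natural-log scales; L0 is
    the arithmetic mean standard length.
    """
    df = covariates.frame if isinstance(covariates, CovariateTable) else covariates
    mass = df["mass"].to_numpy(float)
    length = df["standard_length"].to_numpy(float)
    if (mass <= 0).any() or (length <= 0).any():
        raise ValueError("mass and standard_length must be positive")
    if np.ptp(length) == 0:
        # every (L0/Li) ratio is 1, so SMI = observed mass whatever the slope
        b = 0.0
    else:
        b = sma_slope(np.log(length), np.log(mass))
    l0 = float(length.mean())
    smi = mass * (l0 / length) ** b
    return SMIResult(b_sma=b, l0=l0, smi=pd.Series(smi, index=df["id"].astype(str), name="smi"))


def caudal_aspect_ratio(height: float | np.ndarray, area: float | np.ndarray) -> float | np.ndarray:
    """Caudal fin aspect ratio: height^2 / area (both in mm units)."""
    height = np.asarray(height, float)
    area = np.asarray(area, float)
    if np.any(height <= 0) or np.any(area <= 0):
        raise ValueError("caudal height and area must be positive")
    out = height**2 / area
    return float(out) if out.ndim == 0 else out


def _marginal_submodels(terms: list[str]) -> list[tuple[str, ...]]:
    """All sub-sets of ``terms`` whose interactions keep their main effects,
    from the null model up to the full model."""
    main = [t for t in terms if ":" not in t]
    inter = [t for t in terms if ":" in t]
    models = []
    for mains in itertools.chain.from_iterable(
        itertools.combinations(main, r) for r in range(len(main) + 1)
    ):
        allowed = [
            t for t in inter if all(part in mains for part in t.split(":"))
        ]
        for inters in itertools.chain.from_iterable(
            itertools.combinations(allowed, r) for r in range(len(allowed) + 1)
        ):
            models.append(tuple(mains) + tuple(inters))
    return models


def fit_condition_models(
    data: pd.DataFrame,
    response: str,
    terms: list[str] | None = None,
    aicc: bool = False,
) -> ModelSelectionResult:
    """OLS model selection by AIC for a condition/fin response.

    ``data`` holds the response column plus all term covariates (one row
    per fish, complete cases only).  The candidate set enumerates every
    marginality-respecting sub-model of the full model, always including
    the null (intercept-only) and full models; AIC ties below 1e-6 break
    toward fewer terms.
    """
    if terms is None:
        try:
            terms = DEFAULT_TERMS[response]
        except KeyError:
            raise ValueError(
                f"no default terms for response {response!r}; pass terms explicitly"
            ) from None
    cols = {response} | {p for t in terms for p in t.split(":")}
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    df = data.dropna(subset=sorted(cols)).copy()
    if len(df) < len(terms) + 2:
        raise ValueError(f"too few complete cases ({len(df)}) for {len(terms)} terms")

    rows = []
    fits = {}
    for model_terms in _marginal_submodels(terms):
        formula = f"{response} ~ " + (" + ".join(model_terms) if model_terms else "1")
        fit = smf.ols(formula, data=df).fit()
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError(f"rank-deficient design for model: {formula}")
        aic = fit.aic
        if aicc:
            k = fit.df_model + 2  # coefficients + error variance
            n = len(df)
            if n - k - 1 > 0:
                aic = aic + 2 * k * (k + 1) / (n - k - 1)
        rows.append({"formula": formula, "n_terms": len(model_terms), "aic": float(aic)})
        fits[formula] = fit
    candidates = pd.DataFrame(rows)
    # minimal AIC; ties (< 1e-6) toward fewer terms
    best_aic = candidates["aic"].min()
    tied = candidates[candidates["aic"] <= best_aic + 1e-6]
    best = tied.sort_values(["n_terms", "formula"]).iloc[0]
    fit = fits[best["formula"]]
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelSelectionResult(
        response=response,
        candidates=candidates.sort_values("aic").reset_index(drop=True),
        selected_formula=str(best["formula"]),
        coefficients=coef,
        df_resid=int(fit.df_resid),
        aic=float(best["aic"]),
    )
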