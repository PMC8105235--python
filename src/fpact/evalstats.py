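"""Agreement statistics for paired measurement comparisons.

Implements the usual battery for method-comparison studies: ordinary
least squares of test on reference, Pearson r, Lin's concordance
correlation coefficient (CCC), RMSE about the identity line (accuracy),
RMSD about the regression fit (precision), and Bland-Altman bias with
95% limits of agreement.

CCC uses population (1/n) moments per Lin's original definition:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numpy.typing import NDArray
from scipy import stats


@dataclass
class AgreementReport:
    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    pearson_r: float
    r_ci: Tuple[float, float]
    ccc: float
    ccc_ci: Tuple[float, float]
    rmse: float
    rmsd: float
    bias: float
    loa: Tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci),
            "intercept_ci95": list(self.intercept_ci),
            "pearson_r": self.pearson_r,
            "r_ci95": list(self.r_ci),
            "ccc": self.ccc,
            "ccc_ci95": list(self.ccc_ci),
            "rmse": self.rmse,
            "rmsd": self.rmsd,
            "bland_altman_bias": self.bias,
            "bland_altman_loa": list(self.loa),
            "n": self.n,
        }


def concordance_ccc(x: NDArray, y: NDArray, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``sample_moments=True`` uses 1/(n-1) variances instead of Lin's
    population moments; the difference vanishes for large n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ddof = 1 if sample_moments else 0
    sx2 = np.var(x, ddof=ddof)
    sy2 = np.var(y, ddof=ddof)
    n = x.size
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    if sample_moments:
        sxy *= n / (n - 1)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("degenerate data: zero variance and equal means")
    return float(2.0 * sxy / denom)


def _ccc_ci(ccc: float, r: float, x: NDArray, y: NDArray, alpha: float = 0.05):
    """Normal-theory CI for CCC via Lin's z-transform (asymptotic)."""
    n = x.size
    if abs(ccc) >= 1 or abs(r) < 1e-12 or n <= 2:
        return (float("nan"), float("nan"))
    u = (x.mean() - y.mean()) / np.sqrt(np.std(x) * np.std(y))
    c2 = ccc**2
    se2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - c2**2 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    if se2 <= 0:
        return (float("nan"), float("nan"))
    z = np.arctanh(ccc)
    zc = stats.norm.ppf(1 - alpha / 2) * np.sqrt(se2)
    return (float(np.tanh(z - zc)), float(np.tanh(z + zc)))


def agreement(x, y, alpha: float = 0.05) -> AgreementReport:
    """Full agreement report of test values ``y`` against reference ``x``.

    Requires n >= 3 finite pairs and non-zero variance in ``x``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0:
        raise ValueError("reference values have zero variance: regression undefined")

    n = x.size
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    intercept_ci = (
        fit.intercept - tcrit * fit.intercept_stderr,
        fit.intercept + tcrit * fit.intercept_stderr,
    )

    r = float(fit.rvalue)
    if abs(r) < 1 and n > 3:
        zr = np.arctanh(r)
        zc = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
        r_ci = (float(np.tanh(zr - zc)), float(np.tanh(zr + zc)))
    else:
        r_ci = (float("nan"), float("nan"))

    ccc = concordance_ccc(x, y)
    ccc_ci = _ccc_ci(ccc, r, x, y, alpha)

    resid_identity = y - x
    rmse = float(np.sqrt(np.mean(resid_identity**2)))
    yhat = fit.intercept + fit.slope * x
    rmsd = float(np.sqrt(np.mean((y - yhat) ** 2)))

    bias = float(np.mean(resid_identity))
    sd = float(np.std(resid_identity, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)

    return AgreementReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=tuple(map(float, slope_ci)),
        intercept_ci=tuple(map(float, intercept_ci)),
        pearson_r=r,
        r_ci=r_ci,
        ccc=float(ccc),
        ccc_ci=ccc_ci,
        rmse=rmse,
        rmsd=rmsd,
        bias=bias,
        loa=tuple(map(float, loa)),
        n=n,
    )
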