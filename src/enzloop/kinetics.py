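"""Hill-equation kinetics: rate model and nonlinear least-squares fitting.

The observed rate of the epoxide ring-opening reaction as a function of the
varied substrate concentration S (mM) is modelled by the Hill equation

    v(S) = k_obs,max * S**n / (K_50**n + S**n)

with half-saturation concentration K_50 (mM), limiting rate k_obs,max (1/s)
and Hill coefficient n (apparent cooperativity; n > 1 indicates positive
cooperativity). Fitting follows the statsmodels Model/Results convention:
``HillModel(dataset).fit()`` returns a :class:`HillResults` carrying the
estimates, their standard errors from the curvature at the optimum, and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HillParams",
    "RateDataset",
    "HillModel",
    "HillResults",
    "hill_rate",
    "fit_hill",
    "read_rate_table",
    "EPOXIDE_CONCENTRATIONS_MM",
    "AZIDE_CONCENTRATIONS_MM",
]

#: Epoxide concentration grid (mM) used when the epoxide is varied at a fixed
#: 60 mM azide background.
EPOXIDE_CONCENTRATIONS_MM = (
    5.0, 10.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0,
    80.0, 90.0, 100.0, 110.0, 120.0, 130.0, 140.0, 150.0,
)

#: Azide concentration grid (mM) used when azide is varied at a fixed 100 mM
#: epoxide background.
AZIDE_CONCENTRATIONS_MM = (
    1.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0, 40.0, 60.0, 80.0, 100.0,
)


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters; optional standard errors alongside."""

    K50: float
    kmax: float
    n: float
    K50_se: Optional[float] = None
    kmax_se: Optional[float] = None
    n_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.K50 <= 0 or self.kmax <= 0 or self.n <= 0:
            raise ValueError(
                f"Hill parameters must be positive, got K50={self.K50}, "
                f"kmax={self.kmax}, n={self.n}"
            )

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency k_obs,max / K_50 (1/s/mM)."""
        return self.kmax / self.K50

    def as_array(self) -> np.ndarray:
        return np.array([self.K50, self.kmax, self.n])


@dataclass(frozen=True)
class RateDataset:
    """Observed rates at varied substrate concentrations.

    ``species`` tags which substrate was varied ("epoxide" or "azide");
    ``fixed_cosubstrate_mM`` is the constant co-substrate background.
    """

    concentrations_mM: np.ndarray
    rates_per_s: np.ndarray
    replicate: np.ndarray
    species: str = "epoxide"
    fixed_cosubstrate_mM: float = 60.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_mM, dtype=float)
        rates = np.asarray(self.rates_per_s, dtype=float)
        rep = np.asarray(self.replicate)
        if conc.shape != rates.shape or conc.shape != rep.shape:
            raise ValueError("concentration/rate/replicate arrays must align")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")
        object.__setattr__(self, "concentrations_mM", conc)
        object.__setattr__(self, "rates_per_s", rates)
        object.__setattr__(self, "replicate", rep)

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations_mM).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conc_mM": self.concentrations_mM,
                "rate_per_s": self.rates_per_s,
                "replicate": self.replicate,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_rate_table(path, species: str = "epoxide",
                    fixed_cosubstrate_mM: float = 60.0) -> RateDataset:
    """Read a TSV rate table with columns conc_mM, rate_per_s[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    if "conc_mM" not in df or "rate_per_s" not in df:
        raise ValueError(f"{path}: need columns 'conc_mM' and 'rate_per_s'")
    rep = df["replicate"].to_numpy() if "replicate" in df else np.zeros(len(df), int)
    return RateDataset(
        concentrations_mM=df["conc_mM"].to_numpy(float),
        rates_per_s=df["rate_per_s"].to_numpy(float),
        replicate=rep,
        species=species,
        fixed_cosubstrate_mM=fixed_cosubstrate_mM,
    )


def hill_rate(S, params: HillParams):
    """Hill rate v(S) = kmax * S**n / (K50**n + S**n); v(0) = 0."""
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore"):
        Sn = np.power(S, params.n)
    v = params.kmax * Sn / (params.K50**params.n + Sn)
    v = np.where(S == 0, 0.0, v)
    if v.ndim == 0:
        return float(v)
    return v


class HillModel:
    """Hill-equation model bound to a rate dataset.

    Parameters
    ----------
    data
        A :class:`RateDataset` (or anything :meth:`from_dataframe` builds one
        from). At least 4 distinct concentrations are required to fit the
        three parameters.
    weighted
        If True, residuals are weighted by 1/v (relative least squares),
        matching a multiplicative error model; default is unweighted.
    """

    def __init__(self, data: RateDataset, weighted: bool = False) -> None:
        self.data = data
        self.weighted = weighted

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        conc_col: str = "conc_mM",
        rate_col: str = "rate_per_s",
        replicate_col: str | None = "replicate",
        **kwargs,
    ) -> "HillModel":
        rep = (
            df[replicate_col].to_numpy()
            if replicate_col and replicate_col in df
            else np.zeros(len(df), int)
        )
        ds = RateDataset(
            concentrations_mM=df[conc_col].to_numpy(float),
            rates_per_s=df[rate_col].to_numpy(float),
            replicate=rep,
        )
        return cls(ds, **kwargs)

    def _default_init(self) -> np.ndarray:
        conc = self.data.concentrations_mM
        rates = self.data.rates_per_s
        vmax = float(np.max(rates))
        if vmax <= 0:
            vmax = 1.0
        half = vmax / 2.0
        k50 = float(conc[np.argmin(np.abs(rates - half))])
        k50 = max(k50, 1e-6)
        return np.array([k50, vmax * 1.1, 2.0])

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        k50, kmax, n = x
        v = kmax * self.data.concentrations_mM**n / (
            k50**n + self.data.concentrations_mM**n
        )
        res = v - self.data.rates_per_s
        if self.weighted:
            res = res / np.maximum(np.abs(v), 1e-12)
        return res

    def fit(
        self,
        init: HillParams | None = None,
        n_restarts: int = 10,
        seed: int = 0,
    ) -> "HillResults":
        """Least-squares fit with seeded multi-start initialization.

        The base start places K_50 at the concentration nearest half the
        maximal observed rate, k_obs,max at 1.1x the maximal rate and n at 2;
        ``n_restarts`` log-normal perturbations of that start guard against
        local minima. Standard errors come from the Jacobian at the optimum.
        """
        if self.data.n_distinct < 4:
            raise ValueError(
                f"need >= 4 distinct concentrations to fit 3 parameters, "
                f"got {self.data.n_distinct}"
            )
        x0 = init.as_array() if init is not None else self._default_init()
        conc = self.data.concentrations_mM
        if not (conc.min() < x0[0] < conc.max()):
            warnings.warn(
                "initial K50 outside the sampled concentration range; the "
                "data may not span the half-saturation point",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(n_restarts):
            starts.append(x0 * np.exp(rng.normal(0.0, 0.4, size=3)))

        best = None
        for s in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    np.maximum(s, 1e-8),
                    bounds=([1e-8, 1e-8, 1e-3], [np.inf, np.inf, 50.0]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimization starts failed")

        rss = float(2.0 * best.cost)
        converged = bool(best.success)
        dof = conc.size - 3
        se = np.full(3, np.nan)
        if dof > 0:
            jtj = best.jac.T @ best.jac
            try:
                cov = np.linalg.inv(jtj) * rss / dof
                se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            except np.linalg.LinAlgError:
                converged = False
        params = HillParams(
            K50=float(best.x[0]),
            kmax=float(best.x[1]),
            n=float(best.x[2]),
            K50_se=float(se[0]) if np.isfinite(se[0]) else None,
            kmax_se=float(se[1]) if np.isfinite(se[1]) else None,
            n_se=float(se[2]) if np.isfinite(se[2]) else None,
        )
        return HillResults(model=self, params=params, rss=rss, converged=converged)


@dataclass(frozen=True)
class HillResults:
    """Fit result: estimates, fit standard errors, diagnostics."""

    model: HillModel
    params: HillParams
    rss: float
    converged: bool

    @property
    def efficiency(self) -> float:
        """k_obs,max / K_50 (1/s/mM)."""
        return self.params.efficiency

    @property
    def bse(self) -> dict[str, Optional[float]]:
        """Standard errors of the estimates (from the curvature at the optimum)."""
        p = self.params
        return {"K50": p.K50_se, "kmax": p.kmax_se, "n": p.n_se}

    @property
    def nobs(self) -> int:
        return int(self.model.data.concentrations_mM.size)

    def predict(self, S) -> np.ndarray:
        return hill_rate(S, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Hill-equation fit",
            "=" * 46,
            f"observations        {self.nobs}",
            f"distinct conc.      {self.model.data.n_distinct}",
            f"varied species      {self.model.data.species}",
            f"residual SS         {self.rss:.6g}",
            f"converged           {self.converged}",
            "-" * 46,
            f"K_50 (mM)           {p.K50:.4g}"
            + (f"  +/- {p.K50_se:.2g}" if p.K50_se is not None else ""),
            f"k_obs,max (1/s)     {p.kmax:.4g}"
            + (f"  +/- {p.kmax_se:.2g}" if p.kmax_se is not None else ""),
            f"Hill n (-)          {p.n:.4g}"
            + (f"  +/- {p.n_se:.2g}" if p.n_se is not None else ""),
            f"kmax/K50 (1/s/mM)   {self.efficiency:.4g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Rates and fitted curve on one axes (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.plot(d.concentrations_mM, d.rates_per_s, "o", label="observed")
        s = np.linspace(0, float(d.concentrations_mM.max()) * 1.05, 200)
        ax.plot(s, self.predict(s), "-", label="Hill fit")
        ax.set_xlabel(f"[{d.species}] (mM)")
        ax.set_ylabel("rate (1/s)")
        ax.legend()
        return ax


def fit_hill(
    data: RateDataset,
    init: HillParams | None = None,
    seed: int = 0,
    weighted: bool = False,
) -> HillResults:
    """Functional wrapper around :class:`HillModel` + :meth:`HillModel.fit`."""
    return HillModel(data, weighted=weighted).fit(init=init, seed=seed)
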