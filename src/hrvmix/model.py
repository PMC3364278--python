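"""Model/Results interface to the greedy-EM mixture fit.

`HeartRateMixture` follows the familiar modelling idiom: construct the model
from data (an array of bpm samples, a :class:`~hrvmix.series.HeartRateSeries`,
or a DataFrame column), call :meth:`~HeartRateMixture.fit`, and work with the
returned :class:`HeartRateMixtureResults` — parameter table, approximate
standard errors, information criteria, a ``summary()`` table, generative
sampling and a density plot.

Standard errors are the single-Gaussian asymptotics evaluated at the
effective per-component sample sizes ``N_k = N * pi_k``:

    se(pi_k)      = sqrt(pi_k (1 - pi_k) / N)
    se(mu_k)      = sigma_k / sqrt(N_k)
    se(sigma_k^2) = sigma_k^2 sqrt(2 / N_k)

These ignore component overlap and are therefore slightly optimistic when
components are poorly separated; they are meant for reporting scale, not for
formal inference.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .mixture import (
    DEFAULT_DOMINANCE_THRESHOLD,
    DEFAULT_K_MAX,
    DEFAULT_N_CANDIDATES,
    DEFAULT_REL_TOL,
    FitTrace,
    GaussianMixture,
    dominant_components,
    fit_greedy,
    log_likelihood,
    mixture_pdf,
    responsibilities,
    sample_mixture,
)
from .series import HeartRateSeries

__all__ = ["HeartRateMixture", "HeartRateMixtureResults"]


class HeartRateMixture:
    """Finite Gaussian mixture model of heart-rate samples, fitted greedily.

    Parameters
    ----------
    endog : array-like
        Observed heart-rate values (bpm).  Any one-dimensional float array is
        accepted; use :meth:`from_series` / :meth:`from_dataframe` for the
        package's series type or for tabular data.
    """

    def __init__(self, endog):
        endog = np.asarray(endog, dtype=float).ravel()
        if endog.size < 2:
            raise ValueError("need at least two observations")
        if not np.all(np.isfinite(endog)):
            raise ValueError("observations must be finite")
        self.endog = endog
        self.nobs = endog.size

    @classmethod
    def from_series(cls, hr: HeartRateSeries) -> "HeartRateMixture":
        return cls(hr.values)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column: str = "bpm") -> "HeartRateMixture":
        return cls(data[column].to_numpy())

    def fit(
        self,
        k_max: int = DEFAULT_K_MAX,
        tol: float = DEFAULT_REL_TOL,
        seed: Optional[int] = None,
        n_candidates_per_component: int = DEFAULT_N_CANDIDATES,
        dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
    ) -> "HeartRateMixtureResults":
        """Grow the mixture by greedy EM and return a results object."""
        mixture, trace = fit_greedy(
            self.endog,
            k_max=k_max,
            tol=tol,
            seed=seed,
            n_candidates_per_component=n_candidates_per_component,
        )
        return HeartRateMixtureResults(
            model=self,
            mixture=mixture,
            trace=trace,
            dominance_threshold=dominance_threshold,
            seed=seed,
        )

    def loglike(self, mixture: GaussianMixture) -> float:
        return log_likelihood(mixture, self.endog)


class HeartRateMixtureResults:
    """Fit results: the mixture, its trace, and reporting helpers."""

    def __init__(
        self,
        model: HeartRateMixture,
        mixture: GaussianMixture,
        trace: FitTrace,
        dominance_threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
        seed: Optional[int] = None,
    ):
        self.model = model
        self.mixture = mixture
        self.trace = trace
        self.dominance_threshold = dominance_threshold
        self.seed = seed
        self.llf = log_likelihood(mixture, model.endog)
        self.dominant_mixture, self.n_dominant = dominant_components(
            mixture, dominance_threshold
        )

    # -- parameter tables ---------------------------------------------------

    @property
    def k(self) -> int:
        return self.mixture.k

    @property
    def df_model(self) -> int:
        """Free parameters: K weights (minus the simplex constraint) + K means + K variances."""
        return 3 * self.k - 1

    @property
    def params(self) -> pd.DataFrame:
        """One row per component (weight order): weight, mean, variance."""
        return pd.DataFrame(
            {
                "weight": self.mixture.weights,
                "mean": self.mixture.means,
                "variance": self.mixture.variances,
            },
            index=pd.RangeIndex(1, self.k + 1, name="rank"),
        )

    @property
    def bse(self) -> pd.DataFrame:
        """Approximate standard errors (see module docstring)."""
        n = self.model.nobs
        w = self.mixture.weights
        var = self.mixture.variances
        nk = np.maximum(n * w, 1.0)
        return pd.DataFrame(
            {
                "weight": np.sqrt(w * (1.0 - w) / n),
                "mean": np.sqrt(var / nk),
                "variance": var * np.sqrt(2.0 / nk),
            },
            index=pd.RangeIndex(1, self.k + 1, name="rank"),
        )

    @property
    def aic(self) -> float:
        return 2.0 * self.df_model - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.df_model * np.log(self.model.nobs) - 2.0 * self.llf

    # -- behaviour ----------------------------------------------------------

    def pdf(self, x) -> np.ndarray:
        return mixture_pdf(self.mixture, x)

    def predict_responsibilities(self) -> np.ndarray:
        return responsibilities(self.mixture, self.model.endog)

    def sample(self, n: int, seed: Optional[int] = None, dominant_only: bool = False):
        """Generative draws from the fitted mixture (optionally dominant part only)."""
        m = self.dominant_mixture if dominant_only and self.dominant_mixture else self.mixture
        return sample_mixture(m, n, seed=seed)

    def to_json(self, path) -> None:
        meta = {
            "n": int(self.model.nobs),
            "loglik": self.llf,
            "seed": self.seed,
            "stopping": self.trace.stopping_reason,
            "n_dominant": int(self.n_dominant),
            "dominance_threshold": self.dominance_threshold,
        }
        self.mixture.to_json(path, meta=meta)

    def plot_fit(self, ax=None, bins: int = 60):
        """Histogram of the data with the mixture density and weighted components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.endog
        ax.hist(y, bins=bins, density=True, alpha=0.4, color="0.6", label="data")
        grid = np.linspace(y.min(), y.max(), 400)
        for i, c in enumerate(self.mixture.components, start=1):
            comp = c.weight * np.exp(
                -0.5 * (grid - c.mean) ** 2 / c.variance
            ) / np.sqrt(2 * np.pi * c.variance)
            ax.plot(grid, comp, "r-", lw=1, alpha=0.8,
                    label="weighted components" if i == 1 else None)
        ax.plot(grid, self.pdf(grid), "k-", lw=1.5, label="mixture")
        ax.set_xlabel("heart rate (bpm)")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text summary table in the style of statsmodels results."""
        from statsmodels.iolib.table import SimpleTable

        head = SimpleTable(
            [
                ["No. observations:", f"{self.model.nobs}"],
                ["Components (K):", f"{self.k}"],
                ["Dominant (w > {:.2f}):".format(self.dominance_threshold),
                 f"{self.n_dominant}"],
                ["Log-likelihood:", f"{self.llf:.3f}"],
                ["AIC:", f"{self.aic:.3f}"],
                ["BIC:", f"{self.bic:.3f}"],
                ["Stopping:", self.trace.stopping_reason],
            ],
            title="Heart-rate Gaussian mixture (greedy EM)",
        )
        p, se = self.params, self.bse
        rows = [
            [
                f"{i}",
                f"{p.loc[i, 'weight']:.4f}", f"{se.loc[i, 'weight']:.4f}",
                f"{p.loc[i, 'mean']:.3f}", f"{se.loc[i, 'mean']:.3f}",
                f"{p.loc[i, 'variance']:.3f}", f"{se.loc[i, 'variance']:.3f}",
            ]
            for i in p.index
        ]
        body = SimpleTable(
            rows,
            headers=["rank", "weight", "se", "mean", "se", "variance", "se"],
            title="Components (decreasing weight)",
        )
        return f"{head.as_text()}\n{body.as_text()}"

    def __repr__(self) -> str:
        return (
            f"<HeartRateMixtureResults K={self.k} dominant={self.n_dominant} "
            f"llf={self.llf:.2f}>"
        )
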