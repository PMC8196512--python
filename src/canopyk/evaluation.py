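"""Predictions, observation-level error metrics and the multi-method report.

Every method predicts through the same bounded mean curve
``1 - exp(-k_hat * LAI)``; for the log-transformed linear model this is
exactly the back-transformation of its log-scale predictions, which makes
observation-level mean squared errors comparable across methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Dataset
from .errors import ConfigurationError, ValidationError
from .estimators import (
    METHODS,
    FitResult,
    MCMCConfig,
    OptimizerConfig,
    PriorSpec,
    beer_lambert_mean,
    fit_logtlm,
    fit_lse,
    fit_mle_beta,
    fit_mle_normal,
    run_metropolis,
    summarize_posterior,
)


def predict_fpari(fit: FitResult, lai, genotype: str) -> np.ndarray:
    """Predicted fPARi for one genotype at the given LAI values."""
    if genotype not in fit.k_estimates:
        raise KeyError(
            f"genotype {genotype!r} not present in {fit.method} fit; "
            f"available: {list(fit.k_estimates)}"
        )
    return np.asarray(
        beer_lambert_mean(fit.k_estimates[genotype], np.asarray(lai, dtype=float))
    )


def mse(predicted, observed) -> float:
    """Mean squared difference between predicted and observed values."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ConfigurationError(f"length mismatch: {p.size} vs {o.size}")
    if p.size == 0:
        raise ValidationError("mse of empty input")
    return float(np.mean((p - o) ** 2))


def out_of_range_fraction(values) -> float:
    """Fraction of values outside [0, 1].

    Zero for any mean-curve prediction; meaningful for normal predictive
    draws, which have unbounded support.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("out_of_range_fraction of empty input")
    return float(np.mean((v < 0.0) | (v > 1.0)))


@dataclass
class ResidualSummary:
    """Moments and range of observation-level residuals (predicted - observed)."""

    mean: float
    sd: float
    min: float
    max: float
    mse: float

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "mse": self.mse,
        }


def _predictions(fit: FitResult, d: Dataset) -> np.ndarray:
    missing = set(d.genotype_index) - set(fit.k_estimates)
    if missing:
        raise ValidationError(
            f"{fit.method} fit lacks genotypes {sorted(missing)} present in the data"
        )
    lai, _, codes = d.to_arrays()
    k = fit.k_array(d.genotypes)
    return np.asarray(beer_lambert_mean(k[codes], lai))


def residual_summary(fit: FitResult, d: Dataset) -> ResidualSummary:
    """Observation-level residuals of a fit on a dataset."""
    pred = _predictions(fit, d)
    _, observed, _ = d.to_arrays()
    r = pred - observed
    return ResidualSummary(
        mean=float(np.mean(r)),
        sd=float(np.std(r, ddof=1)) if r.size > 1 else 0.0,
        min=float(np.min(r)),
        max=float(np.max(r)),
        mse=mse(pred, observed),
    )


@dataclass
class ComparisonReport:
    """Estimates, intervals and predictive metrics for several methods.

    ``relative_magnitude`` holds, per method and genotype, the percent size
    of that method's k estimate relative to the log-transformed linear
    model's estimate for the same genotype (full precision; rounding is
    presentation-only). It is empty when no LogTLM fit is present.
    """

    fits: dict[str, FitResult]
    mse_by_method: dict[str, float] = field(default_factory=dict)
    residuals: dict[str, ResidualSummary] = field(default_factory=dict)
    out_of_range: dict[str, float] = field(default_factory=dict)
    relative_magnitude: dict[str, dict[str, float]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fits(
        cls,
        fits: dict[str, FitResult],
        dataset: Dataset | None = None,
        failures: dict[str, str] | None = None,
    ) -> "ComparisonReport":
        """Assemble a report from already-computed fits.

        Predictive metrics require a dataset; with ``dataset=None`` only the
        estimate table and relative magnitudes are populated.
        """
        report = cls(fits=dict(fits), failures=dict(failures or {}))
        if dataset is not None:
            for name, fit in fits.items():
                pred = _predictions(fit, dataset)
                _, observed, _ = dataset.to_arrays()
                report.mse_by_method[name] = mse(pred, observed)
                report.residuals[name] = residual_summary(fit, dataset)
                report.out_of_range[name] = out_of_range_fraction(pred)
        ref = fits.get("LogTLM")
        if ref is not None:
            for name, fit in fits.items():
                report.relative_magnitude[name] = {
                    g: 100.0 * k_hat / ref.k_estimates[g]
                    for g, k_hat in fit.k_estimates.items()
                    if g in ref.k_estimates
                }
        return report

    # -- presentation ------------------------------------------------------

    def estimates_table(self) -> pd.DataFrame:
        """Genotype x method table of "estimate (lo-hi)" strings."""
        genotypes: list[str] = []
        for fit in self.fits.values():
            for g in fit.k_estimates:
                if g not in genotypes:
                    genotypes.append(g)
        methods = [m for m in METHODS if m in self.fits] + [
            m for m in self.fits if m not in METHODS
        ]
        rows = {}
        for g in genotypes:
            row = {}
            for m in methods:
                fit = self.fits[m]
                if g not in fit.k_estimates:
                    row[m] = ""
                    continue
                cell = f"{fit.k_estimates[g]:.2f}"
                if fit.k_interval is not None and g in fit.k_interval:
                    lo, hi = fit.k_interval[g]
                    cell += f" ({lo:.2f}-{hi:.2f})"
                row[m] = cell
            rows[g] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "genotype"
        return frame

    def metrics_table(self) -> pd.DataFrame:
        """Method x metric table (MSE, residual stats, out-of-range fraction)."""
        rows = {}
        for m in self.fits:
            row = {"mse": self.mse_by_method.get(m)}
            rs = self.residuals.get(m)
            if rs is not None:
                row.update(
                    {
                        "residual_mean": rs.mean,
                        "residual_sd": rs.sd,
                        "residual_min": rs.min,
                        "residual_max": rs.max,
                    }
                )
            row["out_of_range_fraction"] = self.out_of_range.get(m)
            rows[m] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "method"
        return frame

    def relative_magnitude_percent(self) -> dict[str, dict[str, int]]:
        """Relative magnitudes rounded to the nearest integer percent."""
        return {
            m: {g: int(round(v)) for g, v in per.items()}
            for m, per in self.relative_magnitude.items()
        }

    def to_dict(self) -> dict:
        return {
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
            "mse": self.mse_by_method,
            "residuals": {m: r.to_dict() for m, r in self.residuals.items()},
            "out_of_range_fraction": self.out_of_range,
            "relative_magnitude": self.relative_magnitude,
            "relative_magnitude_percent": self.relative_magnitude_percent(),
            "failures": self.failures,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def compare_methods(
    d: Dataset,
    methods: list[str] | None = None,
    optimizer_cfg: OptimizerConfig | None = None,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    precomputed: dict[str, FitResult] | None = None,
) -> ComparisonReport:
    """Fit the requested methods on one dataset and assemble the report.

    Individual fit failures are recorded per method and do not abort the
    report. ``precomputed`` fits are taken as-is instead of refitting.
    """
    methods = list(METHODS) if methods is None else list(methods)
    if not methods:
        raise ConfigurationError("at least one method is required")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ConfigurationError(f"unknown method(s) {unknown}; choose from {METHODS}")
    optimizer_cfg = optimizer_cfg or OptimizerConfig()
    precomputed = precomputed or {}

    def bayes(dd):
        return summarize_posterior(run_metropolis(dd, priors=priors, mcmc=mcmc))

    runners = {
        "LSE": lambda dd: fit_lse(dd, optimizer_cfg),
        "MLE_normal": lambda dd: fit_mle_normal(dd, optimizer_cfg),
        "MLE_beta": lambda dd: fit_mle_beta(dd, optimizer_cfg),
        "LogTLM": fit_logtlm,
        "Bayes_beta": bayes,
    }
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for m in methods:
        if m in precomputed:
            fits[m] = precomputed[m]
            continue
        try:
            fits[m] = runners[m](d)
        except Exception as exc:  # recorded, not fatal
            failures[m] = f"{type(exc).__name__}: {exc}"
    return ComparisonReport.from_fits(fits, dataset=d, failures=failures)
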