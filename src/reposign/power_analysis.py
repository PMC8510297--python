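"""Analytic power of a multi-study meta-analysis (Hedges & Pigott style).

Power to detect a summary standardized mean difference across k two-group
studies: each study contributes a Hedges-g variance
v_i = (n1+n2)/(n1*n2) + es^2 / (2*(n1+n2)); between-study heterogeneity
enters as tau2 added to every v_i; the pooled summary variance is
V = 1 / sum(1/(v_i + tau2)), the noncentrality is lambda = es / sqrt(V),
and two-sided power at level alpha is
1 - Phi(z_{1-alpha/2} - lambda) + Phi(-z_{1-alpha/2} - lambda).

Heterogeneity levels follow the convention tau2 = c * mean(v_i) with
c = 0, 1/3, 2/3, 1 for none / low / moderate / high; an explicit tau2
overrides the level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

HETEROGENEITY_COEF = {"none": 0.0, "low": 1.0 / 3.0, "moderate": 2.0 / 3.0, "high": 1.0}


class PowerSpecError(ValueError):
    pass


@dataclass
class PowerSpec:
    """Inputs of the meta-analysis power computation.

    per_study_sizes: (n_case, n_ctrl) per study; target_es: summary Hedges g
    to detect; alpha: two-sided type-I error; heterogeneity_level: one of
    none/low/moderate/high, or set ``tau2`` explicitly.
    """

    per_study_sizes: list[tuple[int, int]]
    target_es: float
    alpha: float = 0.01
    heterogeneity_level: str = "none"
    tau2: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise PowerSpecError("alpha must be in (0, 1)")
        if not self.per_study_sizes:
            raise PowerSpecError("need at least one study")
        for n1, n2 in self.per_study_sizes:
            if n1 < 2 or n2 < 2:
                raise PowerSpecError("each group needs >= 2 samples")
        if self.tau2 is None and self.heterogeneity_level not in HETEROGENEITY_COEF:
            raise PowerSpecError(
                f"heterogeneity_level must be one of {sorted(HETEROGENEITY_COEF)}"
            )
        if self.tau2 is not None and self.tau2 < 0:
            raise PowerSpecError("tau2 must be >= 0")


def study_variance(n_case: int, n_ctrl: int, es: float) -> float:
    """Hedges-g sampling variance of one study at a given effect size."""
    return (n_case + n_ctrl) / (n_case * n_ctrl) + es * es / (2.0 * (n_case + n_ctrl))


def _variances_and_tau2(spec: PowerSpec) -> tuple[np.ndarray, float]:
    v = np.array([study_variance(n1, n2, spec.target_es) for n1, n2 in spec.per_study_sizes])
    tau2 = spec.tau2 if spec.tau2 is not None else HETEROGENEITY_COEF[spec.heterogeneity_level] * float(v.mean())
    return v, float(tau2)


def meta_power(spec: PowerSpec) -> float:
    """Two-sided analytic power of the pooled effect-size test."""
    v, tau2 = _variances_and_tau2(spec)
    V = 1.0 / np.sum(1.0 / (v + tau2))
    lam = spec.target_es / np.sqrt(V)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.sf(z_crit - lam) + stats.norm.cdf(-z_crit - lam))


def monte_carlo_power(spec: PowerSpec, n_reps: int = 5000, seed: int = 0) -> float:
    """Empirical power by simulating per-study effect estimates.

    Per replicate: true study effects theta_i ~ N(es, tau2), observed
    g_i ~ N(theta_i, v_i), pooled with the known weights 1/(v_i + tau2);
    the replicate rejects when |ES/SE| exceeds z_{1-alpha/2}.
    """
    rng = np.random.default_rng(seed)
    v, tau2 = _variances_and_tau2(spec)
    k = v.size
    theta = rng.normal(spec.target_es, np.sqrt(tau2), size=(n_reps, k))
    g = rng.normal(theta, np.sqrt(v)[None, :])
    w = 1.0 / (v + tau2)
    es = (g * w[None, :]).sum(axis=1) / w.sum()
    se = np.sqrt(1.0 / w.sum())
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(np.mean(np.abs(es / se) > z_crit))


def load_table1_sizes() -> pd.DataFrame:
    """Packaged per-study (n_case, n_ctrl) sizes of the 11 discovery cohorts."""
    with resources.files("reposign.data").joinpath("table1_sizes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_size_pairs() -> list[tuple[int, int]]:
    df = load_table1_sizes()
    return [(int(r.n_case), int(r.n_ctrl)) for r in df.itertuples()]
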