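"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* multi-cohort expression — per-cohort genes x samples matrices with planted
  differentially expressed (DE) genes whose true per-study effects follow a
  random-effects model (between-study variance tau2) on the Hedges-g scale
  (unit within-group SD, so planted deltas are directly interpretable as g);
* a drug-perturbation compendium with one planted signature-reversing drug
  and one signature-mimicking drug among i.i.d. null profiles;
* GMT gene-set collections with one planted signature-enriched set;
* survival cohorts with a known exposure hazard ratio, optional shared
  covariate effects on exposure and hazard (healthy-user-style confounding),
  exponential event times (proportional hazards by construction) and
  independent exponential censoring calibrated to a target rate.

All generators are bit-reproducible given their config and seed; one run
seed fans out to per-component child streams via fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset
from .power_analysis import table1_size_pairs

# fixed child-stream offsets: rng for component X is default_rng([seed, OFFSET[X]])
SEED_OFFSETS = {"expression": 1, "drugs": 2, "gene_sets": 3, "survival": 4}


class SimulationError(ValueError):
    pass


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), SEED_OFFSETS[component]])


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

def paper_like_sizes() -> list[tuple[int, int]]:
    """The 11 discovery-cohort (n_case, n_ctrl) pairs (5-30 per group)."""
    return table1_size_pairs()


@dataclass
class SimConfig:
    """Multi-cohort expression simulation settings.

    Defaults reproduce the discovery-study conditions: 11 cohorts with the
    published per-group sizes, 10 000 genes of which 500 are DE at mean
    |g| = 1.0, low between-study heterogeneity (tau2 = 0.05 on the true
    effects), and fully shared gene panels (platform_dropout = 0).
    """

    n_datasets: int = 11
    per_group_sizes: list[tuple[int, int]] = field(default_factory=paper_like_sizes)
    n_genes: int = 10_000
    n_de: int = 500
    de_effect_mean: float = 1.0
    tau2: float = 0.05
    platform_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise SimulationError("n_de must be <= n_genes")
        if len(self.per_group_sizes) != self.n_datasets:
            raise SimulationError("per_group_sizes must list one pair per dataset")
        if any(n1 < 2 or n2 < 2 for n1, n2 in self.per_group_sizes):
            raise SimulationError("each group needs >= 2 samples")
        if not (0 <= self.platform_dropout < 1):
            raise SimulationError("platform_dropout must be in [0, 1)")
        if self.tau2 < 0:
            raise SimulationError("tau2 must be >= 0")


@dataclass
class SimTruth:
    """Ground truth planted by the generators, for recovery tests."""

    de_genes: dict[str, int] = field(default_factory=dict)   # gene -> +1/-1
    true_effects: dict[str, float] = field(default_factory=dict)
    reverser_drug: str | None = None
    mimic_drug: str | None = None
    enriched_set: str | None = None
    true_hr: float | None = None


# ---------------------------------------------------------------------------
# multi-cohort expression
# ---------------------------------------------------------------------------

def gen_multicohort(config: SimConfig) -> tuple[list[ExpressionDataset], SimTruth]:
    """Simulate per-cohort expression with planted DE genes.

    For DE gene j with signed mean effect mu_j, each study i draws a true
    effect delta_ij ~ N(mu_j, tau2); case samples ~ N(delta_ij, 1) and
    controls ~ N(0, 1).  Non-DE genes are N(0, 1) in both groups.  A random
    ``platform_dropout`` fraction of genes is removed per dataset.
    """
    rng = _rng(config.seed, "expression")
    width = len(str(config.n_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])

    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    signs = np.where(rng.random(config.n_de) < 0.5, 1, -1)
    mu = np.zeros(config.n_genes)
    mu[de_idx] = signs * config.de_effect_mean

    truth = SimTruth(
        de_genes={genes[i]: int(s) for i, s in zip(de_idx, signs)},
        true_effects={genes[i]: float(m) for i, m in zip(de_idx, mu[de_idx])},
    )

    datasets = []
    for i, (n_case, n_ctrl) in enumerate(config.per_group_sizes):
        delta = rng.normal(mu, np.sqrt(config.tau2)) if config.tau2 > 0 else mu.copy()
        case = rng.normal(delta[:, None], 1.0, size=(config.n_genes, n_case))
        ctrl = rng.normal(0.0, 1.0, size=(config.n_genes, n_ctrl))
        ds_id = f"SIM{i + 1:02d}"
        cols = [f"{ds_id}_case_{j}" for j in range(n_case)] + [
            f"{ds_id}_ctrl_{j}" for j in range(n_ctrl)
        ]
        expr = pd.DataFrame(np.hstack([case, ctrl]), index=pd.Index(genes, name="gene"),
                            columns=cols)
        if config.platform_dropout > 0:
            n_drop = int(round(config.platform_dropout * config.n_genes))
            drop = rng.choice(config.n_genes, size=n_drop, replace=False)
            expr = expr.drop(index=genes[drop])
        labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=cols)
        datasets.append(ExpressionDataset(ds_id, expr, labels, platform="simulated"))
    return datasets, truth


# ---------------------------------------------------------------------------
# drug compendium
# ---------------------------------------------------------------------------

def gen_drug_compendium(
    truth: SimTruth,
    disease_es: Mapping[str, float],
    n_drugs: int = 781,
    noise_sd: float = 1.0,
    gold_fraction: float = 0.6,
    extra_reverser_strengths: Sequence[float] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x drugs effect-size compendium with a planted reverser.

    One drug ('reverser') gets per-gene effects -disease_es + noise, one
    ('mimic') +disease_es + noise; the remaining n_drugs - 2 are standard
    normal i.i.d.  ``extra_reverser_strengths`` optionally converts that many
    null slots into graded partial reversers (-strength * disease_es + noise,
    named ``reverser_<strength>``), emulating a compendium in which several
    distinct drugs oppose the disease signature to different degrees.  A
    random ``gold_fraction`` of genes per drug is flagged reliable.  Returns
    (effects, gold_mask) tables and records the planted drugs on ``truth``.
    """
    n_extra = len(extra_reverser_strengths)
    if n_drugs < 2 + n_extra:
        raise SimulationError("need at least 2 drugs plus one per extra reverser")
    if not disease_es:
        raise SimulationError("disease_es is empty")
    rng = _rng(seed, "drugs")
    es = pd.Series(disease_es, dtype=float)
    genes = es.index
    n_genes = len(genes)

    extras = [f"reverser_{s:.2f}" for s in extra_reverser_strengths]
    n_null = n_drugs - 2 - n_extra
    drugs = ["reverser", "mimic"] + extras + [f"drug_{i:04d}" for i in range(1, n_null + 1)]
    eff = np.empty((n_genes, n_drugs))
    eff[:, 0] = -es.to_numpy() + rng.normal(0.0, noise_sd, n_genes)
    eff[:, 1] = es.to_numpy() + rng.normal(0.0, noise_sd, n_genes)
    for j, s in enumerate(extra_reverser_strengths):
        eff[:, 2 + j] = -s * es.to_numpy() + rng.normal(0.0, noise_sd, n_genes)
    eff[:, 2 + n_extra:] = rng.normal(0.0, 1.0, size=(n_genes, n_null))
    effects = pd.DataFrame(eff, index=genes, columns=drugs)

    n_gold = int(round(gold_fraction * n_genes))
    gold = np.zeros((n_genes, n_drugs), dtype=bool)
    for jcol in range(n_drugs):
        gold[rng.choice(n_genes, size=n_gold, replace=False), jcol] = True
    gold_mask = pd.DataFrame(gold, index=genes, columns=drugs)

    truth.reverser_drug = "reverser"
    truth.mimic_drug = "mimic"
    return effects, gold_mask


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 50),
    planted_fraction: float = 1.0,
    signature: Sequence[str] = (),
    seed: int = 0,
) -> tuple[dict[str, set[str]], SimTruth]:
    """Simulate a GMT-style collection with one signature-enriched set.

    The planted set draws ``planted_fraction`` of its members from the
    signature (the rest, and every null set, uniformly from the universe);
    set sizes are uniform over ``set_size_range``.
    """
    lo, hi = set_size_range
    universe = list(universe)
    if hi > len(universe):
        raise SimulationError("set size range exceeds the universe")
    if not (0 <= planted_fraction <= 1):
        raise SimulationError("planted_fraction must be in [0, 1]")
    rng = _rng(seed, "gene_sets")
    uni = np.array(universe)
    sig = [g for g in signature if g in set(universe)]

    collection: dict[str, set[str]] = {}
    truth = SimTruth(enriched_set="planted_set")
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0:
            n_from_sig = min(int(round(planted_fraction * size)), len(sig))
            members = set(rng.choice(sig, size=n_from_sig, replace=False)) if n_from_sig else set()
            rest = np.setdiff1d(uni, np.array(sorted(members)), assume_unique=False)
            members |= set(rng.choice(rest, size=size - len(members), replace=False))
            collection["planted_set"] = members
        else:
            collection[f"null_set_{i:03d}"] = set(rng.choice(uni, size=size, replace=False))
    return collection, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class ConfounderSpec:
    """Shared covariate effects on exposure (logit) and hazard (log-HR).

    Keys are covariate names: ``age_std`` (standardized age), ``sex`` and
    ``comorbidity_1`` .. ``comorbidity_k``.  A healthy-user analog puts
    negative exposure coefficients and positive hazard coefficients on the
    comorbidity flags: frail subjects are less likely to receive the drug
    and more likely to reach the outcome.
    """

    n_comorbidities: int = 3
    comorbidity_prev: float = 0.3
    exposure_effects: dict[str, float] = field(default_factory=dict)
    hazard_effects: dict[str, float] = field(default_factory=dict)


def healthy_user_confounding(strength: float = 1.0, n_comorbidities: int = 3) -> ConfounderSpec:
    """Confounder spec where comorbidities reduce exposure and raise hazard."""
    expo = {f"comorbidity_{i+1}": -strength for i in range(n_comorbidities)}
    haz = {f"comorbidity_{i+1}": strength for i in range(n_comorbidities)}
    expo["age_std"] = -0.3 * strength
    haz["age_std"] = 0.3 * strength
    return ConfounderSpec(n_comorbidities=n_comorbidities,
                          exposure_effects=expo, hazard_effects=haz)


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Bisection for the logistic intercept hitting a marginal exposure rate."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        rate = np.mean(1.0 / (1.0 + np.exp(-(mid + lin))))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _calibrate_censor_rate(lam: np.ndarray, target: float) -> float:
    """Bisection for the exponential censoring rate mu with
    E[P(censor)] = mean(mu / (lambda_i + mu)) = target."""
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e6 * float(lam.mean())
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # rates span orders of magnitude
        rate = np.mean(mid / (lam + mid))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_survival_cohort(
    n: int,
    true_hr: float,
    exposure_prob: float = 0.3,
    confounders: ConfounderSpec | None = None,
    censor_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 1500.0,
    control_outcome: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a subject-level analysis cohort with a known exposure HR.

    Covariates: age ~ N(58, 15^2) truncated at 18, sex ~ Bernoulli(0.5), and
    k binary comorbidities.  Exposure follows a logistic model on the
    covariates with the intercept calibrated so the marginal exposure rate
    matches ``exposure_prob``.  Event times are exponential with hazard
    h0 * exp(log(true_hr)*exposure + covariate effects) — proportional
    hazards hold by construction — and censoring is an independent
    exponential calibrated to ``censor_rate``.  When ``control_outcome`` is
    set, a second outcome with HR 1 for exposure but the same covariate
    hazard effects is emitted (columns ``time_control_days`` /
    ``event_control``) for negative-control analyses.
    """
    if true_hr <= 0:
        raise SimulationError("true_hr must be > 0")
    if not (0 < exposure_prob < 1):
        raise SimulationError("exposure_prob must be in (0, 1)")
    if not (0 <= censor_rate < 1):
        raise SimulationError("censor_rate must be in [0, 1)")
    spec = confounders or ConfounderSpec()
    rng = _rng(seed, "survival")

    age = rng.normal(58.0, 15.0, n)
    while (age < 18).any():  # truncate by redraw
        bad = age < 18
        age[bad] = rng.normal(58.0, 15.0, bad.sum())
    sex = rng.integers(0, 2, n)
    covs = pd.DataFrame({"age": age, "sex": sex})
    covs["age_std"] = (age - 58.0) / 15.0
    for i in range(spec.n_comorbidities):
        covs[f"comorbidity_{i+1}"] = rng.binomial(1, spec.comorbidity_prev, n)

    lin_expo = np.zeros(n)
    for name, beta in spec.exposure_effects.items():
        lin_expo += beta * covs[name].to_numpy(dtype=float)
    intercept = _calibrate_intercept(lin_expo, exposure_prob)
    p_expo = 1.0 / (1.0 + np.exp(-(intercept + lin_expo)))
    exposure = rng.binomial(1, p_expo)

    lin_haz = np.zeros(n)
    for name, beta in spec.hazard_effects.items():
        lin_haz += beta * covs[name].to_numpy(dtype=float)
    lam = baseline_hazard * np.exp(np.log(true_hr) * exposure + lin_haz)
    t_event = rng.exponential(1.0 / lam)

    mu = _calibrate_censor_rate(lam, censor_rate)
    t_cens = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cohort = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "exposure": exposure,
        "index_date": rng.integers(0, 2000, n),
        "time_days": np.maximum(time, 1e-8),
        "event": event,
    })
    for c in ["age", "sex"] + [f"comorbidity_{i+1}" for i in range(spec.n_comorbidities)]:
        cohort[c] = covs[c].to_numpy()

    if control_outcome:
        lam_c = baseline_hazard * np.exp(lin_haz)   # exposure HR = 1
        t_event_c = rng.exponential(1.0 / lam_c)
        t_cens_c = rng.exponential(1.0 / mu, n) if mu > 0 else np.full(n, np.inf)
        cohort["time_control_days"] = np.maximum(np.minimum(t_event_c, t_cens_c), 1e-8)
        cohort["event_control"] = (t_event_c <= t_cens_c).astype(int)

    return cohort, SimTruth(true_hr=float(true_hr))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
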