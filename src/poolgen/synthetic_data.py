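"""Synthetic multi-study case-control data with known ground truth.

Generates K independent case-control studies with exactly the statistical
structure the pooling pipeline assumes, so every downstream stage can be
exercised against a known answer:

- genotypes at named variant sites drawn under Hardy-Weinberg equilibrium,
  with rare (1-2%) and common (8-10%) allele frequencies;
- disease risk following a logistic model with a pooled per-variant
  log-OR ``beta`` plus a study-specific random slope ``b_k ~ N(0, sigma_b^2)``
  (simulation inverts the random-effects model the analysis estimates);
- pigmentation phenotypes (hair colour, skin type, nevus count, freckles)
  correlated with carrier status of a designated red-hair variant;
- study-level quirks the harmonizer must handle: sun exposure delivered as
  ordered classes, hours/day, or days/year depending on the study, and
  covariates missing by design in some studies.

Cases and controls are sampled without replacement from a simulated source
population (default 20x the requested number of cases), which preserves
the odds-ratio interpretation of the logistic coefficients under
case-control sampling.  All randomness flows from a single integer seed;
per-study substreams are spawned deterministically from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import logicreg

__all__ = [
    "SimConfig",
    "MultiStudyDataset",
    "generate_multistudy",
    "plant_logic_outcome",
    "degrade",
    "DEFAULT_VARIANTS",
    "EXPOSURE_CODINGS",
    "FOUR_CLASS_LABELS",
]

#: Default variant panel: the nine canonical sites with control allele
#: frequencies in the rare (1-2%) or common (8-10%) range.
DEFAULT_VARIANTS = (
    ("V60L", 0.10),
    ("D84E", 0.01),
    ("V92M", 0.09),
    ("R142H", 0.01),
    ("R151C", 0.09),
    ("I155T", 0.01),
    ("R160W", 0.08),
    ("R163Q", 0.05),
    ("D294H", 0.02),
)

EXPOSURE_CODINGS = ("hours_day", "four_class", "days_year")
FOUR_CLASS_LABELS = ("never", "seldom", "often", "always")
#: hours/day thresholds for the four ordered exposure classes
_FOUR_CLASS_CUTS = (1.0, 2.5, 4.0)
#: deterministic scale linking days/year to the latent hours/day
_DAYS_PER_YEAR_SCALE = 52.0


@dataclass
class ConfounderSpec:
    """One simulated confounder: its distribution and log-odds effect."""

    kind: str = "continuous"      # continuous | binary
    effect: float = 0.0           # gamma, log-odds per SD (or per level)
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5
    available_in: tuple | None = None  # study indices; None = all studies


@dataclass
class SimConfig:
    """Generator configuration; defaults define the reference conditions.

    ``true_log_or`` maps variant name -> pooled log-OR of carrier status
    (dominant coding); variants absent from the map get log(1.5), the
    effect size a typical candidate-variant pooled analysis is powered
    for.  ``sigma_b`` is the between-study SD of each variant's effect.
    """

    n_studies: int = 8
    cases_per_study: int | list = 300
    controls_per_study: int | list = 500
    variant_specs: tuple = DEFAULT_VARIANTS
    true_log_or: dict = field(default_factory=dict)
    sigma_b: float = 0.15
    confounder_specs: dict = field(default_factory=lambda: {
        "age": ConfounderSpec("continuous", effect=0.15, mean=55.0, sd=12.0),
        "sex": ConfounderSpec("binary", effect=0.10, prevalence=0.5),
        "sunburns": ConfounderSpec(
            "binary", effect=0.25, prevalence=0.35, available_in=None),
    })
    red_hair_variant: str = "R151C"
    red_hair_prob_carrier: float = 0.40
    red_hair_prob_other: float = 0.08
    exposure_coding: list | None = None   # per study; None cycles the codings
    intercept_mean: float = 0.0           # logit(0.5) on the case-control scale
    intercept_sd: float = 0.3
    source_multiplier: int = 20
    seed: int = 0

    def __post_init__(self):
        for name, q in self.variant_specs:
            if not 0 < q < 1:
                raise ValueError(f"allele frequency for {name} must be in (0,1)")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        for v in (self._counts(self.cases_per_study)
                  + self._counts(self.controls_per_study)):
            if v <= 0:
                raise ValueError("case/control counts must be positive")
        if self.exposure_coding is not None:
            bad = set(self.exposure_coding) - set(EXPOSURE_CODINGS)
            if bad:
                raise ValueError(f"unknown exposure codings: {sorted(bad)}")

    def _counts(self, spec) -> list:
        if np.isscalar(spec):
            return [int(spec)] * self.n_studies
        if len(spec) != self.n_studies:
            raise ValueError("per-study count list must have n_studies entries")
        return [int(v) for v in spec]

    def log_or(self, variant: str) -> float:
        return float(self.true_log_or.get(variant, np.log(1.5)))


@dataclass
class MultiStudyDataset:
    """Per-study subject tables plus metadata and simulation ground truth."""

    studies: list                 # list of DataFrames
    metadata: list                # list of dicts (design, codings, ...)
    truth: dict | None = None     # config echo + realized random effects

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def combined(self) -> pd.DataFrame:
        return pd.concat(self.studies, ignore_index=True)

    def write(self, directory) -> None:
        """One CSV per study plus a JSON metadata/truth sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.studies):
            df.to_csv(directory / f"study_{i:02d}.csv", index=False)
        sidecar = {"metadata": self.metadata}
        if self.truth is not None:
            sidecar["truth"] = _jsonable(self.truth)
        (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (SimConfig, ConfounderSpec)):
        return _jsonable(vars(obj))
    return obj


def _simulate_study(rng, config: SimConfig, k: int, n_cases: int, n_controls: int,
                    alpha_k: float, b_k: dict) -> pd.DataFrame:
    n_src = config.source_multiplier * max(n_cases, n_controls)
    variants = list(config.variant_specs)

    geno = {}
    for name, q in variants:
        geno[name] = rng.binomial(2, q, size=n_src)
    carriers = {name: (geno[name] >= 1) for name, _ in variants}

    # pigmentation phenotypes, genotype-correlated
    red_carrier = carriers.get(config.red_hair_variant,
                               np.zeros(n_src, dtype=bool))
    p_red = np.where(red_carrier, config.red_hair_prob_carrier,
                     config.red_hair_prob_other)
    red = rng.random(n_src) < p_red
    other_hair = rng.choice(["blond", "brown", "black"], size=n_src,
                            p=[0.2, 0.5, 0.3])
    hair = np.where(red, "red", other_hair)
    burden = sum(geno[name] for name, _ in variants)
    # fair skin types more likely with higher variant burden
    p_fair = expit(-1.2 + 0.55 * burden)
    skin_type = np.where(rng.random(n_src) < p_fair,
                         rng.integers(1, 3, size=n_src),     # I-II
                         rng.integers(3, 5, size=n_src))     # III-IV
    nevi = rng.negative_binomial(2, 2 / (2 + 18.0), size=n_src)  # mean ~18
    freckles = (rng.random(n_src) < np.where(red_carrier, 0.55, 0.25)).astype(int)
    sun_hours = np.clip(rng.gamma(3.0, 0.8, size=n_src), 0.0, 6.0)

    eta = np.full(n_src, alpha_k)
    for name, _q in variants:
        eta += (config.log_or(name) + b_k[name]) * carriers[name]

    conf_cols = {}
    for cname, spec in config.confounder_specs.items():
        if spec.kind == "binary":
            z = (rng.random(n_src) < spec.prevalence).astype(float)
            eta += spec.effect * z
        else:
            z = rng.normal(spec.mean, spec.sd, size=n_src)
            eta += spec.effect * (z - spec.mean) / spec.sd
        conf_cols[cname] = z

    y = rng.random(n_src) < expit(eta)
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if case_idx.size < n_cases:
        raise ValueError(
            f"study {k}: only {case_idx.size} cases arose in the source "
            f"population for {n_cases} requested; disease too rare at these "
            "parameters — increase source_multiplier"
        )
    if ctrl_idx.size < n_controls:
        raise ValueError(
            f"study {k}: only {ctrl_idx.size} controls available for "
            f"{n_controls} requested; increase source_multiplier"
        )
    take = np.concatenate([
        rng.choice(case_idx, size=n_cases, replace=False),
        rng.choice(ctrl_idx, size=n_controls, replace=False),
    ])

    df = pd.DataFrame({
        "study": k,
        "subject_id": [f"S{k:02d}-{j:05d}" for j in range(take.size)],
        "status": y[take].astype(int),
        "case_type": np.where(y[take], "melanoma", ""),
    })
    for name, _q in variants:
        df[name] = geno[name][take]
    df["hair_color"] = hair[take]
    df["skin_type"] = skin_type[take]
    df["nevi_count"] = nevi[take]
    df["freckles"] = freckles[take]
    df["sun_hours_day"] = sun_hours[take]
    for cname, z in conf_cols.items():
        df[cname] = z[take]
    return df


def _encode_exposure(df: pd.DataFrame, coding: str) -> pd.DataFrame:
    """Re-express the latent hours/day exposure in a study's native coding."""
    df = df.copy()
    hours = df["sun_hours_day"].to_numpy(dtype=float)
    if coding == "hours_day":
        return df
    df = df.drop(columns=["sun_hours_day"])
    if coding == "four_class":
        cls = np.digitize(hours, _FOUR_CLASS_CUTS)
        labels = np.array(FOUR_CLASS_LABELS, dtype=object)[cls]
        labels = np.where(np.isnan(hours), None, labels)
        df["sun_class"] = labels
    elif coding == "days_year":
        df["sun_days_year"] = np.round(hours * _DAYS_PER_YEAR_SCALE, 1)
    else:
        raise ValueError(f"unknown exposure coding {coding!r}")
    return df


def generate_multistudy(config: SimConfig | None = None) -> MultiStudyDataset:
    """Generate a multi-study case-control dataset under the pooling model.

    Per study: a large source population is simulated under HWE genotypes
    and logit(P(case)) = alpha_k + sum_v (beta_v + b_kv) * carrier_v +
    sum_c gamma_c Z_c, with b_kv ~ N(0, sigma_b^2); the requested numbers
    of cases and controls are then sampled without replacement.  Exposure
    is delivered in each study's native coding and covariates unavailable
    in a study are wholly missing there.  Byte-identical output for equal
    seeds.
    """
    if config is None:
        config = SimConfig()
    root = np.random.SeedSequence(config.seed)
    # realized random effects and intercepts come from a dedicated stream
    head = np.random.default_rng(root.spawn(1)[0])
    study_seqs = root.spawn(config.n_studies + 1)[1:]

    names = [name for name, _q in config.variant_specs]
    b = {name: head.normal(0.0, config.sigma_b, size=config.n_studies)
         for name in names}
    alphas = head.normal(config.intercept_mean, config.intercept_sd,
                         size=config.n_studies)

    cases = config._counts(config.cases_per_study)
    controls = config._counts(config.controls_per_study)
    codings = (list(config.exposure_coding) if config.exposure_coding is not None
               else [EXPOSURE_CODINGS[k % len(EXPOSURE_CODINGS)]
                     for k in range(config.n_studies)])

    studies, metadata = [], []
    for k in range(config.n_studies):
        rng = np.random.default_rng(study_seqs[k])
        df = _simulate_study(rng, config, k, cases[k], controls[k],
                             float(alphas[k]), {n: float(b[n][k]) for n in names})
        for cname, spec in config.confounder_specs.items():
            if spec.available_in is not None and k not in spec.available_in:
                df[cname] = np.nan
        df = _encode_exposure(df, codings[k])
        studies.append(df)
        metadata.append({
            "study": k,
            "design": "case-control",
            "control_source": "population",
            "matching": False,
            "phenotype_assessment": "questionnaire",
            "genotyping": "sequencing",
            "dna_source": "blood",
            "geographic_area": f"area_{k % 7}",
            "exposure_coding": codings[k],
            "n_cases": cases[k],
            "n_controls": controls[k],
        })

    truth = {
        "config": config,
        "b_k": {n: b[n].tolist() for n in names},
        "alpha_k": alphas.tolist(),
        "true_log_or": {n: config.log_or(n) for n in names},
    }
    return MultiStudyDataset(studies, metadata, truth)


def plant_logic_outcome(dataset: MultiStudyDataset, rule, predictor_names,
                        log_or: float, baseline: float,
                        seed: int = 0) -> MultiStudyDataset:
    """Replace the outcome with one driven by a known Boolean rule.

    The outcome is regenerated as Bernoulli with
    logit(p) = logit(baseline) + log_or * 1[rule true], where ``rule`` is a
    :mod:`poolgen.logicreg` tree whose leaf indices refer to
    ``predictor_names`` — binary 0/1 columns that must exist in every study
    table.  A fixture generator for logic-regression recovery experiments.
    """
    if not 0 < baseline < 1:
        raise ValueError("baseline must be a probability in (0,1)")
    rng = np.random.default_rng(seed)
    new_studies = []
    for df in dataset.studies:
        missing = [nm for nm in predictor_names if nm not in df.columns]
        if missing:
            raise KeyError(f"rule references unknown predictor(s): {missing}")
        X = df[list(predictor_names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("planted-rule predictors must be complete (no NaN)")
        active = logicreg.evaluate_tree(rule, X.astype(np.uint8))
        p = expit(logit(baseline) + log_or * active)
        out = df.copy()
        out["status"] = (rng.random(len(df)) < p).astype(int)
        new_studies.append(out)
    truth = dict(dataset.truth or {})
    truth["planted_rule"] = logicreg.tree_to_string(rule, list(predictor_names))
    truth["planted_log_or"] = float(log_or)
    truth["planted_baseline"] = float(baseline)
    return MultiStudyDataset(new_studies, list(dataset.metadata), truth)


def degrade(dataset: MultiStudyDataset, missing_mask: dict | None = None,
            hwe_disequilibrium: dict | None = None,
            exposure_recode: dict | None = None,
            seed: int = 0) -> MultiStudyDataset:
    """Impose realistic data pathologies on a clean simulated dataset.

    ``missing_mask`` maps study index -> list of column names set wholly
    missing there (missing-by-design covariates).  ``hwe_disequilibrium``
    maps study index -> inbreeding-like coefficient F in [0, 1); the
    study's genotype columns are redrawn with genotype frequencies
    (q^2 + Fq(1-q), 2q(1-q)(1-F), (1-q)^2 + Fq(1-q)), i.e. excess
    homozygosity, using each column's observed allele frequency (note this
    severs that study's genotype-outcome link — it is a QC fixture).
    ``exposure_recode`` maps study index -> a target native coding, giving
    the harmonizer real work to do.
    """
    missing_mask = missing_mask or {}
    hwe_disequilibrium = hwe_disequilibrium or {}
    exposure_recode = exposure_recode or {}
    variant_names = None
    if dataset.truth and "true_log_or" in dataset.truth:
        variant_names = list(dataset.truth["true_log_or"])

    rng = np.random.default_rng(seed)
    new_studies, new_meta = [], []
    for k, df in enumerate(dataset.studies):
        df = df.copy()
        meta = dict(dataset.metadata[k])
        for colname in missing_mask.get(k, []):
            if colname not in df.columns:
                raise KeyError(f"study {k}: no column {colname!r} to mask")
            df[colname] = np.nan
        F = float(hwe_disequilibrium.get(k, 0.0))
        if not 0 <= F < 1:
            raise ValueError("disequilibrium coefficient must be in [0,1)")
        if F > 0:
            cols = (variant_names if variant_names is not None
                    else [c for c in df.columns
                          if df[c].dropna().isin([0, 1, 2]).all()
                          and df[c].nunique() > 1])
            for c in cols:
                g = df[c].to_numpy(dtype=float)
                obs = g[~np.isnan(g)]
                if obs.size == 0:
                    continue
                q = obs.sum() / (2 * obs.size)
                probs = np.array([
                    (1 - q) ** 2 + F * q * (1 - q),
                    2 * q * (1 - q) * (1 - F),
                    q**2 + F * q * (1 - q),
                ])
                draw = rng.choice(3, size=len(df), p=probs / probs.sum())
                g_new = draw.astype(float)
                g_new[np.isnan(g)] = np.nan
                df[c] = g_new
        if k in exposure_recode:
            target = exposure_recode[k]
            df = _recode_exposure_between(df, meta["exposure_coding"], target, rng)
            meta["exposure_coding"] = target
        new_studies.append(df)
        new_meta.append(meta)
    return MultiStudyDataset(new_studies, new_meta, dataset.truth)


def _recode_exposure_between(df, current: str, target: str, rng) -> pd.DataFrame:
    """Convert a study's exposure column from one native coding to another."""
    if current == target:
        return df
    # recover an hours/day working column from the current coding
    if current == "hours_day":
        hours = df["sun_hours_day"].to_numpy(dtype=float)
        df = df.drop(columns=["sun_hours_day"])
    elif current == "days_year":
        hours = df["sun_days_year"].to_numpy(dtype=float) / _DAYS_PER_YEAR_SCALE
        df = df.drop(columns=["sun_days_year"])
    elif current == "four_class":
        lut = {lab: 6.0 * j / 3 for j, lab in enumerate(FOUR_CLASS_LABELS)}
        hours = df["sun_class"].map(lut).to_numpy(dtype=float)
        df = df.drop(columns=["sun_class"])
    else:
        raise ValueError(f"unknown source coding {current!r}")
    tmp = df.copy()
    tmp["sun_hours_day"] = hours
    return _encode_exposure(tmp, target)
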