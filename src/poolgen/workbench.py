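"""Pipeline orchestration, I/O and consistency checks.

Ties the stages together in the order a pooled analysis runs them:
appropriateness checks (HWE among controls per study, funnel/Egger), the
two-stage per-variant pooling under each requested inheritance model,
heterogeneity diagnostics, stratified analysis with the Breslow-Day
homogeneity test, and optional logic regression.  Also provides
screening-tally reconciliation (records in minus per-reason removals must
equal records out) and an exact conditional independence test for r x 2
participation tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetics, pooling

logger = logging.getLogger("poolgen")

__all__ = [
    "AnalysisConfig",
    "ScreeningTally",
    "read_study",
    "run_pipeline",
    "tally_screening",
    "fisher_exact_rx2",
]


@dataclass
class AnalysisConfig:
    """What to analyze and how.

    ``variants`` are genotype column names; ``inheritance_models`` a subset
    of dominant/recessive/additive; ``confounders`` maps study index to the
    confounder column list used in that study's first-stage model (absent
    studies get none: confounder sets may legitimately differ by study).
    """

    outcome: str = "status"
    variants: tuple = genetics.CANONICAL_VARIANTS
    inheritance_models: tuple = ("dominant",)
    confounders: dict = field(default_factory=dict)
    pooling_methods: tuple = ("moment",)
    stratify_by: tuple = ()
    one_stage: bool = False
    hwe_alpha: float = 0.05
    seed: int = 0


@dataclass
class ScreeningTally:
    """Counts at each screening step; must reconcile exactly."""

    records_in: int
    removals: dict          # reason -> count
    records_out: int

    def validate(self) -> "ScreeningTally":
        if self.records_in < 0 or self.records_out < 0:
            raise ValueError("counts must be non-negative")
        if any(v < 0 for v in self.removals.values()):
            raise ValueError("removal counts must be non-negative")
        removed = sum(self.removals.values())
        expected = self.records_in - removed
        if expected != self.records_out:
            raise ValueError(
                f"screening tally does not reconcile: {self.records_in} - "
                f"{removed} = {expected}, not {self.records_out} "
                f"(discrepancy {self.records_out - expected:+d})"
            )
        return self

    def as_frame(self) -> pd.DataFrame:
        rows = [("records in", self.records_in)]
        rows += [(f"removed: {k}", -v) for k, v in self.removals.items()]
        rows += [("records out", self.records_out)]
        return pd.DataFrame(rows, columns=["step", "count"])


def tally_screening(tally: ScreeningTally) -> ScreeningTally:
    """Validate a screening tally and log its reconciliation table."""
    tally.validate()
    logger.info("screening tally reconciles: %d - %d = %d",
                tally.records_in, sum(tally.removals.values()),
                tally.records_out)
    return tally


# --------------------------------------------------------------------------
# study I/O

_MANDATORY = ("status",)


def read_study(csv_path, dictionary_path=None):
    """Read one study CSV (plus optional YAML/JSON data dictionary).

    Validates mandatory columns and genotype value ranges; unknown columns
    are preserved but flagged in the returned metadata.  Returns
    ``(DataFrame, metadata dict)``.
    """
    df = pd.read_csv(csv_path)
    meta = {"path": str(csv_path), "n_rows": len(df)}
    if dictionary_path is not None:
        text = Path(dictionary_path).read_text()
        meta["dictionary"] = (json.loads(text) if str(dictionary_path).endswith(".json")
                              else yaml.safe_load(text))

    problems = []
    for col in _MANDATORY:
        if col not in df.columns:
            problems.append(f"missing mandatory column {col!r}")
    genotype_cols = [c for c in df.columns if c in genetics.CANONICAL_VARIANTS]
    declared = meta.get("dictionary", {}).get("genotype_columns") if dictionary_path else None
    if declared:
        genotype_cols = declared
    for col in genotype_cols:
        if col not in df.columns:
            problems.append(f"declared genotype column {col!r} absent")
            continue
        vals = df[col].dropna()
        bad = ~vals.isin([0, 1, 2])
        if bad.any():
            rows = list(df.index[df[col].notna()][bad])[:20]
            problems.append(
                f"genotype column {col!r} has invalid values at rows {rows}"
            )
    if problems:
        raise ValueError("study validation failed:\n- " + "\n- ".join(problems))

    known = set(_MANDATORY) | set(genotype_cols) | {
        "study", "subject_id", "case_type", "hair_color", "skin_type",
        "nevi_count", "freckles", "sun_hours_day", "sun_class",
        "sun_days_year", "age", "sex", "sunburns",
    }
    meta["unknown_columns"] = sorted(set(df.columns) - known)
    meta["genotype_columns"] = genotype_cols
    logger.info("read %s: %d rows", csv_path, len(df))
    return df, meta


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(studies, config: AnalysisConfig | None = None):
    """Run the staged analysis over a list of per-study tables.

    Stages: HWE among controls per study and variant -> per-variant
    first-stage logistic fits under each inheritance model -> two-stage
    pooling (each requested method) with heterogeneity -> Egger's test ->
    optional one-stage fit and stratified analyses.  Stage failures are
    collected per variant and the run continues where stages are
    independent.  Deterministic given the config seed.

    Returns a nested dict result bundle; see the keys ``hwe``,
    ``associations``, ``egger``, ``stratified``, ``errors``, ``log``.
    """
    if config is None:
        config = AnalysisConfig()
    if hasattr(studies, "studies"):  # accept a MultiStudyDataset directly
        studies = studies.studies
    studies = list(studies)
    bundle = {"hwe": {}, "associations": {}, "egger": {}, "stratified": {},
              "errors": [], "log": []}

    def note(msg, *args):
        logger.info(msg, *args)
        bundle["log"].append(msg % args if args else msg)

    note("pipeline start: %d studies, %d variants", len(studies),
         len(config.variants))

    # --- HWE among controls, per study ---
    for k, df in enumerate(studies):
        controls = df[df[config.outcome] == 0]
        for v in config.variants:
            if v not in df.columns:
                continue
            g = controls[v].dropna()
            if g.empty:
                continue
            counts = [(g == c).sum() for c in (0, 1, 2)]
            try:
                bundle["hwe"][(k, v)] = genetics.hwe_test(counts)
            except ValueError as e:
                bundle["errors"].append(f"hwe study {k} variant {v}: {e}")
    n_fail = sum(1 for r in bundle["hwe"].values()
                 if r.pvalue < config.hwe_alpha and not r.monomorphic)
    note("HWE: %d tests, %d below alpha=%.3g", len(bundle["hwe"]), n_fail,
         config.hwe_alpha)

    # --- per-variant association, each inheritance model ---
    for v in config.variants:
        for model in config.inheritance_models:
            effects = []
            for k, df in enumerate(studies):
                if v not in df.columns:
                    continue
                x = genetics.encode_inheritance(df[v].to_numpy(dtype=float), model)
                if x.ndim > 1:
                    continue  # codominant has two columns; not pooled here
                y = df[config.outcome].to_numpy(dtype=float)
                zcols = [c for c in config.confounders.get(k, []) if c in df.columns]
                z = df[zcols].to_numpy(dtype=float) if zcols else None
                try:
                    eff = pooling.fit_study_logistic(
                        y, x, z, study=f"study{k}", separation="continuity")
                except ValueError as e:
                    bundle["errors"].append(
                        f"first stage {v}/{model} study {k}: {e}")
                    continue
                if np.isfinite(eff.beta) and np.isfinite(eff.var_beta):
                    effects.append(eff)
            if len(effects) < 2:
                note("variant %s (%s): two-stage stage skipped — fewer than "
                     "two usable studies", v, model)
                continue
            entry = {"effects": effects}
            for method in config.pooling_methods:
                try:
                    entry[method] = pooling.pool_two_stage(effects, method)
                except ValueError as e:
                    bundle["errors"].append(f"pooling {v}/{model}/{method}: {e}")
            if len(effects) >= 3:
                try:
                    bundle["egger"][(v, model)] = pooling.egger_test(effects)
                except ValueError as e:
                    bundle["errors"].append(f"egger {v}/{model}: {e}")
            bundle["associations"][(v, model)] = entry

    # --- optional one-stage comparison on the first variant/model ---
    if config.one_stage and config.variants:
        v, model = config.variants[0], config.inheritance_models[0]
        ys, xs, labels = [], [], []
        for k, df in enumerate(studies):
            if v not in df.columns:
                continue
            x = genetics.encode_inheritance(df[v].to_numpy(dtype=float), model)
            ys.append(df[config.outcome].to_numpy(dtype=float))
            xs.append(x)
            labels.append(np.repeat(k, len(df)))
        try:
            bundle["one_stage"] = pooling.fit_one_stage(
                np.concatenate(ys), np.concatenate(xs), np.concatenate(labels))
        except ValueError as e:
            bundle["errors"].append(f"one-stage: {e}")

    # --- stratified analyses ---
    for stratum in config.stratify_by:
        v, model = config.variants[0], config.inheritance_models[0]
        prepared = []
        for df in studies:
            if v not in df.columns or stratum not in df.columns:
                continue
            tmp = df[[config.outcome, stratum]].copy()
            tmp["_x"] = genetics.encode_inheritance(
                df[v].to_numpy(dtype=float), model)
            prepared.append(tmp)
        if not prepared:
            bundle["errors"].append(f"stratified {stratum}: no usable study")
            continue
        try:
            bundle["stratified"][stratum] = pooling.stratified_association(
                prepared, "_x", stratum, outcome=config.outcome)
        except ValueError as e:
            bundle["errors"].append(f"stratified {stratum}: {e}")

    note("pipeline done: %d association entries, %d errors",
         len(bundle["associations"]), len(bundle["errors"]))
    return bundle


def write_results(bundle, directory) -> None:
    """Write the association table as TSV + JSON and funnel coordinates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (v, model), entry in bundle["associations"].items():
        for method in entry:
            if method == "effects":
                continue
            pooled, het = entry[method]
            lo, hi = pooled.ci()
            rows.append({
                "variant": v, "model": model, "method": method,
                "k": pooled.k, "log_or": pooled.beta, "se": pooled.se,
                "or": pooled.odds_ratio,
                "ci_low": np.exp(lo), "ci_high": np.exp(hi),
                "sigma2_b": pooled.sigma2_b, "q": het.q, "i2": het.i2,
                "q_pvalue": het.pvalue,
            })
    table = pd.DataFrame(rows)
    table.to_csv(directory / "associations.tsv", sep="\t", index=False)
    (directory / "associations.json").write_text(
        table.to_json(orient="records", indent=2))
    for (v, model), egger in bundle["egger"].items():
        egger.funnel.to_csv(directory / f"funnel_{v}_{model}.tsv",
                            sep="\t", index=False)


# --------------------------------------------------------------------------
# exact r x 2 independence test


@lru_cache(maxsize=1 << 16)
def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_rx2(table, guard: int = 2_000_000) -> float:
    """Exact conditional test of independence for an r x 2 count table.

    Enumerates every table with the observed margins (depth-first over
    rows, pruned by the running column total) and sums the multivariate
    hypergeometric probabilities of tables no more probable than the one
    observed — the standard two-sided exact p-value, reducing to Fisher's
    test for r = 2.  The ``guard`` bounds the number of visited tables;
    exceeding it raises with a suggestion to use a Monte-Carlo p-value.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("table must be r x 2 with r >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    col1 = int(t[:, 0].sum())
    n = int(t.sum())
    if col1 == 0 or col1 == n or (rows == 0).any():
        raise ValueError("margins must be positive")

    # log P(a_1..a_r | margins) = sum_i lchoose(n_i, a_i) - lchoose(N, C1)
    norm = _lchoose(n, col1)
    obs_logp = sum(_lchoose(int(rows[i]), int(t[i, 0])) for i in range(len(rows))) - norm
    tol = 1e-7 * abs(obs_logp)

    suffix = np.cumsum(rows[::-1])[::-1]  # total capacity of rows i..r-1
    r = len(rows)
    visited = 0
    total = 0.0

    def rec(i: int, remaining: int, logp: float):
        nonlocal visited, total
        if i == r - 1:
            if 0 <= remaining <= rows[i]:
                visited += 1
                if visited > guard:
                    raise ValueError(
                        "enumeration guard exceeded; use a Monte-Carlo "
                        "p-value (resample tables with fixed margins)"
                    )
                lp = logp + _lchoose(int(rows[i]), remaining) - norm
                if lp <= obs_logp + tol:
                    total += np.exp(lp)
            return
        cap_rest = int(suffix[i + 1])
        lo = max(0, remaining - cap_rest)
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a, logp + _lchoose(int(rows[i]), a))

    rec(0, col1, 0.0)
    return float(min(total, 1.0))
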