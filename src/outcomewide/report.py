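"""Outcome-wide report assembly: significance conventions, composite
wellbeing indices, coefficient alpha, and the pooled results table.

Completeness is a contract: every configured outcome appears exactly once
per model, nulls included.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

#: star conventions: p < 0.05 (*), p < 0.005 (**), p < Bonferroni (***)
BASE_THRESHOLDS = (0.05, 0.005)

FLOURISHING_DOMAINS = [
    "happiness_life_satisfaction",
    "mental_physical_health",
    "meaning_purpose",
    "character_virtue",
    "close_social_relationships",
    "financial_material_stability",
]


def bonferroni_threshold(alpha: float, n_outcomes: int) -> dict:
    """Bonferroni-corrected threshold alpha / n, with a 2-significant-
    figure display form; full precision is retained for computation."""
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    exact = alpha / n_outcomes
    display = float(f"{exact:.2g}")
    return {"exact": exact, "display": display}


def percent_retained(n_retained: int, n_total: int) -> float:
    """Retention rate as a percentage, one decimal place."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_retained / n_total, 1)


def retention_table(panel: pd.DataFrame,
                    country_col: str = "country",
                    retained_col: str = "retained") -> pd.DataFrame:
    """Per-country wave sizes and retention percentages, plus an Overall
    row, sorted by retention (descending)."""
    rows = []
    for country, df in panel.groupby(country_col):
        n1 = len(df)
        n2 = int(df[retained_col].sum())
        rows.append(dict(country=country, n_wave1=n1, n_wave2=n2,
                         n_dropped=n1 - n2,
                         pct_retained=percent_retained(n2, n1)))
    out = pd.DataFrame(rows).sort_values(
        "pct_retained", ascending=False, ignore_index=True)
    n1 = int(out["n_wave1"].sum())
    n2 = int(out["n_wave2"].sum())
    overall = pd.DataFrame([dict(country="Overall", n_wave1=n1, n_wave2=n2,
                                 n_dropped=n1 - n2,
                                 pct_retained=percent_retained(n2, n1))])
    return pd.concat([out, overall], ignore_index=True)


def composite_index(items: pd.DataFrame,
                    include_financial: bool = True) -> pd.Series:
    """Composite flourishing score: mean of twelve 0-10 items (two per
    domain), or ten when the financial/material pair is excluded.

    A row with any missing item gets a missing score; imputation is
    upstream's job.
    """
    expected = 12 if include_financial else 10
    if items.shape[1] != expected:
        raise ValueError(
            f"expected {expected} items, got {items.shape[1]}")
    score = items.mean(axis=1)
    score[items.isna().any(axis=1)] = np.nan
    return score


def coefficient_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's coefficient alpha of an item matrix (complete rows)."""
    X = np.asarray(items, float)
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]
    p = X.shape[1]
    if p < 2:
        raise ValueError("alpha requires at least 2 items")
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(p / (p - 1) * (1.0 - item_var.sum() / total_var))


def significance_stars(p: float, bonferroni: float) -> str:
    if p < bonferroni:
        return "***"
    if p < BASE_THRESHOLDS[1]:
        return "**"
    if p < BASE_THRESHOLDS[0]:
        return "*"
    return ""


def assemble_report(
    meta_table: pd.DataFrame,
    outcomes: list[tuple[str, str]],
    alpha: float = 0.05,
    domains: dict[str, str] | None = None,
    sensitivity_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the outcome-wide display table and machine bundle.

    ``meta_table`` is the output of :func:`outcomewide.meta.pool_countries`.
    Binary-outcome rows are exponentiated to RRs for display; continuous
    rows stay on the standardized-effect scale.  tau estimates below 0.01
    carry an instability dagger.  Raises if any configured outcome is
    missing from the meta results — null results are never dropped.
    """
    thr = bonferroni_threshold(alpha, len(outcomes))
    models = sorted(meta_table["model"].unique())
    rows = []
    for outcome, otype in outcomes:
        sub = meta_table[meta_table["outcome"] == outcome]
        if sub.empty:
            raise ValueError(f"outcome '{outcome}' missing from meta results"
                             " (outcome-wide completeness violated)")
        row: dict = {"outcome": outcome, "outcome_type": otype,
                     "domain": (domains or {}).get(outcome, "")}
        for model in models:
            cell = sub[sub["model"] == model]
            if cell.empty:
                raise ValueError(f"outcome '{outcome}' lacks model {model}")
            cell = cell.iloc[0]
            if otype == "binary":
                row[f"{model}_effect"] = math.exp(cell["mu"])
                row[f"{model}_ci_lo"] = math.exp(cell["ci_lo"])
                row[f"{model}_ci_hi"] = math.exp(cell["ci_hi"])
                row[f"{model}_scale"] = "RR"
            else:
                row[f"{model}_effect"] = cell["mu"]
                row[f"{model}_ci_lo"] = cell["ci_lo"]
                row[f"{model}_ci_hi"] = cell["ci_hi"]
                row[f"{model}_scale"] = "ES"
            tau = cell["tau"]
            row[f"{model}_tau"] = tau
            row[f"{model}_tau_dagger"] = bool(tau < 0.01)
            row[f"{model}_global_p"] = cell["global_p"]
            row[f"{model}_stars"] = significance_stars(
                cell["global_p"], thr["exact"])
        rows.append(row)
    table = pd.DataFrame(rows)

    bundle = {
        "alpha": alpha,
        "n_outcomes": len(outcomes),
        "bonferroni": thr,
        "models": models,
        "rows": table.to_dict(orient="records"),
    }
    if sensitivity_table is not None:
        bundle["sensitivity"] = sensitivity_table.to_dict(orient="records")
    return table, bundle


def bundle_roundtrip(bundle: dict) -> dict:
    """JSON round-trip (serialization is part of the report contract)."""
    return json.loads(json.dumps(bundle))
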