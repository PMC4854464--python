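"""Per-protein linear models of site-specific rate.

For each protein, the rate K at every site is regressed (ordinary least
squares, with intercept) on combinations of three per-site predictors:

* ``d``   — distance to the nearest catalytic residue (A),
* ``wcn`` — weighted contact number (1/A^2),
* ``rsa`` — relative solvent accessibility (fraction).

Seven formulas are fit: each predictor alone, each structural predictor
plus d, the purely structural pair WCN + RSA, and the full model.  The gain
in variance explained when d joins a structural model measures the
functional (active-site) constraint that packing and exposure cannot
account for.  Fits are per protein; aggregates average R-squared unweighted
across proteins (one protein, one vote).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ModelError
from .site_metrics import SiteTable

#: Canonical formula names mapped to their predictor columns.
FORMULAS: Mapping[str, tuple[str, ...]] = {
    "K~d": ("d",),
    "K~RSA": ("rsa",),
    "K~WCN": ("wcn",),
    "K~RSA+d": ("rsa", "d"),
    "K~WCN+d": ("wcn", "d"),
    "K~WCN+RSA": ("wcn", "rsa"),
    "K~WCN+RSA+d": ("wcn", "rsa", "d"),
}

#: (structural formula, same formula with d added) pairs for delta-R2.
NESTED_PAIRS: tuple[tuple[str, str], ...] = (
    ("K~RSA", "K~RSA+d"),
    ("K~WCN", "K~WCN+d"),
    ("K~WCN+RSA", "K~WCN+RSA+d"),
)

_PREDICTOR_ALIASES = {"d": "d", "wcn": "WCN", "rsa": "RSA"}


def normalize_formula(formula: str) -> str:
    """Map any predictor ordering ('K~RSA+WCN+d') onto the canonical name."""
    lhs, sep, rhs = formula.replace(" ", "").partition("~")
    if lhs != "K" or not sep:
        raise ValueError(f"not a rate formula: {formula!r}")
    preds = frozenset(p.lower() for p in rhs.split("+") if p)
    for name, cols in FORMULAS.items():
        if frozenset(cols) == preds:
            return name
    raise ValueError(f"unknown predictor combination in {formula!r}")


@dataclass
class ModelFit:
    """One OLS fit of K for one protein and one formula."""

    protein_id: str
    formula: str
    coefficients: Mapping[str, float]  # "intercept" plus one slope per predictor
    r_squared: float
    residuals: np.ndarray
    std_errors: Mapping[str, float] = field(default_factory=dict)
    n_sites: int = 0

    @property
    def predictors(self) -> tuple[str, ...]:
        return FORMULAS[self.formula]


def fit_model(table: SiteTable, formula: str) -> ModelFit:
    """Ordinary least squares of K on the formula's predictors, with intercept.

    A constant response returns R-squared 0 with zero slopes (convention);
    a constant predictor is a rank error naming the predictor.
    """
    formula = normalize_formula(formula)
    predictors = FORMULAS[formula]
    df = table.df.dropna(subset=["K", *predictors])
    n = len(df)
    if n < len(predictors) + 2:
        raise ModelError(
            f"{table.protein_id}: {n} usable sites, need >= {len(predictors) + 2}"
        )
    y = df["K"].to_numpy(dtype=float)
    for p in predictors:
        if np.ptp(df[p].to_numpy(dtype=float)) == 0.0:
            raise ModelError(f"{table.protein_id}: constant predictor {p!r}")
    if np.ptp(y) == 0.0:
        coefs = {"intercept": float(y[0])} | {p: 0.0 for p in predictors}
        return ModelFit(
            protein_id=table.protein_id,
            formula=formula,
            coefficients=coefs,
            r_squared=0.0,
            residuals=np.zeros(n),
            n_sites=n,
        )
    X = sm.add_constant(df[list(predictors)].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    names = ["intercept", *predictors]
    return ModelFit(
        protein_id=table.protein_id,
        formula=formula,
        coefficients=dict(zip(names, res.params)),
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        std_errors=dict(zip(names, res.bse)),
        n_sites=n,
    )


def fit_all_models(table: SiteTable) -> dict[str, ModelFit]:
    """Fit every canonical formula for one protein."""
    return {f: fit_model(table, f) for f in FORMULAS}


def residuals_by_shell(fit: ModelFit, table: SiteTable) -> dict[int, float]:
    """Mean residual (observed - predicted K) per distance shell.

    A structural model that ignores the active-site gradient overestimates
    K near the catalytic site, producing negative mean residuals in the
    inner shells.
    """
    df = table.df.dropna(subset=["K", *fit.predictors])
    if "shell" not in df.columns:
        raise ModelError("site table lacks a shell column")
    if len(df) != len(fit.residuals):
        raise ModelError("fit does not match table (site count differs)")
    shells = df["shell"].to_numpy()
    out: dict[int, float] = {}
    for s in sorted(set(int(x) for x in shells if x >= 0)):
        out[s] = float(fit.residuals[shells == s].mean())
    return out


def pooled_residuals_by_shell(
    fits: Sequence[ModelFit], tables: Sequence[SiteTable]
) -> dict[int, float]:
    """Residue-weighted mean residual per shell pooled over proteins."""
    num: dict[int, float] = {}
    cnt: dict[int, int] = {}
    for fit, table in zip(fits, tables, strict=True):
        df = table.df.dropna(subset=["K", *fit.predictors])
        shells = df["shell"].to_numpy()
        for s in sorted(set(int(x) for x in shells if x >= 0)):
            mask = shells == s
            num[s] = num.get(s, 0.0) + float(fit.residuals[mask].sum())
            cnt[s] = cnt.get(s, 0) + int(mask.sum())
    return {s: num[s] / cnt[s] for s in sorted(num)}


@dataclass(frozen=True)
class ProteinGroupLabel:
    """Stratification label for one protein.

    ``location`` classifies the active site by the mean RSA of the catalytic
    residues: core (< 0.05), intermediate ([0.05, 0.25)), surface (>= 0.25).
    ``size_class`` places the protein in the tertiles of the dataset's
    length distribution (ties to the lower class).
    """

    location: str
    size_class: str
    mean_catalytic_rsa: float
    n_sites: int


CORE_RSA_MAX = 0.05
SURFACE_RSA_MIN = 0.25


def classify_protein(
    table: SiteTable, dataset_lengths: Sequence[int]
) -> ProteinGroupLabel:
    """Assign active-site location and size class for one protein."""
    cat = table.df.loc[table.df["is_catalytic"]]
    if cat.empty:
        raise ModelError(f"{table.protein_id}: no catalytic residues to classify by")
    mean_rsa = float(cat["rsa"].mean())
    if mean_rsa < CORE_RSA_MAX:
        location = "core"
    elif mean_rsa < SURFACE_RSA_MIN:
        location = "intermediate"
    else:
        location = "surface"
    lengths = np.asarray(sorted(dataset_lengths))
    if lengths.size == 0:
        raise ValueError("dataset_lengths must be non-empty")
    q1, q2 = np.quantile(lengths, [1 / 3, 2 / 3])
    n = table.n_sites
    size_class = "small" if n <= q1 else ("medium" if n <= q2 else "large")
    return ProteinGroupLabel(
        location=location,
        size_class=size_class,
        mean_catalytic_rsa=mean_rsa,
        n_sites=n,
    )


@dataclass
class FitAggregate:
    """Across-protein summary of per-protein fits (one protein, one vote)."""

    mean_r_squared: Mapping[str, float]
    r_squared: Mapping[str, np.ndarray]
    delta_r_squared: Mapping[str, np.ndarray]  # keyed by structural formula
    groups: Mapping[str, "FitAggregate"] | None = None


def aggregate_fits(
    fits_per_protein: Sequence[Mapping[str, ModelFit]],
    labels: Sequence[ProteinGroupLabel] | None = None,
    group_by: str = "location",
) -> FitAggregate:
    """Aggregate per-protein fits into mean R2 and delta-R2 distributions.

    ``delta_r_squared[f]`` holds, per protein, R2(f + d) - R2(f) for each
    structural formula f; by OLS nesting it is always >= 0.  With `labels`,
    the same aggregation is repeated within each group of the chosen
    attribute (``location`` or ``size_class``).
    """
    if not fits_per_protein:
        raise ValueError("no fits to aggregate")
    needed = set(FORMULAS)
    for fits in fits_per_protein:
        missing = needed - set(fits)
        if missing:
            raise ModelError(f"protein missing formulas: {sorted(missing)}")
    r2 = {
        f: np.array([fits[f].r_squared for fits in fits_per_protein])
        for f in FORMULAS
    }
    delta = {
        base: r2[with_d] - r2[base] for base, with_d in NESTED_PAIRS
    }
    agg = FitAggregate(
        mean_r_squared={f: float(v.mean()) for f, v in r2.items()},
        r_squared=r2,
        delta_r_squared=delta,
    )
    if labels is not None:
        if len(labels) != len(fits_per_protein):
            raise ValueError("labels must align with fits_per_protein")
        groups: dict[str, FitAggregate] = {}
        keys = [getattr(lab, group_by) for lab in labels]
        for key in sorted(set(keys)):
            sub = [f for f, k in zip(fits_per_protein, keys) if k == key]
            groups[key] = aggregate_fits(sub)
        agg.groups = groups
    return agg


def fits_to_frame(fits: Iterable[ModelFit]) -> pd.DataFrame:
    """Serializable fit summary: one row per protein x formula."""
    rows = []
    for f in fits:
        rows.append(
            {
                "protein_id": f.protein_id,
                "formula": f.formula,
                "r_squared": f.r_squared,
                "coef_intercept": f.coefficients.get("intercept", np.nan),
                "coef_d": f.coefficients.get("d", np.nan),
                "coef_wcn": f.coefficients.get("wcn", np.nan),
                "coef_rsa": f.coefficients.get("rsa", np.nan),
            }
        )
    return pd.DataFrame(rows)
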