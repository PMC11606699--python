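"""Minimal design-matrix builder for the occupancy and detection submodels.

Supports the small term grammar the model structures need:

* ``"x"`` — a numeric column, or a categorical column expanded into
  treatment-coded dummies (reference level dropped);
* ``"I(x^2)"`` — the square of a numeric column;
* ``"a:b"`` — the product of two numeric terms (each side may be a plain
  column or an ``I(...)`` term).

An intercept column is always included first. Categorical level order (the
first level is the reference) is taken from the column's categorical dtype,
so fit-time and prediction-time matrices are guaranteed to align.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_SQUARE_RE = re.compile(r"^I\((\w+)\^2\)$")


def _numeric_term(df: pd.DataFrame, term: str) -> tuple[np.ndarray, str]:
    """Resolve a single numeric term (column or I(col^2)) to a vector."""
    m = _SQUARE_RE.match(term)
    if m:
        col = m.group(1)
        if col not in df.columns:
            raise KeyError(f"unknown covariate {col!r} in term {term!r}")
        return np.asarray(df[col], dtype=float) ** 2, term
    if term not in df.columns:
        raise KeyError(f"unknown covariate {term!r}")
    return np.asarray(df[term], dtype=float), term


def _expand_term(df: pd.DataFrame, term: str) -> list[tuple[np.ndarray, str]]:
    term = term.strip()
    if term in ("1", ""):
        return []
    if ":" in term:
        left, right = (p.strip() for p in term.split(":", 1))
        xl, nl = _numeric_term(df, left)
        xr, nr = _numeric_term(df, right)
        return [(xl * xr, f"{nl}:{nr}")]
    if term in df.columns and isinstance(df[term].dtype, pd.CategoricalDtype):
        cats = list(df[term].cat.categories)
        codes = df[term].cat.codes.to_numpy()
        if (codes < 0).any():
            raise ValueError(f"missing values in categorical covariate {term!r}")
        cols = []
        for k, level in enumerate(cats[1:], start=1):
            cols.append(((codes == k).astype(float), f"{term}[{level}]"))
        return cols
    x, name = _numeric_term(df, term)
    return [(x, name)]


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build an (n, k) design matrix with intercept from a term list.

    Raises if any referenced column is absent or a numeric column contains
    NaN (missing covariates are an error, never imputed).
    """
    n = len(df)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    for term in terms:
        for x, name in _expand_term(df, term):
            if np.isnan(x).any():
                raise ValueError(f"missing values in covariate term {name!r}")
            columns.append(x)
            names.append(name)
    X = np.column_stack(columns) if columns else np.ones((n, 1))
    return X, names


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Split ``"lhs ~ t1 + t2 + ..."`` into (lhs, term list).

    ``"lhs ~ 1"`` (or an empty right side) means intercept only.
    """
    if "~" not in formula:
        raise ValueError(f"formula {formula!r} lacks '~'")
    lhs, rhs = formula.split("~", 1)
    terms = [t.strip() for t in rhs.split("+") if t.strip() not in ("", "1")]
    return lhs.strip(), terms
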