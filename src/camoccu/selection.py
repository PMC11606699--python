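"""Hypothesis-driven multistep AIC model selection.

Three sequential candidate sets mirror the study design of the analysis:

1. *Detection step* — occupancy held constant (intercepts on all first- and
   second-order natural parameters), detection modelled as constant, linear
   Julian date, linear + quadratic Julian date, or lockdown phase.
2. *Marginal step* — best detection structure retained; the focal species'
   (marten's) first-order parameter modelled with vegetation + elevation +
   elevation^2 (Mod0A) or additionally distance to settlements (Mod0B),
   with an uninformative-parameter deviance check between the two. The
   other species keep distance-to-roads (humans) and distance-to-
   settlements (cats) throughout. All second-order parameters zero.
3. *Conditional step* — co-occurrence structures: Mod1 (independence, all
   pairwise terms zero — structurally identical to the winning marginal
   model), Mod2 (constant pairwise intercepts f12, f13), and Mod3A-E where
   f12 and f13 vary with distance to roads, distance to settlements, both
   additively, or interact with elevation. The human-cat term f23 and the
   third-order term are zero in every structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camdata import CovariateTable, DetectionHistory, DEFAULT_SPECIES
from .msom import FittedMSOM, ModelStructure, fit_msom

__all__ = ["CandidateSet", "build_candidate_sets", "aic_rank",
           "uninformative_check", "multistep_select", "SelectionReport"]

MARGINAL_F1_A = ["veg", "ele", "I(ele^2)"]
MARGINAL_F1_B = ["veg", "ele", "I(ele^2)", "dist_settl"]
F2_TERMS = ["dist_road"]
F3_TERMS = ["dist_settl"]

#: Pairwise-term covariates of the conditional candidate structures.
CONDITIONAL_PAIR_TERMS: dict[str, list[str] | None] = {
    "Mod1": None,
    "Mod2": [],
    "Mod3A": ["dist_road"],
    "Mod3B": ["dist_settl"],
    "Mod3C": ["dist_road", "dist_settl"],
    "Mod3D": ["ele", "dist_settl", "ele:dist_settl"],
    "Mod3E": ["ele", "dist_road", "ele:dist_road"],
}

DETECTION_SETS: dict[str, list[str]] = {
    "Constant": [],
    "JD": ["jdate"],
    "JD+JD2": ["jdate", "I(jdate^2)"],
    "Lockdown": ["lockdown"],
}


@dataclass
class CandidateSet:
    name: str
    models: list[ModelStructure]

    def labels(self) -> list[str]:
        return [m.label for m in self.models]


def _structure(label, species, f1, det, pair_terms=None, f23=None) -> ModelStructure:
    occ: dict[str, list[str] | None] = {
        "f1": list(f1), "f2": list(F2_TERMS), "f3": list(F3_TERMS),
        "f12": pair_terms if pair_terms is None else list(pair_terms),
        "f13": pair_terms if pair_terms is None else list(pair_terms),
        "f23": f23,
    }
    return ModelStructure(tuple(species), occ, {sp: list(det) for sp in species},
                          label=label)


def build_candidate_sets(species: tuple[str, ...] = DEFAULT_SPECIES,
                         detection_terms: list[str] | None = None,
                         marginal_f1: list[str] | None = None,
                         lockdown_coding: str = "factor") -> dict[str, CandidateSet]:
    """Build the three candidate sets.

    ``detection_terms`` / ``marginal_f1`` fix the structures carried into
    the later steps (normally supplied by :func:`multistep_select` from the
    earlier steps' winners; defaults are the JD+JD2 detection and Mod0A
    marginal structures). ``lockdown_coding`` is 'factor' (two treatment
    dummies) or 'numeric' (0/1/2 as a single slope).
    """
    if lockdown_coding not in ("factor", "numeric"):
        raise ValueError("lockdown_coding must be 'factor' or 'numeric'")
    lock_term = "lockdown" if lockdown_coding == "factor" else "lockdown_num"

    det_models = []
    for label, terms in DETECTION_SETS.items():
        terms = [lock_term if t == "lockdown" else t for t in terms]
        occ = {"f1": [], "f2": [], "f3": [], "f12": [], "f13": [], "f23": []}
        det_models.append(ModelStructure(tuple(species), occ,
                                         {sp: terms for sp in species}, label=label))
    det_set = CandidateSet("detection", det_models)

    det_terms = detection_terms if detection_terms is not None else DETECTION_SETS["JD+JD2"]
    marg_set = CandidateSet("marginal", [
        _structure("Mod0A", species, MARGINAL_F1_A, det_terms),
        _structure("Mod0B", species, MARGINAL_F1_B, det_terms),
    ])

    f1 = marginal_f1 if marginal_f1 is not None else MARGINAL_F1_A
    cond_models = [_structure(label, species, f1, det_terms, pair_terms=pt)
                   for label, pt in CONDITIONAL_PAIR_TERMS.items()]
    cond_set = CandidateSet("conditional", cond_models)
    return {"detection": det_set, "marginal": marg_set, "conditional": cond_set}


def aic_rank(fits: list[FittedMSOM]) -> pd.DataFrame:
    """AIC table (label, K, loglik, AIC, dAIC, weight) sorted ascending.

    Ties within 0.01 AIC are broken toward the model with fewer parameters.
    All fits must be to the same data (site counts are checked).
    """
    if not fits:
        raise ValueError("no fitted models to rank")
    ns = {f.n_sites for f in fits}
    if len(ns) > 1:
        raise ValueError(f"models fitted to different data (site counts {sorted(ns)})")
    df = pd.DataFrame({
        "label": [f.label for f in fits],
        "K": [f.K for f in fits],
        "loglik": [f.loglik for f in fits],
        "AIC": [f.aic for f in fits],
    })
    df = df.sort_values(["AIC", "K"], kind="mergesort").reset_index(drop=True)
    # near-ties (< 0.01) resolved toward fewer parameters
    order = df.index.to_list()
    for i in range(len(df) - 1):
        if (abs(df.loc[order[i], "AIC"] - df.loc[order[i + 1], "AIC"]) < 0.01
                and df.loc[order[i + 1], "K"] < df.loc[order[i], "K"]):
            order[i], order[i + 1] = order[i + 1], order[i]
    df = df.loc[order].reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    w = np.exp(-0.5 * df["dAIC"])
    df["weight"] = w / w.sum()
    return df


def uninformative_check(smaller: FittedMSOM, larger: FittedMSOM,
                        threshold: float = 2.0) -> dict:
    """Deviance-based check for an uninformative added parameter.

    The larger model must have exactly one extra coefficient. Returns the
    deviance difference 2*(loglik_larger - loglik_smaller) and a flag (the
    added variable is 'uninformative' when the gain falls below
    ``threshold``, i.e. the ~2-AIC-unit criterion). Reporting only — the
    model is never dropped automatically.
    """
    if larger.K - smaller.K != 1:
        raise ValueError("models must differ by exactly one parameter")
    if larger.n_sites != smaller.n_sites:
        raise ValueError("models fitted to different data")
    dev = 2.0 * (larger.loglik - smaller.loglik)
    return {"deviance_diff": dev, "uninformative": dev < threshold,
            "smaller": smaller.label, "larger": larger.label,
            "threshold": threshold}


@dataclass
class SelectionReport:
    detection_table: pd.DataFrame
    marginal_table: pd.DataFrame
    conditional_table: pd.DataFrame
    detection_winner: str
    marginal_winner: str
    conditional_winner: str
    uninformative: dict
    best_fit: FittedMSOM
    fits: dict[str, FittedMSOM] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "detection": self.detection_table.to_dict(orient="records"),
            "marginal": self.marginal_table.to_dict(orient="records"),
            "conditional": self.conditional_table.to_dict(orient="records"),
            "winners": {"detection": self.detection_winner,
                        "marginal": self.marginal_winner,
                        "conditional": self.conditional_winner},
            "uninformative_check": self.uninformative,
            "failures": self.failures,
        }


def _fit_set(candidates: CandidateSet, history, cov, failures, seed,
             **kwargs) -> list[FittedMSOM]:
    fits = []
    for m in candidates.models:
        try:
            fits.append(fit_msom(history, cov, m, seed=seed, **kwargs))
        except (RuntimeError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures[m.label] = str(exc)
    if not fits:
        raise RuntimeError(f"every model in set {candidates.name!r} failed to fit")
    return fits


def multistep_select(history: DetectionHistory, cov: CovariateTable,
                     species: tuple[str, ...] = DEFAULT_SPECIES,
                     lockdown_coding: str = "factor", seed: int = 0,
                     compute_vcov: bool = True) -> SelectionReport:
    """Run the three-step selection and return all AIC tables plus the winner.

    Models that fail to converge are recorded in ``failures`` and excluded
    from the ranking; selection proceeds over the converged models.
    """
    failures: dict[str, str] = {}
    sets = build_candidate_sets(species, lockdown_coding=lockdown_coding)

    det_fits = _fit_set(sets["detection"], history, cov, failures, seed,
                        compute_vcov=False)
    det_table = aic_rank(det_fits)
    det_winner = det_table.loc[0, "label"]
    lock_term = "lockdown" if lockdown_coding == "factor" else "lockdown_num"
    det_terms = [lock_term if t == "lockdown" else t
                 for t in DETECTION_SETS[det_winner]]

    sets = build_candidate_sets(species, detection_terms=det_terms,
                                lockdown_coding=lockdown_coding)
    marg_fits = _fit_set(sets["marginal"], history, cov, failures, seed,
                         compute_vcov=False)
    marg_table = aic_rank(marg_fits)
    marg_winner = marg_table.loc[0, "label"]
    by_label = {f.label: f for f in marg_fits}
    uninf = {}
    if {"Mod0A", "Mod0B"} <= set(by_label):
        uninf = uninformative_check(by_label["Mod0A"], by_label["Mod0B"])
    f1 = MARGINAL_F1_B if marg_winner == "Mod0B" else MARGINAL_F1_A

    sets = build_candidate_sets(species, detection_terms=det_terms,
                                marginal_f1=f1, lockdown_coding=lockdown_coding)
    cond_fits = _fit_set(sets["conditional"], history, cov, failures, seed,
                         compute_vcov=compute_vcov)
    cond_table = aic_rank(cond_fits)
    cond_winner = cond_table.loc[0, "label"]
    best = {f.label: f for f in cond_fits}[cond_winner]
    fits = {f"detection:{f.label}": f for f in det_fits}
    fits |= {f"marginal:{f.label}": f for f in marg_fits}
    fits |= {f"conditional:{f.label}": f for f in cond_fits}
    return SelectionReport(det_table, marg_table, cond_table, det_winner,
                           marg_winner, cond_winner, uninf, best, fits, failures)
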