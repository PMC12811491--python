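"""Leave-one-out stability of the regularized PLS fit.

Each fold drops one participant, re-standardizes both domains within the
fold, and refits at the full-sample regularization budgets.  Fold
components are sign-aligned to the full-sample reference before
summarizing phenotype-coefficient distributions and per-edge coefficient
standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLSComponent, RegularizationSpec, RPLSResults, fit_rpls, standardize_domains

__all__ = ["LOOCVEnsemble", "loocv", "align_signs", "summarize_stability"]


def align_signs(fold_component: PLSComponent, reference_component: PLSComponent) -> PLSComponent:
    """Flip a fold component (both weight vectors) onto the reference sign.

    Flip iff wp . wp_ref < 0; on an exact zero, decide by wc . wc_ref; if
    both overlaps are exactly zero, leave unflipped.
    """
    dp = float(fold_component.wp @ reference_component.wp)
    if dp == 0.0:
        dp = float(fold_component.wc @ reference_component.wc)
        if dp == 0.0:
            warnings.warn("fold component orthogonal to reference; leaving unflipped",
                          stacklevel=2)
            return fold_component
    if dp >= 0:
        return fold_component
    return PLSComponent(
        wc=-fold_component.wc,
        wp=-fold_component.wp,
        phi=-fold_component.phi,
        psi=-fold_component.psi,
        cov_score=fold_component.cov_score,
        pct_cov=fold_component.pct_cov,
        converged=fold_component.converged,
    )


@dataclass
class LOOCVEnsemble:
    """n leave-one-out refits aligned to the full-sample reference."""

    reference: RPLSResults
    fold_results: list[RPLSResults | None]   # None where the fold errored
    fold_errors: dict[int, str]
    spec: RegularizationSpec
    k: int
    phenotype_labels: tuple[str, ...]
    aligned: bool = True

    @property
    def n_folds(self) -> int:
        return len(self.fold_results)

    @property
    def n_ok(self) -> int:
        return sum(r is not None for r in self.fold_results)

    def wp_array(self, component: int) -> np.ndarray:
        """(n_ok, p) matrix of aligned fold phenotype coefficients."""
        return np.vstack(
            [r.components[component].wp for r in self.fold_results if r is not None]
        )

    def wc_array(self, component: int) -> np.ndarray:
        return np.vstack(
            [r.components[component].wc for r in self.fold_results if r is not None]
        )


def loocv(
    C_raw: np.ndarray,
    P_raw: np.ndarray,
    spec: RegularizationSpec,
    k: int = 4,
    phenotype_labels: tuple[str, ...] | None = None,
) -> LOOCVEnsemble:
    """Fit n leave-one-out models at fixed regularization budgets.

    Domains are re-standardized within each fold (no leakage from the
    held-out row); the budgets are NOT re-selected per fold.  Fold-level
    errors are recorded without aborting the ensemble.
    """
    C_raw = np.asarray(C_raw, dtype=float)
    P_raw = np.asarray(P_raw, dtype=float)
    n = C_raw.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 participants for LOOCV, got {n}")
    if phenotype_labels is None:
        phenotype_labels = tuple(f"p{i}" for i in range(P_raw.shape[1]))

    C_full, P_full = standardize_domains(C_raw, P_raw)
    reference = fit_rpls(C_full, P_full, spec, k)

    fold_results: list[RPLSResults | None] = []
    fold_errors: dict[int, str] = {}
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        try:
            Ci, Pi = standardize_domains(C_raw[keep], P_raw[keep])
            res = fit_rpls(Ci, Pi, spec, k)
            res.components = [
                align_signs(res.components[j], reference.components[j]) for j in range(k)
            ]
            fold_results.append(res)
        except ValueError as exc:
            fold_errors[i] = str(exc)
            fold_results.append(None)
        keep[i] = True
    if fold_errors:
        warnings.warn(f"{len(fold_errors)} of {n} LOOCV folds failed", stacklevel=2)
    return LOOCVEnsemble(
        reference, fold_results, fold_errors, spec, k, tuple(phenotype_labels)
    )


def summarize_stability(ensemble: LOOCVEnsemble, stable_threshold: float = 0.9):
    """Stability tables across an aligned LOOCV ensemble.

    Returns a dict with
      - ``phenotype_distribution``: long-format per-fold w_p coefficients,
      - ``phenotype_boxstats``: min/q1/median/q3/max per component/variable,
      - ``edge_sd``: (k, E) per-edge coefficient standard deviation,
      - ``stable``: per-component flag — True when the dominant phenotype
        set (top-2 nonzero |coefficient| variables, the same rule that
        names a component) is identical in >= 90 % of folds.
    """

    def dominant_set(wp: np.ndarray) -> frozenset:
        order = np.argsort(-np.abs(wp), kind="stable")
        return frozenset(int(j) for j in order[:2] if wp[j] != 0)
    k = ensemble.k
    labels = ensemble.phenotype_labels
    long_rows = []
    box_rows = []
    edge_sd = []
    stable = []
    for comp in range(k):
        Wp = ensemble.wp_array(comp)  # (folds, p)
        Wc = ensemble.wc_array(comp)
        fold_ids = [i for i, r in enumerate(ensemble.fold_results) if r is not None]
        for f, row in zip(fold_ids, Wp):
            for j, lab in enumerate(labels):
                long_rows.append((f, comp, lab, row[j]))
        q = np.percentile(Wp, [0, 25, 50, 75, 100], axis=0)
        for j, lab in enumerate(labels):
            box_rows.append((comp, lab, *q[:, j]))
        edge_sd.append(Wc.std(axis=0, ddof=1))
        ref_dom = dominant_set(ensemble.reference.components[comp].wp)
        agree = [dominant_set(row) == ref_dom for row in Wp]
        stable.append(bool(np.mean(agree) >= stable_threshold))
    return {
        "phenotype_distribution": pd.DataFrame(
            long_rows, columns=["fold", "component", "variable", "coefficient"]
        ),
        "phenotype_boxstats": pd.DataFrame(
            box_rows, columns=["component", "variable", "min", "q1", "median", "q3", "max"]
        ),
        "edge_sd": np.vstack(edge_sd),
        "stable": stable,
    }
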